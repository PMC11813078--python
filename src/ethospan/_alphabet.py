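"""Fixed label alphabets shared across the pipeline."""

NODE_NAMES = (
    "head", "eyeL", "eyeR", "proboscis", "thorax", "abdomen",
    "wingL", "wingR", "forelegL", "forelegR", "midlegL", "midlegR",
    "hindlegL", "hindlegR",
)
N_NODES = len(NODE_NAMES)

HEAD = NODE_NAMES.index("head")
THORAX = NODE_NAMES.index("thorax")
PROBOSCIS = NODE_NAMES.index("proboscis")

#: the seven well-defined stereotyped behaviors
BEHAVIORS = (
    "idle", "proboscis", "fore_groom", "hind_groom", "wing_groom",
    "locomotion", "altered_locomotion",
)
EDGE_LABEL = "edge"
UNSTEREOTYPED_LABEL = "unstereotyped"
ALL_LABELS = BEHAVIORS + (EDGE_LABEL, UNSTEREOTYPED_LABEL)

#: nodes excluded from edge-detection features
EDGE_FEATURE_NODES = tuple(n for n in NODE_NAMES if n != "proboscis")

LEG_NODES = ("forelegL", "forelegR", "midlegL", "midlegR", "hindlegL", "hindlegR")
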