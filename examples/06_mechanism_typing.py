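"""Classify drug-combination mechanisms from protein-target sets."""

from phenocomb import TargetProfile, classify_pair

pairs = [
    ("complementary targeted pair",
     TargetProfile("erlotinib-like", {"EGFR", "ERBB2"}),
     TargetProfile("vemurafenib-like", {"BRAF", "RAF1"})),
    ("same-target pair",
     TargetProfile("drugA", {"TOP1", "TOP2A"}),
     TargetProfile("drugB", {"TOP1", "TOP2A"})),
    ("targeted + wide-spectrum",
     TargetProfile("specific", {"ALK"}),
     TargetProfile("multikinase", {f"K{i}" for i in range(60)})),
    ("intermediate target count",
     TargetProfile("midrange", {f"P{i}" for i in range(25)}),
     TargetProfile("narrow", {"JAK3"})),
]

for label, a, b in pairs:
    call = classify_pair(a, b)
    print(f"{label:30s} overlap={call.overlap_type} "
          f"specificity={call.specificity_type} "
          f"ratios=({call.common_ratio_A:.2f}, {call.common_ratio_B:.2f})")

# overlap: a = mostly different targets (<10% shared for both drugs),
#          b = partial overlap, c = same targets (>80% for both).
# specificity: d = two molecularly targeted drugs (<=10 targets each),
#          e = two wide-spectrum drugs (>50 each), f = mixed;
#          drugs with 11-50 targets have no defined class -> unclassified.
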