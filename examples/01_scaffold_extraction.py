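"""Clean raw SMILES, fragment them with RECAP, and filter the fragments to
ring-containing, fragment-like scaffolds with `*` attachment points."""

from phenocomb import clean_structure, filter_scaffolds, recap_scaffolds

RAW = [
    "CN1CCC[C@H]1c1cccnc1.Cl",          # nicotine hydrochloride salt, with stereo
    "CC(=O)Nc1ccc(O)cc1",               # acetaminophen
    "CNC(=O)c1ccccc1",                  # N-methylbenzamide
    "CCCCCCCC",                         # acyclic: no scaffold survives
]

for raw in RAW:
    record = clean_structure(raw)
    fragments = recap_scaffolds(record)
    kept = filter_scaffolds(fragments)
    print(f"{raw:40s} -> clean {record.smiles}")
    print(f"  {len(fragments)} RECAP fragment(s), {len(kept)} pass the scaffold filter")
    for s in kept:
        print(f"    scaffold {s.smiles}  rings={s.n_rings} heavy={s.n_heavy} "
              f"hetero={s.n_hetero} breakpoints={s.n_breakpoints}")

# The scaffold filter keeps ring-containing fragments inside fragment-like
# property bounds; single-ring fragments with a single attachment point must
# additionally be complex (>10 heavy atoms or >2 heteroatoms), which is why
# the bare benzamide core is dropped while fused or di-substituted rings pass.
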