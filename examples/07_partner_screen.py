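"""End-to-end partner screen: given a known drug and the phenotype of its
desired partner, generate scaffolds, screen a compound library, and rank
candidate partners by predicted synergy (~4 min on one CPU)."""

import numpy as np
from dataclasses import replace

from phenocomb import clean_structure
from phenocomb.gsg import GSGConfig, train_gsg
from phenocomb.screen import run_partner_screen, select_candidates
from phenocomb.sdsp import SDSPConfig, train_sdsp
from phenocomb.synthetic import (SyntheticSpec, decorate_scaffold,
                                 gen_cell_profiles, gen_decorated_library,
                                 gen_phenotype_scaffold_pairs,
                                 gen_synergy_dataset, scaffold_variant)

spec = SyntheticSpec(seed=5)
rng = np.random.default_rng(1)

# 1. train the two models on synthetic data
toy = [scaffold_variant(spec.scaffold_families[i % 8], rng) for i in range(500)]
gsg_cfg = GSGConfig(n_c=8, n_H=64, n_s=6, emb_dim=32, enc_window=12,
                    lr=5e-3, batch_size=32, seed=0)
gsg, _ = train_gsg(toy, "pretrain", cfg=gsg_cfg, epochs=20, seed=0)
pairs, _, _ = gen_phenotype_scaffold_pairs(spec)
gsg, _ = train_gsg(pairs, "finetune", model=gsg, epochs=25, seed=0)

train, _, _ = gen_synergy_dataset(spec, n_samples=4000, seed=11)
sdsp_cfg = SDSPConfig(n_H=32, emb_dim=32, head_widths=(64, 32, 1),
                      lr=2e-3, batch_size=128, accumulate=1, seed=0)
sdsp, _ = train_sdsp(train, sdsp_cfg, epochs=14, seed=0)

# 2. the screen: known drug from family 2, partner phenotype = class 0,
#    in the cell line where (family 2, family 0) is the planted synergy
library, family_of, _ = gen_decorated_library(
    replace(spec, library_size=250, family_weights=(1, 1, 3, 0, 0, 0, 0, 0)))
profiles, _ = gen_cell_profiles(spec)
cell = profiles["CELL2"][0].values
known = clean_structure(decorate_scaffold(spec.scaffold_families[2],
                                          np.random.default_rng(77)), "known")
partner_phenotype = pairs[0][0]  # a class-0 vector

result = run_partner_screen(partner_phenotype, known, library, gsg, sdsp,
                            cell, "CELL2", n_scaffolds=100, temperature=0.7, seed=0)
print(f"status={result.status}  surviving scaffolds={len(result.scaffolds)}  "
      f"candidates={len(result.candidates)}")
potent = select_candidates(result.candidates, synergistic_only=True)
print(f"potent candidates (score >= 5): {len(potent)}")
for c in potent[:5]:
    fam = family_of.get(c.drugB.id, "?")
    print(f"  {c.drugB.smiles:35s} family={fam} score={c.score:+.2f}")

# Candidates from the planted partner family dominate the potent list;
# their predicted scores sit near the planted synergy bonus (+12) while
# random library drugs score near the background mean (~ -0.5).
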