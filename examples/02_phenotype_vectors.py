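"""Build discrete differential-expression phenotype vectors from a small
expression table: +1 = up-regulated (log2 fold change > 1), -1 = down, 0 =
unchanged."""

import numpy as np
import pandas as pd

from phenocomb import deg_vector, minmax_normalize

genes = [f"G{i:04d}" for i in range(1, 9)]
expr = pd.DataFrame(
    {"control": [10, 10, 10, 10, 5, 5, 5, 5],
     "treated": [45, 10, 2, 11, 5, 22, 1, 5]},
    index=genes, dtype=float)

print("min-max normalized (per gene, across samples):")
print(minmax_normalize(expr).round(2))

vec = deg_vector(expr["treated"], expr["control"], gene_ids=genes)
print("\nphenotype vector (gene: call):")
for g, v in zip(vec.gene_ids, vec.values):
    print(f"  {g}: {v:+d}" if v else f"  {g}:  0")

# G0001 (10->45) and G0006 (5->22) are up (fold change > 2x), G0003 and
# G0007 are down; a 10->11 change stays 0 because the threshold is strict.
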