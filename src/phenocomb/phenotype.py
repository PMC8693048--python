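"""Cell-line expression features and discrete differential-expression
phenotype vectors over the 978 landmark genes.

A phenotype vector encodes the transcriptional change between two cell
states (drug-treated vs control, knockout vs wild type, tumour vs normal)
as one integer per landmark gene: +1 up-regulated (log2 fold change > 1),
-1 down-regulated (< -1), 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_LANDMARK = 978

__all__ = [
    "N_LANDMARK", "ExpressionProfile", "PhenotypeVector", "landmark_gene_ids",
    "minmax_normalize", "deg_vector", "collapse_replicates", "read_expression_tsv",
]


def landmark_gene_ids(n: int = N_LANDMARK) -> list[str]:
    """The package's default landmark identifiers (synthetic G0001..G0978);
    any fixed 978-id list, e.g. real landmark probe ids, works identically."""
    return [f"G{i + 1:04d}" for i in range(n)]


@dataclass(frozen=True)
class ExpressionProfile:
    """Min-max scaled basal expression of the landmark genes for one sample."""

    gene_ids: tuple
    values: np.ndarray  # floats in [0, 1], length == len(gene_ids)

    def __post_init__(self):
        if len(self.gene_ids) != len(self.values):
            raise ValueError("gene_ids and values differ in length")


@dataclass(frozen=True)
class PhenotypeVector:
    gene_ids: tuple
    values: np.ndarray  # ints in {-1, 0, 1}

    def __post_init__(self):
        vals = np.asarray(self.values)
        if len(self.gene_ids) != len(vals):
            raise ValueError("gene_ids and values differ in length")
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("phenotype entries must be in {-1, 0, 1}")

    def __neg__(self) -> "PhenotypeVector":
        return PhenotypeVector(self.gene_ids, -np.asarray(self.values))


def minmax_normalize(matrix: pd.DataFrame, constant_value: float = 0.0) -> pd.DataFrame:
    """Per-gene min-max scaling of a genes x samples matrix to [0, 1].

    Genes constant across samples map to ``constant_value`` (default 0:
    unexpressed-by-convention).  Idempotent on already-scaled data with a
    full [0, 1] range.
    """
    lo = matrix.min(axis=1)
    hi = matrix.max(axis=1)
    span = hi - lo
    out = matrix.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    return out.fillna(constant_value)


def profiles_from_matrix(matrix: pd.DataFrame) -> dict[str, ExpressionProfile]:
    norm = minmax_normalize(matrix)
    gene_ids = tuple(norm.index)
    return {c: ExpressionProfile(gene_ids, norm[c].to_numpy()) for c in norm.columns}


def deg_vector(treated: np.ndarray | pd.Series, control: np.ndarray | pd.Series,
               gene_ids=None, threshold: float = 1.0, pseudocount: float = 0.0) -> PhenotypeVector:
    """Discretize log2 fold changes treated/control at +-``threshold``.

    The threshold is strict: |log2FC| exactly equal to the threshold maps
    to 0.  Zero or negative values require a positive ``pseudocount``.
    """
    t = np.asarray(treated, dtype=float) + pseudocount
    c = np.asarray(control, dtype=float) + pseudocount
    if t.shape != c.shape:
        raise ValueError("treated and control differ in shape")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("non-positive expression values; pass a pseudocount")
    lfc = np.log2(t / c)
    vals = np.where(lfc > threshold, 1, np.where(lfc < -threshold, -1, 0))
    if gene_ids is None:
        gene_ids = landmark_gene_ids(len(vals))
    return PhenotypeVector(tuple(gene_ids), vals)


def collapse_replicates(matrix: pd.DataFrame, groups: dict[str, list[str]],
                        how: str = "median") -> pd.DataFrame:
    """Collapse replicate sample columns into one column per condition.

    ``how`` is "median" (default; robust, used for synergy tables) or
    "mean" (used for expression profiles).
    """
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    out = {}
    for name, cols in groups.items():
        sub = matrix[cols]
        out[name] = sub.median(axis=1) if how == "median" else sub.mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids); a two-line
    GCT-style header ('#1.2' + dimensions) is tolerated and skipped."""
    with open(path) as fh:
        first = fh.readline()
        skip = 2 if first.startswith("#1.") else 0
    return pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
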