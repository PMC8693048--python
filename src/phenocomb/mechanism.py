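"""Drug-combination mechanism typing from protein-target sets.

Two orthogonal classifications of a drug pair:

* **target overlap** — type ``a`` if the common-target ratio
  |tA ∩ tB| / |tX| is below 10% for both drugs (complementary mechanisms),
  ``c`` if above 80% for both (same targets), ``b`` otherwise;
* **drug specificity** — a drug with at most 10 targets is *molecularly
  targeted*, one with more than 50 is *wide-spectrum*; pairs are typed
  ``d`` (two targeted), ``e`` (two wide), ``f`` (mixed).  Drugs with 11-50
  targets have no defined class and yield an explicit ``unclassified``
  flag rather than a silent guess.  An alternative mapping
  (``figure_mapping=True``: d=two targeted, e=mixed, f=two wide) is
  available because the two conventions both appear in the literature.

A minimal pluggable drug-target-interaction predictor interface is
included so screened compounds without curated targets can be annotated by
any external compound-protein model; a lookup-table implementation ships
for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .phenotype import PhenotypeVector

__all__ = [
    "TargetProfile", "MechanismCall", "classify_overlap", "classify_specificity",
    "classify_pair", "filter_reference_targets", "DTIPredictor", "LookupDTIPredictor",
]


@dataclass(frozen=True)
class TargetProfile:
    drug_id: str
    targets: frozenset

    def __post_init__(self):
        object.__setattr__(self, "targets", frozenset(self.targets))


@dataclass(frozen=True)
class MechanismCall:
    overlap_type: str          # 'a' | 'b' | 'c'
    specificity_type: str      # 'd' | 'e' | 'f' | 'unclassified'
    common_ratio_A: float
    common_ratio_B: float


def classify_overlap(tA: TargetProfile, tB: TargetProfile,
                     low: float = 0.10, high: float = 0.80) -> tuple[str, float, float]:
    """Overlap type plus the per-drug common-target ratios.

    Boundaries are strict on both sides: both ratios < ``low`` gives 'a',
    both > ``high`` gives 'c', anything else 'b'.
    """
    if not tA.targets or not tB.targets:
        raise ValueError("empty target set")
    common = len(tA.targets & tB.targets)
    ra = common / len(tA.targets)
    rb = common / len(tB.targets)
    if ra < low and rb < low:
        t = "a"
    elif ra > high and rb > high:
        t = "c"
    else:
        t = "b"
    return t, ra, rb


def _drug_class(n_targets: int, targeted_max: int = 10, wide_min: int = 50) -> str:
    if n_targets <= targeted_max:           # "no more than ten" is inclusive
        return "targeted"
    if n_targets > wide_min:                # "more than 50" is strict
        return "wide"
    return "unclassified"


def classify_specificity(tA: TargetProfile, tB: TargetProfile,
                         figure_mapping: bool = False) -> str:
    """Pair specificity type from the per-drug target counts.

    Default mapping: d = two targeted, e = two wide-spectrum, f = mixed.
    ``figure_mapping=True`` swaps e and f (e = mixed, f = two wide).
    Returns 'unclassified' when either drug has 11-50 targets.
    """
    if not tA.targets or not tB.targets:
        raise ValueError("empty target set")
    ca, cb = _drug_class(len(tA.targets)), _drug_class(len(tB.targets))
    if "unclassified" in (ca, cb):
        return "unclassified"
    if ca == cb == "targeted":
        return "d"
    if ca == cb == "wide":
        return "e" if not figure_mapping else "f"
    return "f" if not figure_mapping else "e"


def classify_pair(tA: TargetProfile, tB: TargetProfile, figure_mapping: bool = False) -> MechanismCall:
    overlap, ra, rb = classify_overlap(tA, tB)
    return MechanismCall(
        overlap_type=overlap,
        specificity_type=classify_specificity(tA, tB, figure_mapping=figure_mapping),
        common_ratio_A=ra,
        common_ratio_B=rb,
    )


def filter_reference_targets(deg: PhenotypeVector, direction: str,
                             universe: dict) -> set:
    """Proteins whose genes move in ``direction`` ('up' = +1, 'down' = -1),
    intersected with the gene -> protein ``universe`` map."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not universe:
        raise ValueError("empty gene->protein universe")
    want = 1 if direction == "up" else -1
    vals = np.asarray(deg.values)
    return {universe[g] for g, v in zip(deg.gene_ids, vals) if v == want and g in universe}


class DTIPredictor(Protocol):
    """Pluggable drug-target-interaction model: (drug SMILES, protein
    sequence or id) -> interaction probability in [0, 1]."""

    def predict(self, smiles: str, protein: str) -> float: ...


class LookupDTIPredictor:
    """Table-backed predictor for tests and curated annotations."""

    def __init__(self, table: dict[tuple[str, str], float], default: float = 0.0):
        self.table = dict(table)
        self.default = default

    def predict(self, smiles: str, protein: str) -> float:
        return self.table.get((smiles, protein), self.default)

    def targets_of(self, smiles: str, proteins, threshold: float = 0.5) -> frozenset:
        return frozenset(p for p in proteins if self.predict(smiles, p) >= threshold)
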