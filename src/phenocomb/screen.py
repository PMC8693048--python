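"""End-to-end virtual screening: phenotype -> generated scaffolds -> library
substructure hits -> drug pairs -> synergy scores -> ranked candidates.

Two modes mirror the two screening applications:

* **partner screen** — a known drug A plus the phenotype of its desired
  partner; the generator proposes scaffolds for drug B, the library is
  screened for compounds containing them, and each hit is scored in
  combination with drug A.
* **de novo screen** — both drugs come from the library: hits of
  *different* generated scaffolds are paired (cross-scaffold product,
  unordered, deduplicated) and scored.

Candidate selection keeps potent pairs (|predicted Bliss| >= 5 by default,
inclusive), and ranking is deterministic: by predicted score, ties broken
by canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .chem import (MoleculeRecord, Scaffold, ScaffoldFilter, filter_scaffolds,
                   scaffold_from_smiles, screen_substructure)
from .gsg import GSG
from .phenotype import PhenotypeVector
from .sdsp import SDSP, SynergySample

__all__ = ["ScreeningCandidate", "ScreenResult", "generate_filtered_scaffolds",
           "run_partner_screen", "run_denovo_screen", "select_candidates"]


@dataclass(frozen=True)
class ScreeningCandidate:
    drugA: MoleculeRecord
    drugB: MoleculeRecord
    cell_id: str
    score: float
    scaffolds: tuple  # generated-scaffold SMILES the screened drug(s) matched

    def key(self) -> tuple:
        return (self.drugA.smiles, self.drugB.smiles)


@dataclass
class ScreenResult:
    status: str                      # ok | no-scaffolds | no-hits | insufficient-families
    candidates: list = field(default_factory=list)
    scaffolds: list = field(default_factory=list)   # surviving Scaffold objects
    n_pairs_scored: int = 0


def generate_filtered_scaffolds(model: GSG, phenotype: PhenotypeVector, n: int = 100,
                                temperature: float = 1.0, seed: int = 0,
                                rules: ScaffoldFilter | None = None) -> list[Scaffold]:
    """Sample ``n`` scaffolds from the generator, keep the chemically valid
    ones, deduplicate on canonical fragment SMILES, and apply the scaffold
    filter."""
    generated = model.generate(phenotype, n, temperature=temperature, seed=seed)
    seen: dict[str, Scaffold] = {}
    for g in generated:
        if not g.valid:
            continue
        try:
            sc = scaffold_from_smiles(g.smiles)
        except ValueError:
            continue
        seen.setdefault(sc.smiles, sc)
    return filter_scaffolds(list(seen.values()), rules=rules)


def _hits_by_scaffold(scaffolds: list[Scaffold], library: list[MoleculeRecord]
                      ) -> dict[str, list[MoleculeRecord]]:
    return {sc.smiles: screen_substructure(sc, library) for sc in scaffolds}


def _ranked(cands: list[ScreeningCandidate]) -> list[ScreeningCandidate]:
    return sorted(cands, key=lambda c: (-c.score, c.drugA.smiles, c.drugB.smiles))


def run_partner_screen(phenotype: PhenotypeVector, known_drug: MoleculeRecord,
                       library: list[MoleculeRecord], gsg_model: GSG, sdsp_model: SDSP,
                       cell: np.ndarray, cell_id: str = "", n_scaffolds: int = 100,
                       temperature: float = 1.0, seed: int = 0,
                       rules: ScaffoldFilter | None = None,
                       scaffolds: list[Scaffold] | None = None) -> ScreenResult:
    """``scaffolds`` overrides generation (e.g. curated scaffolds); otherwise
    they are sampled from ``gsg_model`` and filtered."""
    if scaffolds is None:
        scaffolds = generate_filtered_scaffolds(gsg_model, phenotype, n=n_scaffolds,
                                                temperature=temperature, seed=seed, rules=rules)
    if not scaffolds:
        return ScreenResult(status="no-scaffolds")
    hits = _hits_by_scaffold(scaffolds, library)
    provenance: dict[str, list[str]] = {}
    by_id: dict[str, MoleculeRecord] = {}
    for scaf_smiles, recs in hits.items():
        for rec in recs:
            by_id[rec.id] = rec
            provenance.setdefault(rec.id, []).append(scaf_smiles)
    if not by_id:
        return ScreenResult(status="no-hits", scaffolds=scaffolds)
    partners = [by_id[i] for i in sorted(by_id)]
    samples = [SynergySample(known_drug.smiles, p.smiles, cell, 0.0, cell_id)
               for p in partners]
    scores = sdsp_model.predict_batch(samples)
    cands = [ScreeningCandidate(known_drug, p, cell_id, float(s),
                                tuple(sorted(provenance[p.id])))
             for p, s in zip(partners, scores)]
    return ScreenResult(status="ok", candidates=_ranked(cands), scaffolds=scaffolds,
                        n_pairs_scored=len(cands))


def count_cross_scaffold_pairs(hit_counts: list[int]) -> int:
    """Closed form for disjoint hit groups: sum over i<j of h_i * h_j."""
    return sum(a * b for a, b in combinations(hit_counts, 2))


def run_denovo_screen(phenotype: PhenotypeVector, library: list[MoleculeRecord],
                      gsg_model: GSG, sdsp_model: SDSP, cell: np.ndarray,
                      cell_id: str = "", n_scaffolds: int = 100, temperature: float = 1.0,
                      seed: int = 0, rules: ScaffoldFilter | None = None,
                      allow_same_scaffold: bool = False, max_pairs: int | None = None,
                      scaffolds: list[Scaffold] | None = None) -> ScreenResult:
    """Pair library hits of different scaffolds and score every pair.

    ``max_pairs`` caps the number of scored pairs (deterministic order)
    for very large screens; ``scaffolds`` overrides generation.
    """
    if scaffolds is None:
        scaffolds = generate_filtered_scaffolds(gsg_model, phenotype, n=n_scaffolds,
                                                temperature=temperature, seed=seed, rules=rules)
    if not scaffolds:
        return ScreenResult(status="no-scaffolds")
    hits = _hits_by_scaffold(scaffolds, library)
    groups = [(smi, recs) for smi, recs in sorted(hits.items()) if recs]
    if len(groups) < 2 and not allow_same_scaffold:
        return ScreenResult(status="insufficient-families", scaffolds=scaffolds)
    membership: dict[str, set] = {}
    by_id: dict[str, MoleculeRecord] = {}
    for smi, recs in groups:
        for rec in recs:
            by_id[rec.id] = rec
            membership.setdefault(rec.id, set()).add(smi)
    pairs: dict[tuple, tuple] = {}
    ids = sorted(by_id)
    for ia, ib in combinations(ids, 2):
        # cross-scaffold rule: the pair must realise two *different* scaffolds,
        # i.e. some scaffold i of one drug and j of the other with i != j; this
        # only fails when both drugs match exactly the same single scaffold
        ma, mb = membership[ia], membership[ib]
        if not allow_same_scaffold and ma == mb and len(ma) == 1:
            continue
        a, b = sorted((by_id[ia], by_id[ib]), key=lambda r: r.smiles)
        pairs[(a.smiles, b.smiles)] = (a, b, tuple(sorted(ma | mb)))
    items = [pairs[k] for k in sorted(pairs)]
    if max_pairs is not None:
        items = items[:max_pairs]
    if not items:
        return ScreenResult(status="insufficient-families", scaffolds=scaffolds)
    samples = [SynergySample(a.smiles, b.smiles, cell, 0.0, cell_id) for a, b, _ in items]
    scores = sdsp_model.predict_batch(samples)
    cands = [ScreeningCandidate(a, b, cell_id, float(s), prov)
             for (a, b, prov), s in zip(items, scores)]
    return ScreenResult(status="ok", candidates=_ranked(cands), scaffolds=scaffolds,
                        n_pairs_scored=len(cands))


def select_candidates(candidates: list[ScreeningCandidate], threshold: float = 5.0,
                      synergistic_only: bool = False) -> list[ScreeningCandidate]:
    """Potent pairs: score >= threshold or (unless synergistic_only)
    score <= -threshold; the boundary is inclusive."""
    if synergistic_only:
        return [c for c in candidates if c.score >= threshold]
    return [c for c in candidates if c.score >= threshold or c.score <= -threshold]
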