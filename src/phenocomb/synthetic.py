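"""Synthetic data generators: every model in the package can be trained and
exercised end-to-end from these, with no external download.

The generators emulate the *shape* of the real inputs, not their biology:

* ``gen_phenotype_scaffold_pairs`` — K phenotype classes, each defined by a
  disjoint block of informative landmark genes with fixed signs, paired
  with decorated variants of one scaffold family per class.  The class is
  decodable from the vector by construction (up to the noise rate), so a
  conditional generator trained on these pairs can be probed for whether it
  routes phenotype information into scaffold structure.
* ``gen_cell_profiles`` / ``gen_synergy_dataset`` — cell lines carry a
  class-specific basal-expression block; a synergy table draws a Gaussian
  Bliss-score background N(-0.55, 5.45^2) and adds a deterministic bonus
  (+12) or penalty (-12) when the (drug family, drug family, cell class)
  triple matches a planted rule, plus unit observation noise.  The planted
  rules are symmetric in drug order.
* ``gen_decorated_library`` — compounds built by filling every scaffold
  attachment point with small substituents (guaranteed substructure hits),
  plus scaffold-free decoys (verified non-hits).
* ``gen_target_profiles`` — labelled target-set fixtures covering every
  mechanism class.

Every generator is a pure function of (spec, seed) and returns a manifest
describing how to regenerate its output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from rdkit import Chem

from .chem import clean_structure, scaffold_from_smiles, screen_substructure
from .mechanism import TargetProfile
from .phenotype import N_LANDMARK, ExpressionProfile, PhenotypeVector, landmark_gene_ids
from .sdsp import SynergySample

__all__ = [
    "SyntheticSpec", "DEFAULT_FAMILIES", "gen_phenotype_scaffold_pairs",
    "gen_cell_profiles", "gen_synergy_dataset", "gen_decorated_library",
    "gen_target_profiles", "decorate_scaffold", "scaffold_variant",
]

# ring systems chosen to be fast to substructure-match and mutually distinct
# under Morgan/Tanimoto; all pass the default scaffold filter
DEFAULT_FAMILIES = (
    "*c1ccc(*)cc1",        # benzene, para
    "*c1ccc2[nH]ccc2c1",   # indole
    "*c1ccnc(*)c1",        # pyridine
    "*C1CCN(*)CC1",        # piperidine
    "*c1cnc2ccccc2c1",     # quinoline
    "*C1COC(*)CN1",        # morpholine
    "*c1ccc2ccccc2c1",     # naphthalene
    "*c1ncc(*)cn1",        # pyrimidine
)

_SUBSTITUENTS = ("C", "CC", "CCC", "OC", "N", "F", "Cl", "CO")
_DECOY_ATOMS = ("C", "C", "C", "O", "N")


@dataclass
class SyntheticSpec:
    n_classes: int = 3
    genes_per_class: int = 60
    noise_rate: float = 0.02        # per-gene probability of a random flip
    pairs_per_class: int = 200
    scaffold_families: tuple = DEFAULT_FAMILIES
    library_size: int = 550
    decoy_fraction: float = 0.5
    family_weights: tuple | None = None  # relative planted-compound frequency per family
    n_genes: int = N_LANDMARK
    synergy_bonus: float = 12.0
    antagonism_penalty: float = -12.0
    background_mean: float = -0.55
    background_sd: float = 5.45
    observation_noise_sd: float = 1.0
    rule_fraction: float = 0.5      # fraction of synergy samples drawn from planted rules
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 phenotype classes")
        if len(self.scaffold_families) < self.n_classes:
            raise ValueError("fewer scaffold families than classes")
        if self.n_classes * self.genes_per_class > self.n_genes:
            raise ValueError("informative gene blocks must fit in the landmark set")

    def manifest(self, what: str) -> dict:
        m = asdict(self)
        m["scaffold_families"] = list(m["scaffold_families"])
        m["generator"] = what
        return m

    def planted_rules(self) -> list[tuple[int, int, int, float]]:
        """(familyA, familyB, cell_class, effect) triples; symmetric in the
        two families.  Class k is synergistic for (k, k+1 mod K) and
        antagonistic for (k, k+2 mod K) pairs (K = number of classes)."""
        K = self.n_classes
        rules = []
        for k in range(K):
            rules.append((k, (k + 1) % K, k, self.synergy_bonus))
            if K > 2:
                rules.append((k, (k + 2) % K, k, self.antagonism_penalty))
        return rules


# ----------------------------------------------------------------- chemistry
def decorate_scaffold(family_smiles: str, rng: np.random.Generator,
                      substituents: tuple = _SUBSTITUENTS, max_tries: int = 20,
                      ring_substitution: float = 0.5) -> str:
    """Fill every ``*`` attachment point with a small substituent; the result
    is a full molecule guaranteed to contain the family as a substructure.
    With probability ``ring_substitution`` the core also gains extra ring
    substituents first, which widens the space of distinct library members."""
    dummy = Chem.MolFromSmarts("[#0]")
    core = family_smiles
    for _ in range(max_tries):
        if rng.random() < ring_substitution:
            core = scaffold_variant(family_smiles, rng, max_extra=2)
        mol = Chem.MolFromSmiles(core)
        try:
            while mol.HasSubstructMatch(dummy):
                sub = Chem.MolFromSmiles(str(rng.choice(substituents)))
                mol = Chem.ReplaceSubstructs(mol, dummy, sub, replaceAll=False)[0]
                Chem.SanitizeMol(mol)
            return Chem.MolToSmiles(mol)
        except Exception:
            continue
    raise RuntimeError(f"could not decorate {family_smiles!r} with a valid molecule")


def scaffold_variant(family_smiles: str, rng: np.random.Generator,
                     max_extra: int = 2, max_tries: int = 20) -> str:
    """A within-family scaffold variant: the attachment points are kept and
    up to ``max_extra`` ring CH positions gain a small substituent."""
    for _ in range(max_tries):
        mol = Chem.RWMol(Chem.MolFromSmiles(family_smiles))
        n_extra = int(rng.integers(0, max_extra + 1))
        try:
            for _ in range(n_extra):
                cands = [a.GetIdx() for a in mol.GetAtoms()
                         if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0 and a.IsInRing()]
                if not cands:
                    break
                tgt = int(rng.choice(cands))
                frag = Chem.MolFromSmiles(str(rng.choice(("C", "F", "Cl", "N", "OC"))))
                start = mol.GetNumAtoms()
                mol = Chem.RWMol(Chem.CombineMols(mol, frag))
                mol.AddBond(tgt, start, Chem.BondType.SINGLE)
            out = mol.GetMol()
            Chem.SanitizeMol(out)
            return Chem.MolToSmiles(out)
        except Exception:
            continue
    return Chem.MolToSmiles(Chem.MolFromSmiles(family_smiles))


def _decoy(rng: np.random.Generator) -> str:
    """A scaffold-free molecule: a random acyclic branched skeleton of
    carbons with occasional chain heteroatoms.  Being acyclic, it cannot
    contain any of the ring-based scaffold families."""
    n = int(rng.integers(6, 16))

    def grow(budget: int) -> str:
        if budget <= 0:
            return ""
        atom = str(rng.choice(_DECOY_ATOMS))
        budget -= 1
        if budget and rng.random() < 0.3:  # branch
            left = int(rng.integers(1, budget + 1))
            branch = grow(left)
            rest = grow(budget - left)
            return f"{atom}({branch}){rest}" if branch else atom + rest
        return atom + grow(budget)

    # heteroatom adjacencies are chemically fine here (ethers/amines); the
    # caller re-verifies every decoy against the family scaffolds anyway
    return "C" + grow(n - 1)


# ---------------------------------------------------------------- phenotypes
def _class_signature(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """(K, n_genes) matrix of class-defining {-1,0,1} patterns; class k is
    nonzero exactly on its own gene block (disjoint across classes)."""
    sig = np.zeros((spec.n_classes, spec.n_genes), dtype=int)
    for k in range(spec.n_classes):
        block = slice(k * spec.genes_per_class, (k + 1) * spec.genes_per_class)
        sig[k, block] = rng.choice((-1, 1), size=spec.genes_per_class)
    return sig


def _noisy_vector(base: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    vals = base.copy()
    flips = rng.random(spec.n_genes) < spec.noise_rate
    vals[flips] = rng.choice((-1, 0, 1), size=int(flips.sum()))
    return vals


def gen_phenotype_scaffold_pairs(spec: SyntheticSpec, seed: int | None = None):
    """Planted phenotype -> scaffold-family training pairs.

    Returns (pairs, labels, manifest) where pairs are (PhenotypeVector,
    scaffold SMILES) and labels give the class index of each pair.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gene_ids = tuple(landmark_gene_ids(spec.n_genes))
    sig = _class_signature(spec, rng)
    pairs, labels = [], []
    for k in range(spec.n_classes):
        fam = spec.scaffold_families[k]
        for _ in range(spec.pairs_per_class):
            vec = PhenotypeVector(gene_ids, _noisy_vector(sig[k], spec, rng))
            pairs.append((vec, scaffold_variant(fam, rng)))
            labels.append(k)
    return pairs, np.array(labels), spec.manifest("phenotype_scaffold_pairs")


def gen_cell_profiles(spec: SyntheticSpec, seed: int | None = None):
    """One basal expression profile per phenotype class: baseline uniform
    noise in [0, 0.4] with the class's informative block raised to ~0.9."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 7)
    gene_ids = tuple(landmark_gene_ids(spec.n_genes))
    profiles = {}
    for k in range(spec.n_classes):
        vals = rng.uniform(0.0, 0.4, spec.n_genes)
        block = slice(k * spec.genes_per_class, (k + 1) * spec.genes_per_class)
        vals[block] = rng.uniform(0.8, 1.0, spec.genes_per_class)
        profiles[f"CELL{k}"] = (ExpressionProfile(gene_ids, vals), k)
    return profiles, spec.manifest("cell_profiles")


# -------------------------------------------------------------- synergy table
def true_synergy_effect(famA: int | None, famB: int | None, cell_class: int,
                        spec: SyntheticSpec) -> float:
    """Deterministic planted effect for a (family, family, cell) triple;
    0 for background pairs.  Symmetric in the two families."""
    for a, b, c, eff in spec.planted_rules():
        if c == cell_class and {a, b} == {famA, famB}:
            return eff
    return 0.0


def gen_synergy_dataset(spec: SyntheticSpec, n_samples: int = 5000, seed: int | None = None):
    """Ground-truth synergy table.

    Returns (samples, truths, manifest): ``samples`` are SynergySamples with
    observed scores; ``truths`` records (familyA, familyB, cell_class,
    deterministic effect) per sample for oracle checks.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    # the cell panel is a fixed property of the spec, not of the draw seed:
    # train/test tables and downstream screens must share the same profiles
    profiles, _ = gen_cell_profiles(spec)
    cells = [(cid, prof.values, k) for cid, (prof, k) in sorted(profiles.items())]
    rules = spec.planted_rules()
    samples, truths = [], []
    for _ in range(n_samples):
        if rng.random() < spec.rule_fraction:
            famA, famB, cls, _eff = rules[int(rng.integers(len(rules)))]
            if rng.random() < 0.5:
                famA, famB = famB, famA
            cid, cvals, _k = cells[cls]
        else:
            famA = int(rng.integers(spec.n_classes))
            famB = int(rng.integers(spec.n_classes))
            cid, cvals, cls = cells[int(rng.integers(len(cells)))]
        effect = true_synergy_effect(famA, famB, cls, spec)
        score = (rng.normal(spec.background_mean, spec.background_sd)
                 + effect + rng.normal(0.0, spec.observation_noise_sd))
        samples.append(SynergySample(
            drugA=decorate_scaffold(spec.scaffold_families[famA], rng),
            drugB=decorate_scaffold(spec.scaffold_families[famB], rng),
            cell=cvals, score=float(score), cell_id=cid,
        ))
        truths.append((famA, famB, cls, effect))
    return samples, truths, spec.manifest("synergy_dataset")


# ------------------------------------------------------------------- library
def gen_decorated_library(spec: SyntheticSpec, seed: int | None = None):
    """Compound library with planted scaffold instances plus verified
    scaffold-free decoys.  Returns (records, family_of, manifest) where
    ``family_of`` maps record id -> family index (-1 for decoys)."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 13)
    families = [scaffold_from_smiles(s) for s in spec.scaffold_families]
    n_decoys = int(round(spec.library_size * spec.decoy_fraction))
    n_planted = spec.library_size - n_decoys
    if spec.family_weights is not None:
        w = np.asarray(spec.family_weights, dtype=float)
        if len(w) != len(families) or (w < 0).any() or w.sum() == 0:
            raise ValueError("family_weights must be non-negative, one per family")
        fam_seq = rng.choice(len(families), size=4 * n_planted + 16, p=w / w.sum())
    else:
        fam_seq = np.arange(4 * n_planted + 16) % len(families)
    records, family_of = [], {}
    seen = set()
    i = 0
    n_kept_planted = 0
    while n_kept_planted < n_planted:
        if i > 200 * n_planted:
            raise RuntimeError("library decoration stalled; enlarge the decoration space")
        fam = int(fam_seq[i % len(fam_seq)])
        smi = decorate_scaffold(spec.scaffold_families[fam], rng)
        rec = clean_structure(smi, mol_id=f"LIB{i:05d}")
        i += 1
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        records.append(rec)
        family_of[rec.id] = fam
        n_kept_planted += 1
    attempts = 0
    while len(records) < spec.library_size:
        attempts += 1
        if attempts > 200 * spec.library_size:
            raise RuntimeError("decoy generation stalled; loosen the spec")
        smi = _decoy(rng)
        try:
            rec = clean_structure(smi, mol_id=f"DEC{i:05d}")
        except Exception:
            i += 1
            continue
        i += 1
        if rec.smiles in seen:
            continue
        # verification pass: a decoy must not contain any family scaffold
        if any(screen_substructure(f, [rec]) for f in families):
            continue
        seen.add(rec.smiles)
        records.append(rec)
        family_of[rec.id] = -1
    return records, family_of, spec.manifest("decorated_library")


# ---------------------------------------------------------------- target sets
def gen_target_profiles(spec: SyntheticSpec, seed: int | None = None):
    """Labelled target-profile fixtures covering every overlap type (a/b/c),
    every specificity type (d/e/f) and the unclassified gap, each at least
    twice.  Returns (cases, manifest); cases are dicts with profiles A/B and
    expected labels."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 29)
    universe = [f"P{i:04d}" for i in range(200)]

    def pick(n, exclude=frozenset()):
        pool = [p for p in universe if p not in exclude]
        return frozenset(rng.choice(pool, size=n, replace=False))

    cases = []
    for rep in range(2):
        # type a + d: two targeted drugs, disjoint targets
        ta = pick(5)
        cases.append(dict(A=ta, B=pick(6, ta), overlap="a", specificity="d"))
        # type c + d: identical small sets
        tc = pick(4)
        cases.append(dict(A=tc, B=tc, overlap="c", specificity="d"))
        # type b + f(mixed): targeted subset of a wide-spectrum drug
        wide = pick(60)
        sub = frozenset(list(wide)[:8])
        cases.append(dict(A=wide, B=sub, overlap="b", specificity="f"))
        # type a + e: two wide-spectrum drugs, small overlap
        w1 = pick(60)
        w2 = pick(55, w1)
        cases.append(dict(A=w1, B=w2, overlap="a", specificity="e"))
        # unclassified: intermediate target count (11-50)
        mid = pick(30)
        cases.append(dict(A=mid, B=pick(5, mid), overlap="a", specificity="unclassified"))
    out = []
    for i, c in enumerate(cases):
        out.append(dict(
            A=TargetProfile(f"DRUGA{i}", c["A"]),
            B=TargetProfile(f"DRUGB{i}", c["B"]),
            overlap=c["overlap"], specificity=c["specificity"],
        ))
    return out, spec.manifest("target_profiles")
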