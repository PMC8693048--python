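"""SMILES handling: tokenization, cleaning, randomization, RECAP scaffold
extraction and filtering, Morgan/Tanimoto similarity, and substructure
screening.

The token alphabet is deliberately narrow: 25 SMILES characters covering
common organic chemistry (C, H, O, N, F, S, Cl, Br, aromatic c/n/o/s,
charges, ring-closure digits 1-6, bond symbols and brackets), plus ``*`` for
scaffold attachment points and ``<`` / ``>`` as sequence start/stop markers
for the recurrent models.  Compounds that need anything outside this
alphabet are rejected during cleaning, which keeps every downstream model
input in-vocabulary by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, Recap
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "TokenVocabulary", "VOCAB", "MoleculeRecord", "Scaffold", "ScaffoldFilter",
    "TokenizationError", "StructureRejected",
    "tokenize_smiles", "detokenize", "clean_structure", "clean_library",
    "randomize_smiles", "recap_scaffolds", "filter_scaffolds",
    "morgan_fingerprint", "tanimoto", "screen_substructure", "scaffold_from_smiles",
]

# the 25 chemistry characters; two-character halogens listed first so the
# greedy tokenizer prefers them over C + l / B + r
_CHEM_TOKENS = [
    "Cl", "Br", "C", "H", "O", "N", "F", "S", "c", "n", "o", "s",
    "+", "-", "1", "2", "3", "4", "5", "6", "=", "#", "[", "]", "(", ")",
]
PAD, BOS, EOS, BREAKPOINT = "_", "<", ">", "*"


class TokenizationError(ValueError):
    def __init__(self, smiles: str, char: str, pos: int):
        self.char, self.pos = char, pos
        super().__init__(f"character {char!r} at position {pos} of {smiles!r} is not in the vocabulary")


class TokenVocabulary:
    """Bijective token <-> index map with greedy longest-match tokenization."""

    def __init__(self, chem_tokens: list[str] | None = None):
        chem = list(chem_tokens) if chem_tokens is not None else list(_CHEM_TOKENS)
        self.tokens: list[str] = [PAD, BOS, EOS, BREAKPOINT] + chem
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens")
        self._multi = sorted((t for t in self.tokens if len(t) > 1), key=len, reverse=True)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def tokenize(self, s: str) -> list[str]:
        if not s:
            raise ValueError("empty SMILES")
        out: list[str] = []
        i = 0
        while i < len(s):
            for m in self._multi:
                if s.startswith(m, i):
                    out.append(m)
                    i += len(m)
                    break
            else:
                ch = s[i]
                if ch not in self.index:
                    raise TokenizationError(s, ch, i)
                out.append(ch)
                i += 1
        return out

    def encode(self, s: str) -> list[int]:
        return [self.index[t] for t in self.tokenize(s)]

    def decode(self, ids) -> str:
        """Ids back to a SMILES body; start/stop/padding markers are dropped."""
        skip = {self.index[PAD], self.index[BOS], self.index[EOS]}
        return "".join(self.tokens[i] for i in ids if i not in skip)


VOCAB = TokenVocabulary()


def tokenize_smiles(s: str, vocab: TokenVocabulary = VOCAB) -> list[str]:
    return vocab.tokenize(s)


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


# --------------------------------------------------------------------- records
@dataclass(frozen=True)
class MoleculeRecord:
    smiles: str
    id: str = ""
    length: int = 0

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparseable SMILES {self.smiles!r}")
        return m


@dataclass(frozen=True)
class Scaffold:
    """Ring-containing fragment with ``*`` attachment points."""

    smiles: str
    parent_id: str = ""
    n_rings: int = 0
    n_heavy: int = 0
    n_hetero: int = 0
    n_breakpoints: int = 0

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparseable scaffold {self.smiles!r}")
        return m


def scaffold_from_smiles(smiles: str, parent_id: str = "") -> Scaffold:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"unparseable scaffold {smiles!r}")
    # heavy atoms / heteroatoms exclude the * dummies (atomic number 0)
    n_break = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0)
    n_heavy = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 1)
    n_het = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() not in (0, 1, 6))
    return Scaffold(
        smiles=Chem.MolToSmiles(m),
        parent_id=parent_id,
        n_rings=m.GetRingInfo().NumRings(),
        n_heavy=n_heavy,
        n_hetero=n_het,
        n_breakpoints=n_break,
    )


# -------------------------------------------------------------------- cleaning
class StructureRejected(ValueError):
    """Raised when a raw structure fails cleaning; ``reason`` is one of
    unparseable / too-long / bad-token / inorganic."""

    def __init__(self, smiles: str, reason: str):
        self.reason = reason
        super().__init__(f"{smiles!r} rejected: {reason}")


def clean_structure(raw: str, mol_id: str = "", max_tokens: int = 100,
                    vocab: TokenVocabulary = VOCAB) -> MoleculeRecord:
    """Canonicalize a raw SMILES: keep the largest organic component, strip
    salts and stereochemistry, enforce the token alphabet and a length cap."""
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureRejected(raw, "unparseable")
    frags = Chem.GetMolFrags(mol, asMols=True)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        raise StructureRejected(raw, "inorganic")
    mol = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    Chem.RemoveStereochemistry(mol)
    smiles = Chem.MolToSmiles(mol)
    try:
        tokens = vocab.tokenize(smiles)
    except TokenizationError as exc:
        raise StructureRejected(raw, "bad-token") from exc
    if len(tokens) > max_tokens:
        raise StructureRejected(raw, "too-long")
    return MoleculeRecord(smiles=smiles, id=mol_id, length=len(tokens))


def clean_library(raw: list[tuple[str, str]], **kwargs) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Clean (id, smiles) pairs; duplicates collapse on canonical SMILES.
    Returns (records, rejections) where rejections are (id, reason)."""
    seen: dict[str, MoleculeRecord] = {}
    rejected: list[tuple[str, str]] = []
    for mol_id, smi in raw:
        try:
            rec = clean_structure(smi, mol_id=mol_id, **kwargs)
        except StructureRejected as exc:
            rejected.append((mol_id, exc.reason))
            continue
        seen.setdefault(rec.smiles, rec)
    return list(seen.values()), rejected


def randomize_smiles(record: MoleculeRecord | str, seed: int) -> str:
    """A random valid SMILES rendering of the molecule (atom renumbering);
    deterministic for a fixed (molecule, seed)."""
    import numpy as np

    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(mol.GetNumAtoms()).tolist()
    mol = Chem.RenumberAtoms(mol, [int(i) for i in perm])
    return Chem.MolToSmiles(mol, canonical=False)


# ----------------------------------------------------------------- scaffolding
def recap_scaffolds(record: MoleculeRecord) -> list[Scaffold]:
    """All RECAP fragments of the molecule (every node of the decomposition
    tree), ordered by canonical SMILES.  A molecule with no cleavable bond
    yields itself as the sole candidate fragment."""
    mol = record.mol()
    tree = Recap.RecapDecompose(mol)
    frag_smiles: set[str] = set()
    stack = list(tree.children.values())
    while stack:
        node = stack.pop()
        frag_smiles.add(node.smiles)
        stack.extend(node.children.values())
    if not frag_smiles:
        frag_smiles = {Chem.MolToSmiles(mol)}
    out = []
    for smi in sorted(frag_smiles):
        try:
            out.append(scaffold_from_smiles(smi, parent_id=record.id))
        except ValueError:
            continue
    return out


@dataclass(frozen=True)
class ScaffoldFilter:
    """Fragment-likeness ("rule-of-three") bounds plus ring/complexity rules.

    A fragment is retained iff it satisfies the property bounds, contains at
    least one ring, and — when it has exactly one ring and exactly one
    attachment point — is complex enough (more than ``min_heavy_single``
    heavy atoms or more than ``min_hetero_single`` heteroatoms).
    """

    max_mw: float = 300.0
    max_logp: float = 3.0
    max_hbd: int = 3
    max_hba: int = 3
    max_rotatable: int = 3
    min_heavy_single: int = 10        # strict: need n_heavy > this
    min_hetero_single: int = 2        # strict by default; see hetero_inclusive
    hetero_inclusive: bool = False    # True reads "two heteroatoms" as >= 2

    def passes(self, scaffold: Scaffold) -> bool:
        m = scaffold.mol()
        if scaffold.n_rings < 1:
            return False
        if (Descriptors.MolWt(m) > self.max_mw
                or Crippen.MolLogP(m) > self.max_logp
                or Lipinski.NumHDonors(m) > self.max_hbd
                or Lipinski.NumHAcceptors(m) > self.max_hba
                or Lipinski.NumRotatableBonds(m) > self.max_rotatable):
            return False
        if scaffold.n_rings == 1 and scaffold.n_breakpoints == 1:
            hetero_ok = (scaffold.n_hetero >= self.min_hetero_single
                         if self.hetero_inclusive
                         else scaffold.n_hetero > self.min_hetero_single)
            if not (scaffold.n_heavy > self.min_heavy_single or hetero_ok):
                return False
        return True


def filter_scaffolds(frags: list[Scaffold], rules: ScaffoldFilter | None = None) -> list[Scaffold]:
    rules = rules or ScaffoldFilter()
    kept = [f for f in frags if rules.passes(f)]
    return sorted(kept, key=lambda s: s.smiles)


# ---------------------------------------------------------------- fingerprints
_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprint(record: MoleculeRecord | Scaffold):
    return _MORGAN.GetFingerprint(record.mol())


def tanimoto(a: MoleculeRecord | Scaffold, b: MoleculeRecord | Scaffold) -> float:
    return DataStructs.TanimotoSimilarity(morgan_fingerprint(a), morgan_fingerprint(b))


# ------------------------------------------------------------------- screening
def screen_substructure(scaffold: Scaffold, library: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Molecules of ``library`` containing the scaffold as a substructure.

    ``*`` attachment points act as wildcards (any atom), and additional
    substitution elsewhere on the core is allowed: a scaffold is a core to
    be decorated, not an exact match.  Order follows the library.
    """
    query = Chem.MolFromSmiles(scaffold.smiles)
    if query is None:
        raise ValueError(f"unparseable scaffold {scaffold.smiles!r}")
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeDummiesQueries = True  # '*' matches any atom, one per breakpoint
    query = Chem.AdjustQueryProperties(query, params)
    hits = []
    for rec in library:
        if rec.mol().HasSubstructMatch(query):
            hits.append(rec)
    return hits
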