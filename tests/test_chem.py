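"""SMILES handling: tokenization, cleaning, randomization, RECAP
fragmentation, scaffold filtering, similarity and substructure screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from phenocomb.chem import (VOCAB, MoleculeRecord, Scaffold, ScaffoldFilter,
                            StructureRejected, TokenizationError, clean_library,
                            clean_structure, filter_scaffolds, randomize_smiles,
                            recap_scaffolds, scaffold_from_smiles,
                            screen_substructure, tanimoto, tokenize_smiles)

# ------------------------------------------------------------------- tokenizer

@pytest.mark.parametrize("smiles, expected", [
    ("CCO", ["C", "C", "O"]),
    ("CCl", ["C", "Cl"]),                      # greedy two-character match
    ("BrCBr", ["Br", "C", "Br"]),
    ("c1ccccc1", list("c1ccccc1")),
    ("C(=O)[O-]", ["C", "(", "=", "O", ")", "[", "O", "-", "]"]),
    ("*c1ccc(*)cc1", ["*", "c", "1", "c", "c", "c", "(", "*", ")", "c", "c", "1"]),
])
def test_tokenize_examples(smiles, expected):
    assert tokenize_smiles(smiles) == expected


def test_tokenize_rejects_unknown_character_with_position():
    with pytest.raises(TokenizationError) as exc:
        tokenize_smiles("CSi")  # Si is not in the alphabet; S then i fails
    assert exc.value.char == "i" and exc.value.pos == 2


def test_tokenize_empty_rejected():
    with pytest.raises(ValueError):
        tokenize_smiles("")


@given(st.lists(st.sampled_from(VOCAB.tokens[4:]), min_size=1, max_size=30))
@settings(max_examples=200, deadline=None)
def test_tokenize_detokenize_roundtrip(tokens):
    s = "".join(tokens)
    assert "".join(tokenize_smiles(s)) == s


def test_vocabulary_bijection():
    assert len(set(VOCAB.index.values())) == len(VOCAB.tokens)
    for t, i in VOCAB.index.items():
        assert VOCAB.tokens[i] == t


# -------------------------------------------------------------------- cleaning

def test_clean_strips_salt_and_stereo():
    rec = clean_structure("C[C@H](N)C(=O)O.Cl")
    assert rec.smiles == Chem.CanonSmiles("CC(N)C(=O)O")
    assert "@" not in rec.smiles and "Cl" not in rec.smiles


def test_clean_identity_on_clean_input():
    assert clean_structure("CCO").smiles == "CCO"


def test_clean_rejections():
    with pytest.raises(StructureRejected) as exc:
        clean_structure("C" * 150)
    assert exc.value.reason == "too-long"
    with pytest.raises(StructureRejected) as exc:
        clean_structure("not a molecule((")
    assert exc.value.reason == "unparseable"
    with pytest.raises(StructureRejected) as exc:
        clean_structure("[Na+].[Cl-]")
    assert exc.value.reason == "inorganic"
    with pytest.raises(StructureRejected) as exc:
        clean_structure("C[Si](C)C")  # silicon is outside the alphabet
    assert exc.value.reason == "bad-token"


def test_clean_library_collapses_duplicates():
    recs, rejected = clean_library([("a", "OCC"), ("b", "CCO"), ("c", "CC(C)=O"), ("d", "QQ")])
    assert [r.smiles for r in recs] == ["CCO", "CC(C)=O"]
    assert rejected == [("d", "unparseable")]


# --------------------------------------------------------------- randomization

def test_randomize_smiles_is_seeded_and_isomorphic():
    rec = MoleculeRecord("Oc1ccccc1")
    outs = {randomize_smiles(rec, seed) for seed in range(20)}
    assert len(outs) >= 2
    for s in outs:
        assert Chem.CanonSmiles(s) == Chem.CanonSmiles("Oc1ccccc1")
    assert randomize_smiles(rec, 7) == randomize_smiles(rec, 7)


def test_randomize_single_atom_is_fixed():
    assert randomize_smiles(MoleculeRecord("C"), 3) == "C"


# ----------------------------------------------------------------------- RECAP

def test_recap_cleaves_amide_bond():
    frags = recap_scaffolds(MoleculeRecord("CNC(=O)c1ccccc1", id="benzamide"))
    smiles = {f.smiles for f in frags}
    assert Chem.CanonSmiles("*C(=O)c1ccccc1") in {Chem.CanonSmiles(s) for s in smiles}
    assert all(f.parent_id == "benzamide" for f in frags)


def test_recap_no_cleavable_bond_returns_molecule():
    frags = recap_scaffolds(MoleculeRecord("C1CCCCC1"))
    assert [f.smiles for f in frags] == [Chem.CanonSmiles("C1CCCCC1")]


def test_recap_acyclic_fragment_dies_in_filter():
    frags = recap_scaffolds(MoleculeRecord("CC"))
    assert filter_scaffolds(frags) == []


def test_recap_ordering_deterministic():
    rec = MoleculeRecord("CNC(=O)c1ccc(OC(=O)CN)cc1")
    a = [f.smiles for f in recap_scaffolds(rec)]
    b = [f.smiles for f in recap_scaffolds(rec)]
    assert a == b == sorted(a)


# ------------------------------------------------------------ scaffold filter

def brute_force_filter(frags, rules: ScaffoldFilter):
    """Literal rule-by-rule oracle, written independently of the library
    implementation: rule-of-three property bounds, ring presence, and the
    single-ring/single-breakpoint complexity rule."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    kept = []
    for f in frags:
        m = Chem.MolFromSmiles(f.smiles)
        props_ok = (Descriptors.MolWt(m) <= rules.max_mw
                    and Crippen.MolLogP(m) <= rules.max_logp
                    and Lipinski.NumHDonors(m) <= rules.max_hbd
                    and Lipinski.NumHAcceptors(m) <= rules.max_hba
                    and Lipinski.NumRotatableBonds(m) <= rules.max_rotatable)
        n_rings = m.GetRingInfo().NumRings()
        n_break = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0)
        n_heavy = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 1)
        n_het = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() not in (0, 1, 6))
        rule3_ok = True
        if n_rings == 1 and n_break == 1:
            rule3_ok = n_heavy > 10 or n_het > 2
        if props_ok and n_rings >= 1 and rule3_ok:
            kept.append(f.smiles)
    return sorted(kept)


HAND_BUILT_FRAGMENTS = [
    "*c1ccccc1",             # 1 ring, 1 breakpoint, 6 heavy, 0 hetero -> complexity rule
    "*c1ccc(*)cc1",          # 2 breakpoints -> complexity rule not triggered
    "*c1ccc2ncccc2c1",       # 2 rings
    "*CCCC",                 # acyclic
    "*c1cc(O)c(O)c(O)c1O",   # 4 donors -> property bounds
    "*C1CCN(*)CC1",
    "*c1ccc(CCCCCCCCCCCC)cc1",  # logP and rotatable bonds blown
    "*N1CCOCC1",             # 1 ring 1 breakpoint, 2 hetero (boundary case)
    "*n1ccnc1",              # imidazole: 1 ring 1 breakpoint 5 heavy 2 hetero
    "*c1nc(N)nc(N)n1",       # triazine: >2 hetero
    "C1CCCCC1",              # no breakpoint at all
    "*c1ccc2[nH]ccc2c1",
    "*C(=O)c1ccccc1",
    "*Cc1ccccc1CCCN",
    "*c1ccccc1C(=O)O",
    "*c1cnc2ccccc2c1",
    "*OC1CCOC1",             # THF ether
    "*c1ccsc1",              # thiophene
    "*C1CC1",                # cyclopropane
    "*c1ccc(Cl)cc1Cl",
]


def test_filter_agrees_with_rule_oracle():
    rules = ScaffoldFilter()
    frags = [scaffold_from_smiles(s) for s in HAND_BUILT_FRAGMENTS]
    got = sorted(f.smiles for f in filter_scaffolds(frags, rules))
    assert got == brute_force_filter(frags, rules)


def test_filter_examples():
    rejected = scaffold_from_smiles("*c1ccccc1")
    kept = scaffold_from_smiles("*c1ccc2ncccc2c1")
    out = {f.smiles for f in filter_scaffolds([rejected, kept])}
    assert rejected.smiles not in out and kept.smiles in out


def test_filter_order_invariant_and_idempotent():
    frags = [scaffold_from_smiles(s) for s in HAND_BUILT_FRAGMENTS]
    once = filter_scaffolds(frags)
    assert filter_scaffolds(list(reversed(frags))) == once
    assert filter_scaffolds(once) == once


def test_filter_hetero_boundary_configurable():
    # morpholine-like: exactly 2 heteroatoms, strict reading rejects it
    frag = scaffold_from_smiles("*N1CCOCC1")
    assert filter_scaffolds([frag], ScaffoldFilter(hetero_inclusive=False)) == []
    assert filter_scaffolds([frag], ScaffoldFilter(hetero_inclusive=True)) == [frag]


# ------------------------------------------------------------------ similarity

def test_tanimoto_self_and_symmetry():
    rng = np.random.default_rng(0)
    mols = [MoleculeRecord(s) for s in
            ["CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "C1CCNCC1", "CCOC(=O)C"]]
    for m in mols:
        assert tanimoto(m, m) == pytest.approx(1.0)
    for _ in range(20):
        a, b = rng.choice(len(mols), 2)
        assert tanimoto(mols[a], mols[b]) == pytest.approx(tanimoto(mols[b], mols[a]))


def test_tanimoto_disjoint_bits():
    assert tanimoto(MoleculeRecord("C"), MoleculeRecord("O")) == 0.0


# ------------------------------------------------------------------- screening

def test_screen_wildcard_matches_substituted_core():
    scaf = scaffold_from_smiles("*c1ccc(*)cc1")
    library = [MoleculeRecord("Cc1ccc(CC)cc1", id="para"),
               MoleculeRecord("Cc1ccccc1", id="mono"),
               MoleculeRecord("C1CCCCC1", id="ring")]
    hits = screen_substructure(scaf, library)
    assert [h.id for h in hits] == ["para"]


def test_screen_self_match():
    rec = MoleculeRecord(Chem.CanonSmiles("c1ccc2[nH]ccc2c1"))
    scaf = scaffold_from_smiles(rec.smiles)  # no breakpoints
    assert screen_substructure(scaf, [rec]) == [rec]


def test_screen_superset_closed():
    scaf = scaffold_from_smiles("*c1ccc(*)cc1")
    small = [MoleculeRecord("Cc1ccc(O)cc1", id="a")]
    big = small + [MoleculeRecord("CCc1ccc(N)cc1", id="b"), MoleculeRecord("CCCC", id="c")]
    hits_small = {h.id for h in screen_substructure(scaf, small)}
    hits_big = {h.id for h in screen_substructure(scaf, big)}
    assert hits_small <= hits_big
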