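"""Generator self-checks: separability, moments, round-trips, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from phenocomb.chem import (clean_structure, scaffold_from_smiles,
                            screen_substructure, tanimoto)
from phenocomb.mechanism import classify_overlap, classify_specificity
from phenocomb.synthetic import (DEFAULT_FAMILIES, SyntheticSpec,
                                 decorate_scaffold, gen_cell_profiles,
                                 gen_decorated_library,
                                 gen_phenotype_scaffold_pairs,
                                 gen_synergy_dataset, gen_target_profiles,
                                 scaffold_variant, true_synergy_effect)
from phenocomb.chem import ScaffoldFilter, filter_scaffolds

SMALL = SyntheticSpec(pairs_per_class=30, library_size=60, seed=0)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(n_classes=1)
    with pytest.raises(ValueError):
        SyntheticSpec(n_classes=4, scaffold_families=DEFAULT_FAMILIES[:2])
    with pytest.raises(ValueError):
        SyntheticSpec(n_classes=8, genes_per_class=200)


def test_default_families_pass_scaffold_filter():
    frags = [scaffold_from_smiles(s) for s in DEFAULT_FAMILIES]
    assert len(filter_scaffolds(frags, ScaffoldFilter())) == len(frags)


# -------------------------------------------------------------- phenotype pairs

def test_pair_counts_and_class_structure():
    pairs, labels, manifest = gen_phenotype_scaffold_pairs(SMALL)
    assert len(pairs) == SMALL.n_classes * SMALL.pairs_per_class
    assert manifest["generator"] == "phenotype_scaffold_pairs"
    # informative blocks are disjoint: class k is nonzero (mostly) on its block
    for k in range(SMALL.n_classes):
        vec = pairs[k * SMALL.pairs_per_class][0].values
        block = slice(k * SMALL.genes_per_class, (k + 1) * SMALL.genes_per_class)
        assert np.mean(np.asarray(vec[block]) != 0) > 0.8


def test_noise_free_vectors_perfectly_decodable():
    spec = replace(SMALL, noise_rate=0.0)
    pairs, labels, _ = gen_phenotype_scaffold_pairs(spec)
    for (vec, _), k in zip(pairs, labels):
        active = np.flatnonzero(np.asarray(vec.values))
        decoded = set(active // spec.genes_per_class)
        assert decoded == {k}


def test_within_class_similarity_exceeds_between():
    pairs, labels, _ = gen_phenotype_scaffold_pairs(SMALL)
    scaffolds = [scaffold_from_smiles(s) for _, s in pairs]
    rng = np.random.default_rng(0)
    within, between = [], []
    for _ in range(300):
        i, j = rng.integers(0, len(scaffolds), 2)
        if i == j:
            continue
        sim = tanimoto(scaffolds[i], scaffolds[j])
        (within if labels[i] == labels[j] else between).append(sim)
    assert np.mean(within) > np.mean(between)


def test_pair_generation_deterministic():
    a, la, _ = gen_phenotype_scaffold_pairs(SMALL)
    b, lb, _ = gen_phenotype_scaffold_pairs(SMALL)
    assert [s for _, s in a] == [s for _, s in b]
    assert np.array_equal(la, lb)
    assert all((x[0].values == y[0].values).all() for x, y in zip(a, b))


# ------------------------------------------------------------------- synergy

def test_background_moments_match_spec():
    # random (family, family, cell) triples can still hit a planted rule, so
    # the background check conditions on a zero deterministic effect
    spec = replace(SMALL, rule_fraction=0.0)
    samples, truths, _ = gen_synergy_dataset(spec, n_samples=20_000, seed=1)
    scores = np.array([s.score for s in samples])
    effects = np.array([eff for *_, eff in truths])
    bg = scores[effects == 0]
    assert len(bg) > 10_000
    assert abs(bg.mean() - spec.background_mean) < 0.2
    # observed sd includes the unit observation noise
    expected_sd = np.hypot(spec.background_sd, spec.observation_noise_sd)
    assert abs(bg.std() - expected_sd) < 0.2


def test_planted_effect_shifts_scores_by_bonus():
    samples, truths, _ = gen_synergy_dataset(SMALL, n_samples=6000, seed=2)
    scores = np.array([s.score for s in samples])
    effects = np.array([eff for *_, eff in truths])
    syn = scores[effects > 0].mean() - scores[effects == 0].mean()
    ant = scores[effects < 0].mean() - scores[effects == 0].mean()
    assert syn == pytest.approx(SMALL.synergy_bonus, abs=0.6)
    assert ant == pytest.approx(SMALL.antagonism_penalty, abs=0.6)


def test_planted_rules_symmetric_in_drug_order():
    for a in range(SMALL.n_classes):
        for b in range(SMALL.n_classes):
            for c in range(SMALL.n_classes):
                assert (true_synergy_effect(a, b, c, SMALL)
                        == true_synergy_effect(b, a, c, SMALL))


def test_cell_profiles_in_unit_interval_with_raised_block():
    profiles, _ = gen_cell_profiles(SMALL)
    assert len(profiles) == SMALL.n_classes
    for cid, (prof, k) in profiles.items():
        assert (prof.values >= 0).all() and (prof.values <= 1).all()
        block = slice(k * SMALL.genes_per_class, (k + 1) * SMALL.genes_per_class)
        assert prof.values[block].mean() > prof.values.mean()


# ------------------------------------------------------------------- library

def test_decorations_always_hit_their_family():
    rng = np.random.default_rng(3)
    fam = scaffold_from_smiles(DEFAULT_FAMILIES[0])
    recs = [clean_structure(decorate_scaffold(DEFAULT_FAMILIES[0], rng), str(i))
            for i in range(50)]
    hits = screen_substructure(fam, recs)
    assert len(hits) == 50


def test_library_round_trip_and_decoy_purity():
    records, family_of, _ = gen_decorated_library(SMALL)
    assert len(records) == SMALL.library_size
    families = [scaffold_from_smiles(s) for s in SMALL.scaffold_families]
    for rec in records:
        fam = family_of[rec.id]
        if fam >= 0:
            assert screen_substructure(families[fam], [rec]) == [rec]
        else:
            assert not any(screen_substructure(f, [rec]) for f in families)


def test_library_weights_bias_family_counts():
    spec = replace(SMALL, family_weights=(3, 1, 1, 0, 0, 0, 0, 0), library_size=80,
                   decoy_fraction=0.25)
    _, family_of, _ = gen_decorated_library(spec)
    counts = {f: sum(1 for v in family_of.values() if v == f) for f in (0, 1, 2)}
    assert counts[0] > counts[1] and counts[0] > counts[2]
    assert sum(1 for v in family_of.values() if v == 3) == 0


def test_library_deterministic():
    a, _, _ = gen_decorated_library(SMALL)
    b, _, _ = gen_decorated_library(SMALL)
    assert [r.smiles for r in a] == [r.smiles for r in b]


# -------------------------------------------------------------------- targets

def test_target_fixtures_close_the_loop():
    cases, _ = gen_target_profiles(SMALL)
    coverage = {}
    for case in cases:
        got_overlap = classify_overlap(case["A"], case["B"])[0]
        got_spec = classify_specificity(case["A"], case["B"])
        assert got_overlap == case["overlap"]
        assert got_spec == case["specificity"]
        coverage[case["overlap"]] = coverage.get(case["overlap"], 0) + 1
        coverage[case["specificity"]] = coverage.get(case["specificity"], 0) + 1
    for label in ("a", "b", "c", "d", "e", "f", "unclassified"):
        assert coverage.get(label, 0) >= 2, f"class {label} under-covered"
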