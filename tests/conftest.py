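"""Shared fixtures.

The trained models are expensive (minutes each on one CPU), so they are
session-scoped and shared between the behavioural tests and the acceptance
suite.  Everything is seeded; the desk-scale model sizes used here are
documented in docs/methods.md.
"""

from dataclasses import replace

import numpy as np
import pytest

from phenocomb.gsg import GSG, GSGConfig, train_gsg
from phenocomb.phenotype import PhenotypeVector, landmark_gene_ids
from phenocomb.sdsp import SDSPConfig, train_sdsp
from phenocomb.synthetic import (SyntheticSpec, gen_cell_profiles,
                                 gen_decorated_library,
                                 gen_phenotype_scaffold_pairs,
                                 gen_synergy_dataset, scaffold_variant)

GSG_CFG = GSGConfig(n_c=8, n_H=64, n_s=6, emb_dim=32, enc_window=12,
                    lr=5e-3, batch_size=32, seed=0)
SDSP_CFG = SDSPConfig(n_H=32, emb_dim=32, head_widths=(64, 32, 1),
                      lr=2e-3, batch_size=128, accumulate=1, seed=0)


@pytest.fixture(scope="session")
def bench_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=5)


@pytest.fixture(scope="session")
def toy_scaffolds(bench_spec):
    rng = np.random.default_rng(1)
    return [scaffold_variant(bench_spec.scaffold_families[i % 8], rng)
            for i in range(500)]


@pytest.fixture(scope="session")
def pretrained_gsg(toy_scaffolds):
    model, trace = train_gsg(toy_scaffolds, "pretrain", cfg=GSG_CFG, epochs=20, seed=0)
    model.pretrain_trace = trace
    return model


@pytest.fixture(scope="session")
def phenotype_pairs(bench_spec):
    pairs, labels, _ = gen_phenotype_scaffold_pairs(bench_spec)
    return pairs, labels


@pytest.fixture(scope="session")
def finetuned_gsg(pretrained_gsg, phenotype_pairs):
    pairs, _ = phenotype_pairs
    model = GSG(pretrained_gsg.cfg, pretrained_gsg.vocab)
    model.load_arrays([a.copy() for a in pretrained_gsg.state_arrays()])
    model, _ = train_gsg(pairs, "finetune", model=model, epochs=25, seed=0)
    return model


@pytest.fixture(scope="session")
def class_vectors(phenotype_pairs, bench_spec):
    """One representative phenotype vector per planted class."""
    pairs, labels = phenotype_pairs
    return {k: pairs[int(np.flatnonzero(labels == k)[0])][0]
            for k in range(bench_spec.n_classes)}


@pytest.fixture(scope="session")
def mixed_vector(class_vectors):
    """All class signatures superimposed (later classes win collisions;
    blocks are disjoint so none occur)."""
    vals = np.zeros(978, dtype=int)
    for vec in class_vectors.values():
        vals = np.where(vec.values != 0, vec.values, vals)
    return PhenotypeVector(tuple(landmark_gene_ids()), vals)


@pytest.fixture(scope="session")
def synergy_train(bench_spec):
    samples, _, _ = gen_synergy_dataset(bench_spec, n_samples=5000, seed=11)
    return samples


@pytest.fixture(scope="session")
def synergy_test(bench_spec):
    samples, truths, _ = gen_synergy_dataset(bench_spec, n_samples=1000, seed=12)
    return samples, truths


@pytest.fixture(scope="session")
def sdsp_model(synergy_train):
    model, trace = train_sdsp(synergy_train, SDSP_CFG, epochs=16, seed=0)
    model.train_trace = trace
    return model


@pytest.fixture(scope="session")
def sdsp_alpha0(synergy_train):
    model, _ = train_sdsp(synergy_train, replace(SDSP_CFG, alpha=0.0), epochs=16, seed=0)
    return model


@pytest.fixture(scope="session")
def sdsp_null(synergy_train):
    rng = np.random.default_rng(99)
    perm = rng.permutation(len(synergy_train))
    shuffled = [replace(s, score=synergy_train[j].score)
                for s, j in zip(synergy_train, perm)]
    model, _ = train_sdsp(shuffled, SDSP_CFG, epochs=6, seed=0)
    return model


@pytest.fixture(scope="session")
def screen_library(bench_spec):
    """Weighted library for the screening benchmark: the planted-rule
    families (0, 1) are rarer than family 2, plus 50% decoys."""
    spec = replace(bench_spec, library_size=250, decoy_fraction=0.5,
                   family_weights=(1, 1, 3, 0, 0, 0, 0, 0))
    records, family_of, _ = gen_decorated_library(spec)
    return records, family_of


@pytest.fixture(scope="session")
def cell_profiles(bench_spec):
    profiles, _ = gen_cell_profiles(bench_spec)
    return profiles
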