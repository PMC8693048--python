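"""Synergy predictor mechanics: augmentation, loss algebra, head symmetry,
metrics and FWHM stability (fast checks on tiny/untrained models)."""

from dataclasses import replace

import numpy as np
import pytest

from phenocomb.nn import Tensor
from phenocomb.sdsp import (SDSP, AugmentationConfig, PredictionPair, SDSPConfig,
                            SynergySample, augment_dataset, evaluate, fwhm,
                            fwhm_stability, sdsp_loss)

CELL = np.zeros(16)
TINY = SDSPConfig(n_H=8, emb_dim=6, head_widths=(8, 1), n_genes=16,
                  batch_size=64, seed=0)


def _samples(scores, rng=None):
    drugs = ["CCO", "c1ccccc1", "CCN", "CC(C)O", "c1ccncc1", "CCOC"]
    rng = rng or np.random.default_rng(0)
    return [SynergySample(str(rng.choice(drugs)), str(rng.choice(drugs)),
                          CELL, float(s)) for s in scores]


# ----------------------------------------------------------------- augmentation

def test_augment_p_equals_q_adds_almost_nothing():
    rng = np.random.default_rng(1)
    scores = rng.normal(-0.55, 5.45, 4000)
    cfg = AugmentationConfig(target_mean=-0.55, target_sd=5.45,
                             n_target_draws=4000, seed=2)
    out = augment_dataset(_samples(scores), cfg, mirror=False)
    assert (len(out) - 4000) / 4000 < 0.10  # only counting-noise additions


def test_augment_mirror_doubles_and_preserves_originals():
    scores = np.random.default_rng(3).normal(-0.55, 5.45, 500)
    samples = _samples(scores)
    cfg = AugmentationConfig(n_target_draws=500, seed=0)
    out = augment_dataset(samples, cfg)
    unmirrored = augment_dataset(samples, cfg, mirror=False)
    assert len(out) == 2 * len(unmirrored)
    assert unmirrored[: len(samples)] == samples  # originals kept verbatim


def test_augment_mirroring_makes_pairs_exchangeable():
    scores = np.random.default_rng(4).normal(0, 5, 300)
    out = augment_dataset(_samples(scores), AugmentationConfig(n_target_draws=300, seed=0))
    counts = {}
    for s in out:
        counts[(s.drugA, s.drugB)] = counts.get((s.drugA, s.drugB), 0) + 1
    for (a, b), n in counts.items():
        assert counts.get((b, a), 0) == n


def test_augment_validates():
    with pytest.raises(ValueError):
        augment_dataset([], AugmentationConfig())
    with pytest.raises(ValueError):
        augment_dataset(_samples([0.0]), AugmentationConfig(target_sd=-1))


def test_augment_strict_abs_diff_adds_more():
    scores = np.random.default_rng(5).normal(-0.55, 5.45, 2000)
    samples = _samples(scores)
    plain = augment_dataset(samples, AugmentationConfig(n_target_draws=2000, seed=1),
                            mirror=False)
    strict = augment_dataset(samples,
                             AugmentationConfig(n_target_draws=2000, seed=1,
                                                strict_abs_diff=True), mirror=False)
    assert len(strict) >= len(plain)


# ------------------------------------------------------------------------ loss

def test_loss_zero_at_exact_symmetric_fit():
    ab = Tensor(np.array([[2.0]]))
    ba = Tensor(np.array([[2.0]]))
    assert float(sdsp_loss(ab, ba, [2.0]).data) == 0.0


def test_loss_arithmetic_example():
    ab = Tensor(np.array([[1.0]]))
    ba = Tensor(np.array([[3.0]]))
    # final = 2 -> MSE 0; |1-3| = 2 -> total 2 at alpha=1
    assert float(sdsp_loss(ab, ba, [2.0], alpha=1.0).data) == pytest.approx(2.0)
    assert float(sdsp_loss(ab, ba, [2.0], alpha=0.0).data) == pytest.approx(0.0)


def test_loss_rejects_nonfinite():
    ab = Tensor(np.array([[1.0]]))
    with pytest.raises(ValueError):
        sdsp_loss(ab, ab, [np.nan])


def test_prediction_pair_final_is_mean():
    assert PredictionPair(2.0, 4.0).final == 3.0


# ------------------------------------------------------------------- the model

def test_predict_degenerate_pair_well_defined():
    model = SDSP(TINY)
    s = SynergySample("CCO", "CCO", CELL, 0.0)
    pair = model.predict(s)
    assert np.isfinite(pair.ss_AB) and np.isfinite(pair.ss_BA)
    assert pair.final == pytest.approx(0.5 * (pair.ss_AB + pair.ss_BA))


def test_swap_routes_concatenations_to_opposite_heads():
    """final(B,A) must equal (head1 on the BA concat + head2 on the AB
    concat)/2, reconstructed by hand from the encoders."""
    from phenocomb.nn import concat

    model = SDSP(TINY)
    a, b = "CCO", "c1ccccc1"
    z = model.encode_drugs([a, b])
    z_G = model.cell_mlp(Tensor(CELL[None, :])).relu()
    z_A, z_B = z[0:1, :], z[1:2, :]
    hand_ab = float(model.head_ab(concat([z_G, z_B, z_A], axis=1)).data[0, 0])
    hand_ba = float(model.head_ba(concat([z_G, z_A, z_B], axis=1)).data[0, 0])
    swapped = model.predict(SynergySample(b, a, CELL, 0.0))
    assert swapped.ss_AB == pytest.approx(hand_ab, abs=1e-9)
    assert swapped.ss_BA == pytest.approx(hand_ba, abs=1e-9)
    assert swapped.final == pytest.approx(0.5 * (hand_ab + hand_ba), abs=1e-9)


def test_tied_heads_make_prediction_order_invariant():
    model = SDSP(TINY)
    for pa, pb in zip(model.head_ab.parameters(), model.head_ba.parameters()):
        pb.data = pa.data.copy()
    s = SynergySample("CCO", "c1ccccc1", CELL, 0.0)
    assert model.predict(s).final == pytest.approx(model.predict(s.swapped()).final,
                                                   abs=1e-6)


def test_fingerprint_variant_same_contracts():
    model = SDSP(replace(TINY, encoder="fingerprint", fp_bits=512))
    pair = model.predict(SynergySample("CCO", "CCN", CELL, 0.0))
    assert np.isfinite(pair.final)
    batch = model.predict_batch(_samples(np.zeros(5)))
    assert batch.shape == (5,)


# -------------------------------------------------------------------- metrics

def test_evaluate_identity_and_symmetric_cases():
    rng = np.random.default_rng(6)
    truth = rng.normal(0, 6, 500)
    m = evaluate(truth, truth, preds_reversed=truth)
    assert m["pearson_r"] == pytest.approx(1.0)
    assert m["spearman_rho"] == pytest.approx(1.0)
    assert m["ab_ba_pearson"] == pytest.approx(1.0)


def test_evaluate_random_scores_auroc_near_half():
    rng = np.random.default_rng(7)
    truth = rng.normal(-0.55, 5.45, 10_000)
    preds = rng.normal(0, 1, 10_000)
    m = evaluate(preds, truth)
    assert 0.45 < m["auroc"] < 0.55


def test_evaluate_flags_degenerate_inputs():
    with pytest.raises(ValueError):
        evaluate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    m = evaluate(np.ones(10), np.arange(10.0))
    assert m["constant_input"] and np.isnan(m["pearson_r"])


# ----------------------------------------------------------------------- FWHM

def test_fwhm_zero_for_constant_and_scales_with_spread():
    assert fwhm(np.full(100, 3.0)) == 0.0
    rng = np.random.default_rng(8)
    narrow = fwhm(rng.normal(0, 1, 5000))
    wide = fwhm(rng.normal(0, 3, 5000))
    assert narrow < wide
    # Gaussian FWHM is ~2.355 sigma; histogram estimate is coarse
    assert 1.5 < narrow < 3.3


def test_fwhm_stability_contracts():
    model = SDSP(TINY)
    with pytest.raises(ValueError):
        fwhm_stability(model, [("CCO", "CCN", CELL)], k=1)
    widths = fwhm_stability(model, [("CCO", "c1ccccc1", CELL)], k=3, seed=0)
    assert len(widths) == 1 and widths[0] >= 0.0


def test_fwhm_zero_for_drug_blind_model():
    model = SDSP(TINY)
    # zero the drug pathway: encoder output contributes nothing
    if model.cfg.encoder == "smiles":
        model.drug_fc.W.data[:] = 0.0
        model.drug_fc.b.data[:] = 0.0
    widths = fwhm_stability(model, [("CCO", "c1ccccc1", CELL),
                                    ("CCN", "c1ccncc1", CELL)], k=3, seed=1)
    assert widths == [0.0, 0.0]
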