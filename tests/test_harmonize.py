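"""Empirical-Bayes batch correction: recovery, identity cases, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import dysbioformer as d
from dysbioformer.compositional import CompositionMatrix, clr_transform, zero_replace
from dysbioformer.harmonize import (
    alignment_score,
    apply_batch_correction,
    estimate_batch_params,
)
from dysbioformer.io_formats import SampleMetadata


def _null_clr(n_taxa=20, n_per_batch=100, n_batches=2, seed=0):
    """Null multi-study CLR matrix (no batch effect, no disease effect)."""
    tree = d.simulate_tree(n_taxa, seed)
    cfg = d.SimConfig(
        n_taxa=n_taxa,
        studies=[(f"b{k}", n_per_batch // 2, n_per_batch - n_per_batch // 2)
                 for k in range(n_batches)],
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        sequencing_depth_mean=20000,
        seed=seed + 1,
    )
    counts, meta, _ = d.simulate_cohorts(cfg, tree)
    return clr_transform(zero_replace(counts)), meta


def _plant_shift(clr, meta, batch, shift):
    """Add a zero-sum per-taxon shift to one batch's CLR columns."""
    values = clr.values.copy()
    cols = np.where(meta.studies(clr.samples) == batch)[0]
    values[:, cols] += shift[:, None]
    return CompositionMatrix(list(clr.taxa), list(clr.samples), values, clr.mode)


def _zero_sum_unit_shift(n_taxa):
    """+1.0 on the first half of the taxa, -1.0 on the second half."""
    shift = np.ones(n_taxa)
    shift[n_taxa // 2:] = -1.0
    assert abs(shift.sum()) < 1e-12
    return shift


def test_single_batch_correction_is_identity():
    clr, meta = _null_clr(n_batches=1, seed=2)
    model = estimate_batch_params(clr, meta, lam=0.01)
    out = apply_batch_correction(clr, model, meta)
    np.testing.assert_allclose(out.values, clr.values, atol=1e-9)


def test_full_shrinkage_limit():
    clr, meta = _null_clr(seed=3)
    model = estimate_batch_params(clr, meta, lam=1e12)
    for b in range(len(model.batches)):
        np.testing.assert_allclose(model.mu_b[:, b], model.mu_star, atol=1e-6)


def test_planted_shift_recovered():
    clr, meta = _null_clr(seed=4)
    shift = _zero_sum_unit_shift(len(clr.taxa))
    shifted = _plant_shift(clr, meta, "b1", shift)
    model = estimate_batch_params(shifted, meta, lam=0.01)
    est = model.mu_b[:, model.batches.index("b1")] - model.mu_b[:, model.batches.index("b0")]
    plus = shift > 0
    assert abs(est[plus].mean() - 1.0) < 0.1
    assert abs(est[~plus].mean() + 1.0) < 0.1


def test_correction_aligns_batch_means():
    clr, meta = _null_clr(seed=5)
    shifted = _plant_shift(clr, meta, "b1", _zero_sum_unit_shift(len(clr.taxa)))
    model = estimate_batch_params(shifted, meta, lam=0.01)
    out = apply_batch_correction(shifted, model, meta)
    studies = meta.studies(out.samples)
    m0 = out.values[:, studies == "b0"].mean(axis=1)
    m1 = out.values[:, studies == "b1"].mean(axis=1)
    assert np.abs(m0 - m1).max() < 0.05


def test_second_application_near_identity():
    clr, meta = _null_clr(seed=6)
    shifted = _plant_shift(clr, meta, "b1", _zero_sum_unit_shift(len(clr.taxa)))
    model = estimate_batch_params(shifted, meta, lam=0.01)
    once = apply_batch_correction(shifted, model, meta)
    model2 = estimate_batch_params(once, meta, lam=0.01)
    twice = apply_batch_correction(once, model2, meta)
    assert np.abs(twice.values - once.values).mean() < 0.05


def test_null_correction_barely_changes_values():
    clr, meta = _null_clr(seed=7)
    model = estimate_batch_params(clr, meta, lam=0.01)
    out = apply_batch_correction(clr, model, meta)
    assert np.abs(out.values - clr.values).mean() < 0.1


def test_alignment_score_zero_for_identical_batches():
    rng = np.random.default_rng(8)
    block = rng.normal(size=(5, 10))
    block -= block.mean(axis=0, keepdims=True)
    values = np.concatenate([block, block], axis=1)
    samples = [f"s{j}" for j in range(20)]
    clr = CompositionMatrix([f"t{i}" for i in range(5)], samples, values, "clr")
    meta = SampleMetadata(
        pd.DataFrame(
            {"study_id": ["a"] * 10 + ["b"] * 10, "label": ["control"] * 20},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    scores, total = alignment_score(clr, meta)
    assert total == pytest.approx(0.0, abs=1e-12)


def test_alignment_score_decreases_after_correction():
    clr, meta = _null_clr(seed=9)
    shifted = _plant_shift(clr, meta, "b1", _zero_sum_unit_shift(len(clr.taxa)))
    model = estimate_batch_params(shifted, meta, lam=0.01)
    out = apply_batch_correction(shifted, model, meta)
    _, pre = alignment_score(shifted, meta)
    _, post = alignment_score(out, meta)
    assert post < pre


def test_alignment_null_permutation_ratio_near_one():
    clr, meta = _null_clr(seed=10)
    rng = np.random.default_rng(11)
    _, base = alignment_score(clr, meta)
    ratios = []
    for _ in range(50):
        frame = meta.frame.copy()
        frame["study_id"] = rng.permutation(frame["study_id"].to_numpy())
        permuted = SampleMetadata(frame)
        _, score = alignment_score(clr, permuted)
        ratios.append(score / base)
    assert 0.5 < float(np.median(ratios)) < 2.0


def test_small_batch_falls_back_to_identity():
    clr, meta = _null_clr(seed=12)
    frame = meta.frame.copy()
    lone = frame.index[0]
    frame.loc[lone, "study_id"] = "singleton"
    meta2 = SampleMetadata(frame)
    model = estimate_batch_params(clr, meta2, lam=0.01)
    assert "singleton" in model.identity_batches
    out = apply_batch_correction(clr, model, meta2)
    col = clr.samples.index(lone)
    np.testing.assert_allclose(out.values[:, col], clr.values[:, col], atol=1e-9)


def test_unknown_batch_raises_by_default():
    clr, meta = _null_clr(seed=13)
    train = [s for s in clr.samples if meta.frame.loc[s, "study_id"] == "b0"]
    model = estimate_batch_params(clr.subset_samples(train), meta.subset(train))
    with pytest.raises(ValueError, match="not fitted"):
        apply_batch_correction(clr, model, meta, unknown_batch="error")
    # identity mode passes held-out batches through
    out = apply_batch_correction(clr, model, meta, unknown_batch="identity")
    assert out.values.shape == clr.values.shape


def test_correction_preserves_within_batch_ordering():
    clr, meta = _null_clr(seed=14)
    model = estimate_batch_params(clr, meta, lam=0.01)
    out = apply_batch_correction(clr, model, meta)
    studies = meta.studies(clr.samples)
    cols = np.where(studies == "b0")[0]
    for i in range(0, len(clr.taxa), 5):
        before = np.argsort(clr.values[i, cols])
        after = np.argsort(out.values[i, cols])
        assert (before == after).all()


def test_fitted_on_records_training_samples():
    clr, meta = _null_clr(seed=15)
    model = estimate_batch_params(clr, meta)
    assert model.fitted_on == list(clr.samples)
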