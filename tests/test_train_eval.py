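"""Fold planning, metrics, leakage guard, and a separable end-to-end toy."""

import numpy as np
import pandas as pd
import pytest

import dysbioformer as d
from dysbioformer.io_formats import CountTable, SampleMetadata, read_tree
from dysbioformer.set_model import ModelConfig
from dysbioformer.train_eval import (
    LeakageError,
    PipelineConfig,
    TrainConfig,
    assert_no_leakage,
    compute_metrics,
    make_folds,
    run_fold,
    summarize_folds,
)


def _meta(labels, studies, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SampleMetadata(
        pd.DataFrame({"study_id": studies, "label": labels},
                     index=pd.Index(ids, name="sample_id"))
    )


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

def test_stratified_folds_balance_classes():
    meta = _meta(["disease"] * 50 + ["control"] * 50, ["x"] * 100)
    plan = make_folds(meta, "stratified_within_study", 5, seed=42)
    for train, test in plan.folds:
        labels = meta.labels(test)
        assert (labels == "disease").sum() == 10
        assert (labels == "control").sum() == 10
        assert len(train) == 80


def test_leave_study_out_one_study_per_fold():
    labels = ["disease", "control"] * 25
    studies = [f"study_{i % 5}" for i in range(50)]
    plan = make_folds(_meta(labels, studies), "leave_study_out", 5, seed=42)
    for train, test in plan.folds:
        meta = _meta(labels, studies)
        test_studies = set(meta.studies(test))
        assert len(test_studies) == 1
        assert test_studies.isdisjoint(set(meta.studies(train)))


def test_folds_deterministic_under_seed():
    meta = _meta(["disease", "control"] * 30, [f"g{i % 6}" for i in range(60)])
    p1 = make_folds(meta, "leave_study_out", 5, seed=42)
    p2 = make_folds(meta, "leave_study_out", 5, seed=42)
    assert p1.folds == p2.folds


def test_folds_partition_samples():
    meta = _meta(["disease", "control"] * 30, [f"g{i % 6}" for i in range(60)])
    plan = make_folds(meta, "leave_study_out", 5, seed=1)
    all_test = sorted(s for _, test in plan.folds for s in test)
    assert all_test == sorted(meta.sample_ids)


def test_folds_error_on_too_few_studies():
    meta = _meta(["disease", "control"] * 4, ["a", "a", "b", "b"] * 2)
    with pytest.raises(ValueError, match="studies"):
        make_folds(meta, "leave_study_out", 5)


def test_folds_error_on_too_few_samples():
    meta = _meta(["disease"] * 3 + ["control"] * 10, ["x"] * 13)
    with pytest.raises(ValueError, match="fewer"):
        make_folds(meta, "stratified_within_study", 5)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_metrics_perfect_prediction():
    y = np.array([0, 1, 1, 0, 1])
    m = compute_metrics(y, y.astype(float))
    assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1", "auc"))


def test_metrics_chance_constant_probability():
    y = np.array([0, 1] * 10)
    m = compute_metrics(y, np.full(20, 0.5))
    assert m["accuracy"] == 0.5  # deterministic >= 0.5 tie rule predicts all 1
    assert m["auc"] == 0.5


def test_metrics_hand_confusion_matrix():
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    p = np.array([0.9, 0.8, 0.4, 0.7, 0.6, 0.2, 0.1, 0.3])
    m = compute_metrics(y, p)
    # preds: 1,1,0,1,1,0,0,0 -> TP=3 FP=1 FN=1 TN=3
    assert m["precision"] == pytest.approx(3 / 4)
    assert m["recall"] == pytest.approx(3 / 4)
    assert m["f1"] == pytest.approx(3 / 4)
    assert m["accuracy"] == pytest.approx(6 / 8)
    # rank-statistic oracle: fraction of concordant case-control pairs
    concordant = ties = 0
    for i in np.where(y == 1)[0]:
        for j in np.where(y == 0)[0]:
            concordant += p[i] > p[j]
            ties += p[i] == p[j]
    assert m["auc"] == pytest.approx((concordant + 0.5 * ties) / 16)


def test_metrics_single_class_auc_missing():
    with pytest.warns(UserWarning, match="AUC"):
        m = compute_metrics(np.ones(5, dtype=int), np.linspace(0, 1, 5))
    assert m["auc"] is None


def test_summary_is_arithmetic_mean():
    from dysbioformer.train_eval import FoldResult

    results = [
        FoldResult(i, {"accuracy": a, "precision": a, "recall": a, "f1": a, "auc": a},
                   10, 5)
        for i, a in enumerate([0.8, 0.9, 1.0])
    ]
    summary = summarize_folds(results)
    assert summary["accuracy"][0] == pytest.approx(0.9)


# ---------------------------------------------------------------------------
# Leakage guard
# ---------------------------------------------------------------------------

def test_assert_no_leakage_raises_on_overlap():
    with pytest.raises(LeakageError, match="fitted"):
        assert_no_leakage(["a", "b", "c"], ["c", "d"])
    assert_no_leakage(["a", "b"], ["c", "d"])  # disjoint: fine


def _toy_problem():
    """Noise-free disjoint single-taxon signatures: trivially separable."""
    tree = read_tree("((A:0.1,B:0.2):0.1,C:0.3);")
    n = 40
    counts = np.zeros((3, n), dtype=np.int64)
    labels, studies, ids = [], [], []
    for i in range(n):
        disease = i % 2 == 0
        counts[0 if disease else 1, i] = 1000
        counts[2, i] = 100
        labels.append("disease" if disease else "control")
        studies.append(f"st{i % 2}")
        ids.append(f"s{i}")
    table = CountTable(["A", "B", "C"], ids, counts)
    meta = SampleMetadata(
        pd.DataFrame({"study_id": studies, "label": labels},
                     index=pd.Index(ids, name="sample_id"))
    )
    config = PipelineConfig(
        model=ModelConfig(token_dim=8, sab_layers=1, n_heads=2, pma_seeds=2,
                          ffn_dim=16, head_hidden=8, dropout=0.0, seed=0),
        train=TrainConfig(lr=5e-3, batch_size=8, epochs=40, patience=40,
                          warmup_steps=20, seed=0),
        phylo_dim=2,
    )
    return table, meta, tree, config


def test_pipeline_config_dict_roundtrip():
    cfg = PipelineConfig()
    rebuilt = PipelineConfig.from_dict(cfg.to_dict())
    assert rebuilt.to_dict() == cfg.to_dict()
    with pytest.raises(ValueError, match="unknown config key"):
        PipelineConfig.from_dict({"learning_rate": 0.1})


def test_run_fold_rejects_overlapping_ids():
    table, meta, tree, config = _toy_problem()
    ids = meta.sample_ids
    with pytest.raises(LeakageError):
        run_fold(0, ids[:30], ids[25:], table, meta, tree, config)


def test_perfectly_separable_toy_reaches_full_accuracy():
    table, meta, tree, config = _toy_problem()
    ids = meta.sample_ids
    train_ids = ids[:32]
    test_ids = ids[32:]
    result = run_fold(0, train_ids, test_ids, table, meta, tree, config)
    assert result.metrics["accuracy"] == 1.0
    assert result.metrics["auc"] == 1.0
    # learning curve sanity: end below start
    assert result.history["train_loss"][-1] < result.history["train_loss"][0]
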