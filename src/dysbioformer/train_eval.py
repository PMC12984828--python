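"""Leakage-safe cross-validation, training loop, and metrics.

Two split modes are supported: ``stratified_within_study`` (class-stratified
5-fold) and ``leave_study_out`` — the headline evaluation — where entire
studies are held out so no study contributes samples to both sides of a
fold. Every fitted object (batch model, tokenizer, network) records the
sample IDs it was fitted on; the driver asserts that no test sample appears
in any fitted-on list and raises :class:`LeakageError` otherwise. The
compositional closure and CLR are per-sample maps with no fitted state, so
they may be applied to all samples up front.

Reported summary metrics are the arithmetic means of the per-fold values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam
from .compositional import CompositionMatrix, clr_transform, zero_replace
from .harmonize import apply_batch_correction, estimate_batch_params
from .io_formats import CountTable, PhyloTree, SampleMetadata
from .phylo import kernel_features, phylo_kernel
from .set_model import DysbioNet, ModelConfig, weighted_cross_entropy
from .tokens import TokenSet, apply_normalizer, build_token_sets, fit_normalizer

log = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """A fitted object saw samples that belong to a test fold."""


def assert_no_leakage(fitted_on, test_ids, what: str = "model") -> None:
    overlap = set(fitted_on) & set(test_ids)
    if overlap:
        raise LeakageError(
            f"{what} was fitted on {len(overlap)} test sample(s), "
            f"e.g. {sorted(overlap)[:3]}"
        )


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    mode: str  # {"stratified_within_study", "leave_study_out"}
    n_folds: int
    seed: int
    folds: list[tuple[list[str], list[str]]]  # (train ids, test ids)

    def __post_init__(self) -> None:
        all_test = [s for _, test in self.folds for s in test]
        if len(all_test) != len(set(all_test)):
            raise ValueError("fold test sets overlap")


def make_folds(
    meta: SampleMetadata, mode: str = "leave_study_out", n_folds: int = 5, seed: int = 42
) -> FoldPlan:
    """Deterministic cross-validation plan.

    ``stratified_within_study`` preserves the class ratio per fold (+/- 1
    sample); ``leave_study_out`` assigns whole studies to folds so no
    study_id ever straddles a train/test boundary.
    """
    ids = np.array(meta.sample_ids)
    labels = meta.labels()
    folds: list[tuple[list[str], list[str]]] = []
    if mode == "stratified_within_study":
        counts = {lab: int((labels == lab).sum()) for lab in set(labels)}
        too_few = [lab for lab, n in counts.items() if n < n_folds]
        if too_few:
            raise ValueError(f"classes with fewer than {n_folds} samples: {too_few}")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(ids, labels):
            folds.append((list(ids[train_idx]), list(ids[test_idx])))
    elif mode == "leave_study_out":
        studies = meta.studies()
        unique = sorted(set(studies))
        if len(unique) < n_folds:
            raise ValueError(
                f"leave_study_out needs >= {n_folds} studies, found {len(unique)}"
            )
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(unique))
        groups: list[list[str]] = [[] for _ in range(n_folds)]
        for k, study in enumerate(order):
            groups[k % n_folds].append(study)
        for g in groups:
            test_mask = np.isin(studies, g)
            folds.append((list(ids[~test_mask]), list(ids[test_mask])))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return FoldPlan(mode, n_folds, seed, folds)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict[str, float | None]:
    """Threshold-0.5 class metrics plus rank-based AUC (binary).

    ``y_prob`` is the probability of the positive class. With a single-class
    ``y_true`` the AUC is undefined and reported as None (with a warning).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    y_pred = (y_prob >= 0.5).astype(int)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUC undefined", stacklevel=2)
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(y_true, y_prob))
    return out


@dataclass
class FoldResult:
    fold: int
    metrics: dict[str, float | None]
    n_train: int
    n_test: int
    history: dict[str, list[float]] = field(default_factory=dict)
    test_ids: list[str] = field(default_factory=list)
    y_prob: np.ndarray | None = None


def summarize_folds(results: list[FoldResult]) -> dict[str, tuple[float, float]]:
    """Mean +/- SD of each metric across folds (None-valued metrics skipped)."""
    out = {}
    for key in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = [r.metrics[key] for r in results if r.metrics.get(key) is not None]
        if vals:
            out[key] = (float(np.mean(vals)), float(np.std(vals)))
    return out


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 5e-4
    batch_size: int = 64
    epochs: int = 200
    patience: int = 20  # early stopping on validation loss
    val_fraction: float = 0.1
    warmup_steps: int = 0  # linear lr ramp from 0 over the first steps
    seed: int = 42


def train_model(
    net: DysbioNet,
    tokens: TokenSet,
    y: np.ndarray,
    cfg: TrainConfig,
) -> dict[str, list[float]]:
    """Train with Adam + class-weighted cross-entropy + early stopping.

    A stratified ``val_fraction`` of the provided samples is held aside for
    the stopping rule; the best-validation parameters are restored at the
    end. Returns the learning-curve history.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    classes = np.unique(y)
    # inverse-frequency class weights against imbalanced cohorts
    weights = np.ones(net.config.n_classes)
    for cls in classes:
        weights[cls] = n / (len(classes) * (y == cls).sum())

    # stratified validation split
    val_idx: list[int] = []
    for cls in classes:
        members = np.where(y == cls)[0]
        k = max(1, int(round(cfg.val_fraction * members.size)))
        val_idx.extend(rng.choice(members, size=k, replace=False))
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_idx = np.where(~val_mask)[0]
    val_idx = np.where(val_mask)[0]

    opt = Adam(net.params, lr=cfg.lr)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best = np.inf, net.state_copy(), 0
    ids = np.array(tokens.sample_ids)

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            sub = tokens.subset(list(ids[batch]))
            if cfg.warmup_steps > 0:
                opt.lr = cfg.lr * min(1.0, (opt.t + 1) / cfg.warmup_steps)
            opt.zero_grad()
            logits, _ = net.forward_logits(sub, train=True, rng=drop_rng)
            loss = weighted_cross_entropy(logits, y[batch], weights)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_sub = tokens.subset(list(ids[val_idx]))
        val_logits, _ = net.forward_logits(val_sub, train=False)
        val_loss = float(weighted_cross_entropy(val_logits, y[val_idx], weights).data)
        history["train_loss"].append(epoch_loss / max(1, n_batches))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_state, since_best = val_loss, net.state_copy(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                log.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    net.load_state(best_state)
    return history


# ---------------------------------------------------------------------------
# Pipeline configuration and fold execution
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end configuration; the defaults are the full-scale settings."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    delta: float = 1e-6  # CLR pseudo-count
    eb_lambda: float = 0.01  # empirical-Bayes shrinkage strength
    lambda_k: float = 1.0  # phylogenetic kernel decay
    phylo_dim: int = 64  # spectral feature dimension m
    positive_label: str = "disease"

    def to_dict(self) -> dict:
        return {
            "token_dim": self.model.token_dim,
            "sab_layers": self.model.sab_layers,
            "heads": self.model.n_heads,
            "pma_seeds": self.model.pma_seeds,
            "dropout": self.model.dropout,
            "batch": self.train.batch_size,
            "lr": self.train.lr,
            "epochs": self.train.epochs,
            "delta": self.delta,
            "eb_lambda": self.eb_lambda,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from the flat key scheme of :meth:`to_dict` (the
        published-settings YAML layout); unknown keys raise."""
        cfg = cls()
        handlers = {
            "token_dim": lambda v: setattr(cfg.model, "token_dim", int(v)),
            "sab_layers": lambda v: setattr(cfg.model, "sab_layers", int(v)),
            "heads": lambda v: setattr(cfg.model, "n_heads", int(v)),
            "pma_seeds": lambda v: setattr(cfg.model, "pma_seeds", int(v)),
            "dropout": lambda v: setattr(cfg.model, "dropout", float(v)),
            "batch": lambda v: setattr(cfg.train, "batch_size", int(v)),
            "lr": lambda v: setattr(cfg.train, "lr", float(v)),
            "epochs": lambda v: setattr(cfg.train, "epochs", int(v)),
            "delta": lambda v: setattr(cfg, "delta", float(v)),
            "eb_lambda": lambda v: setattr(cfg, "eb_lambda", float(v)),
        }
        for key, value in data.items():
            if key not in handlers:
                raise ValueError(f"unknown config key {key!r}")
            handlers[key](value)
        return cfg


def run_fold(
    fold_id: int,
    train_ids: list[str],
    test_ids: list[str],
    counts: CountTable,
    meta: SampleMetadata,
    tree: PhyloTree,
    config: PipelineConfig,
    return_artifacts: bool = False,
):
    """Fit the whole preprocessing + model stack on the training samples and
    evaluate on the held-out samples with frozen parameters.

    With ``return_artifacts=True`` also returns the fitted network, the
    normalized token sets and the corrected CLR matrix (for attribution)."""
    if set(train_ids) & set(test_ids):
        raise LeakageError("train and test sample sets overlap")

    # per-sample stateless maps (no fitting): closure + CLR
    frac = zero_replace(counts, config.delta)
    clr = clr_transform(frac)

    # empirical-Bayes harmonization: fit on train, transform all
    batch_model = estimate_batch_params(
        clr.subset_samples(train_ids), meta.subset(train_ids), config.eb_lambda
    )
    assert_no_leakage(batch_model.fitted_on, test_ids, "batch model")
    corrected = apply_batch_correction(clr, batch_model, meta, unknown_batch="identity")

    # phylogenetic geometry (tree-derived, label- and sample-free);
    # the spectral dimension cannot exceed the taxon count
    pmodel = kernel_features(
        phylo_kernel(tree, counts.taxa, config.lambda_k),
        min(config.phylo_dim, len(counts.taxa)),
    )

    tokens_raw = build_token_sets(corrected, frac, counts, pmodel)
    tok_state = fit_normalizer(
        tokens_raw.subset(train_ids), config.model.token_dim, config.model.seed
    )
    assert_no_leakage(tok_state.fitted_on, test_ids, "token normalizer")
    tokens = apply_normalizer(tokens_raw, tok_state)

    labels = meta.labels(tokens.sample_ids)
    label_set = tuple(sorted(set(meta.labels())))
    y_all = np.array([label_set.index(l) for l in labels])
    pos = label_set.index(config.positive_label)

    net = DysbioNet(
        tokens.feature_dim,
        tokens.phylo_dim,
        config.model,
        labels=label_set,
        tokenizer_state=tok_state,
    )
    id_pos = {s: i for i, s in enumerate(tokens.sample_ids)}
    train_y = y_all[[id_pos[s] for s in train_ids]]
    history = train_model(net, tokens.subset(train_ids), train_y, config.train)

    test_tokens = tokens.subset(test_ids)
    probs = net.predict_proba(test_tokens)[:, pos]
    test_y = (y_all[[id_pos[s] for s in test_ids]] == pos).astype(int)
    metrics = compute_metrics(test_y, probs)
    result = FoldResult(
        fold_id, metrics, len(train_ids), len(test_ids), history, list(test_ids), probs
    )
    if return_artifacts:
        return result, {"net": net, "tokens": tokens, "clr": corrected, "frac": frac}
    return result


def run_cv(
    counts: CountTable,
    meta: SampleMetadata,
    tree: PhyloTree,
    config: PipelineConfig,
    mode: str = "leave_study_out",
    n_folds: int = 5,
    seed: int = 42,
) -> tuple[list[FoldResult], dict[str, tuple[float, float]]]:
    plan = make_folds(meta, mode, n_folds, seed)
    results = [
        run_fold(k, train_ids, test_ids, counts, meta, tree, config)
        for k, (train_ids, test_ids) in enumerate(plan.folds)
    ]
    return results, summarize_folds(results)
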