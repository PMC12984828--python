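"""The default synthetic diagnostic benchmark.

Five studies of 80 samples each (40 cases / 40 controls), 100 tree-
correlated taxa, 5 planted disease-associated taxa at latent log-fold +1.5,
per-study batch shifts on — evaluated by leave-study-out cross-validation
with a scaled-down model (token_dim 32, 2 SAB layers, 4 heads, 4 PMA seeds,
30 epochs) so a full run finishes in minutes on one CPU. Attribution is
computed per fold on the held-out study and pooled by stability selection;
the generator's ground truth says which taxa were planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribution import AttributionReport, StabilityResult, stability_selection, taxon_importance
from .io_formats import CountTable, SampleMetadata
from .set_model import ModelConfig
from .synthetic import GroundTruth, SimConfig, simulate_cohorts, simulate_tree
from .train_eval import (
    FoldResult,
    PipelineConfig,
    TrainConfig,
    make_folds,
    run_fold,
    summarize_folds,
)

N_PLANTED = 5
PLANTED_LOG_FOLD = 1.5


def scaled_pipeline_config(seed: int = 42) -> PipelineConfig:
    """Desk-scale model settings; lr/batch/widths sized for the small model."""
    return PipelineConfig(
        model=ModelConfig(
            token_dim=32,
            sab_layers=2,
            n_heads=4,
            pma_seeds=4,
            ffn_dim=128,
            head_hidden=64,
            dropout=0.2,
            seed=seed,
        ),
        train=TrainConfig(
            lr=4e-3, batch_size=32, epochs=30, patience=30, warmup_steps=60, seed=seed
        ),
        phylo_dim=64,
    )


def benchmark_sim_config(seed: int = 42) -> SimConfig:
    """Study conditions of the benchmark; planted taxa chosen by the seed."""
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{i + 1:04d}" for i in range(100)]
    planted = sorted(rng.choice(100, size=N_PLANTED, replace=False))
    return SimConfig(
        n_taxa=100,
        studies=[(f"study_{k + 1}", 40, 40) for k in range(5)],
        effect_taxa={taxa[i]: PLANTED_LOG_FOLD for i in planted},
        batch_shift_sd=0.5,
        batch_scale_sd=0.1,
        sequencing_depth_mean=20000,
        overdispersion=0.3,
        seed=seed,
    )


@dataclass
class BenchmarkResult:
    seed: int
    counts: CountTable
    meta: SampleMetadata
    truth: GroundTruth
    fold_results: list[FoldResult]
    summary: dict[str, tuple[float, float]]
    reports: list[AttributionReport] = field(default_factory=list)
    stability: StabilityResult | None = None

    @property
    def mean_auc(self) -> float:
        return self.summary["auc"][0]

    @property
    def planted(self) -> list[str]:
        return self.truth.planted


def run_benchmark(
    seed: int = 42,
    permute_labels: bool = False,
    with_attribution: bool = True,
    attribution_k: int = 10,
) -> BenchmarkResult:
    """Generate the benchmark cohort and run leave-study-out CV end to end."""
    sim = benchmark_sim_config(seed)
    tree = simulate_tree(sim.n_taxa, seed)
    counts, meta, truth = simulate_cohorts(sim, tree)
    if permute_labels:
        rng = np.random.default_rng(seed + 1000)
        frame = meta.frame.copy()
        frame["label"] = rng.permutation(frame["label"].to_numpy())
        meta = SampleMetadata(frame)

    config = scaled_pipeline_config(seed)
    plan = make_folds(meta, "leave_study_out", 5, seed)
    fold_results: list[FoldResult] = []
    reports: list[AttributionReport] = []
    for k, (train_ids, test_ids) in enumerate(plan.folds):
        result, artifacts = run_fold(
            k, train_ids, test_ids, counts, meta, tree, config, return_artifacts=True
        )
        fold_results.append(result)
        if with_attribution:
            reports.append(
                taxon_importance(
                    artifacts["net"],
                    artifacts["tokens"].subset(test_ids),
                    counts.taxa,
                    clr=artifacts["clr"].subset_samples(test_ids),
                    meta=meta,
                )
            )
    stability = (
        stability_selection(reports, attribution_k) if with_attribution else None
    )
    return BenchmarkResult(
        seed,
        counts,
        meta,
        truth,
        fold_results,
        summarize_folds(fold_results),
        reports,
        stability,
    )


def planted_recovery(result: BenchmarkResult, k: int = 10) -> dict[str, float]:
    """How well attribution recovered the planted taxa.

    Returns the count of planted taxa inside the pooled attribution top-k
    and the mean stability frequency of planted vs non-planted taxa.
    """
    assert result.stability is not None
    planted = set(result.planted)
    ranked = result.stability.ranked_taxa()
    in_top = len(planted & set(ranked[:k]))
    freq = result.stability.frequency
    taxa = result.stability.taxa
    is_planted = np.array([t in planted for t in taxa])
    return {
        "planted_in_top_k": float(in_top),
        "planted_mean_stability": float(freq[is_planted].mean()),
        "other_mean_stability": float(freq[~is_planted].mean()),
    }
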