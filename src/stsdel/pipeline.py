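"""End-to-end driver: QC -> features -> training -> calls -> merged intervals.

The shipped classifier defaults are C = 2^9 and sigma = 2^3; pass an
:class:`~stsdel.svm.SVMConfig` to re-select them by grid search instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from stsdel.catalog import STSCatalog
from stsdel.features import FeatureMatrix, compute_features, sts_stats
from stsdel.merge import DeletionInterval, MergeParams, merge_calls
from stsdel.qc import DepthMatrix, QCParams, QCReport, run_qc
from stsdel.simulate import SimCohort, make_training_subset
from stsdel.svm import (
    CallMatrix,
    DeletionClassifier,
    SVMConfig,
    TrainingSet,
    classify,
    grid_search_cv,
    train_classifier,
)

DEFAULT_C = 2.0**9
DEFAULT_SIGMA = 2.0**3


@dataclass
class PipelineResult:
    qc_matrix: DepthMatrix
    qc_report: QCReport
    features: FeatureMatrix
    training: TrainingSet
    classifier: DeletionClassifier
    calls: CallMatrix
    intervals: dict[str, list[DeletionInterval]]
    grid: pd.DataFrame | None = None


def run_pipeline(
    depth: DepthMatrix,
    catalog: STSCatalog,
    training: TrainingSet,
    qc_params: QCParams = QCParams(),
    merge_params: MergeParams = MergeParams(),
    svm_config: SVMConfig | None = None,
    C: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
) -> PipelineResult:
    """Run every stage on an existing depth matrix and training set."""
    qc_matrix, report = run_qc(depth, qc_params)
    stats = sts_stats(qc_matrix)
    features = compute_features(qc_matrix, stats)
    grid = None
    if svm_config is not None:
        C, sigma, grid = grid_search_cv(training, svm_config)
    classifier = train_classifier(
        training, C, sigma, seed=svm_config.seed if svm_config else None
    )
    calls = classify(classifier, features)
    intervals = merge_calls(calls, catalog, merge_params)
    return PipelineResult(
        qc_matrix=qc_matrix,
        qc_report=report,
        features=features,
        training=training,
        classifier=classifier,
        calls=calls,
        intervals=intervals,
        grid=grid,
    )


def run_simulated_pipeline(
    cohort: SimCohort,
    n_training_events: int = 134,
    n_training_samples: int = 26,
    seed: int = 0,
    qc_params: QCParams = QCParams(),
    merge_params: MergeParams = MergeParams(),
    svm_config: SVMConfig | None = None,
    C: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
) -> PipelineResult:
    """Run the pipeline on a simulated cohort, drawing training labels from
    its planted truth (the synthetic stand-in for PCR-validated events)."""
    qc_matrix, report = run_qc(cohort.depth, qc_params)
    stats = sts_stats(qc_matrix)
    features = compute_features(qc_matrix, stats)
    training = make_training_subset(
        cohort.truth,
        features,
        n_events=n_training_events,
        n_samples=n_training_samples,
        seed=seed,
    )
    grid = None
    if svm_config is not None:
        C, sigma, grid = grid_search_cv(training, svm_config)
    classifier = train_classifier(
        training, C, sigma, seed=svm_config.seed if svm_config else seed
    )
    calls = classify(classifier, features)
    intervals = merge_calls(calls, cohort.catalog, merge_params)
    return PipelineResult(
        qc_matrix=qc_matrix,
        qc_report=report,
        features=features,
        training=training,
        classifier=classifier,
        calls=calls,
        intervals=intervals,
        grid=grid,
    )


def call_accuracy(result: PipelineResult, truth_deleted: pd.DataFrame) -> dict:
    """Per-STS sensitivity/specificity of the calls against planted truth,
    restricted to evaluated (sample, STS) pairs."""
    table = result.calls.table
    evaluated = table[table["state"] != "not_evaluated"]
    truth_long = truth_deleted.stack()
    truth_long.index.names = ["sample_id", "sts_id"]
    idx = pd.MultiIndex.from_frame(evaluated[["sample_id", "sts_id"]])
    truth_vals = truth_long.reindex(idx).to_numpy(dtype=bool)
    called = (evaluated["state"] == "deleted").to_numpy()
    tp = int((called & truth_vals).sum())
    fn = int((~called & truth_vals).sum())
    fp = int((called & ~truth_vals).sum())
    tn = int((~called & ~truth_vals).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
    }


def interval_recovery(
    result: PipelineResult, cohort: SimCohort, min_overlap: float = 0.5
) -> dict:
    """Interval-level sensitivity: fraction of planted runs for which some
    called interval in the same sample recovers >= ``min_overlap`` of the
    planted member STSs that survived QC."""
    qualified = set(result.qc_matrix.sts_ids)
    sts_ids = list(cohort.truth.deleted.columns)
    n_planted = 0
    n_recovered = 0
    for sample, runs in cohort.truth.intervals.items():
        called_members = {
            t for iv in result.intervals.get(sample, []) for t in iv.member_sts
        }
        for lo, hi in runs:
            planted = {
                sts_ids[k]
                for k in range(lo, hi + 1)
                if sts_ids[k] in qualified and bool(cohort.truth.deleted.iloc[:, k][sample])
            }
            if not planted:
                continue
            n_planted += 1
            overlap = len(planted & called_members) / len(planted)
            if overlap >= min_overlap:
                n_recovered += 1
    return {
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_planted if n_planted else float("nan"),
    }
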