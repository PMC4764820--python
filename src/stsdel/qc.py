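"""Depth-matrix quality control: IQR outlier removal, median-depth cutoff,
per-sample normalization and standard-deviation filtering.

The cascade runs in a fixed order on a raw samples x STSs mean-depth matrix:

1. :func:`iqr_outlier_filter` — samples and STSs whose mean depth is outside
   the 1.5x-IQR fences of the respective distribution are dropped (both sets
   are computed on the initial matrix and removed jointly).
2. :func:`median_depth_filter` — STSs whose raw median depth across remaining
   samples is below the cutoff (default 15x) are dropped.
3. :func:`normalize` — each entry is divided by its sample's mean depth over
   the surviving STSs, so every row mean becomes exactly 1.
4. :func:`sd_filter` — samples whose standard deviation of normalized depth
   exceeds the cutoff (default 0.7, strict ``>``) are dropped.

:func:`run_qc` chains the stages and returns the qualified matrix together
with a :class:`QCReport` whose counts always reconcile with the input sizes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stsdel._round import round_half_up
from stsdel.errors import ContractError, ValidationError


@dataclass
class DepthMatrix:
    """Samples x STSs matrix of mean per-base depth.

    ``frame`` is indexed by sample id with STS ids as columns. ``normalized``
    records whether the values have been divided by per-sample means.
    """

    frame: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.frame.to_numpy() < 0).any():
            raise ValidationError("depth matrix contains negative entries")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in depth matrix")
        if self.frame.columns.has_duplicates:
            raise ValidationError("duplicate STS ids in depth matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sts_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_sts(self) -> int:
        return self.frame.shape[1]

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def drop(self, samples: list[str] | None = None, sts: list[str] | None = None) -> "DepthMatrix":
        frame = self.frame
        if samples:
            frame = frame.drop(index=samples)
        if sts:
            frame = frame.drop(columns=sts)
        return DepthMatrix(frame, normalized=self.normalized)

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "DepthMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(frame.astype(float), normalized=normalized)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the filter cascade; defaults follow the shipped pipeline."""

    iqr_multiplier: float = 1.5
    median_depth_cutoff: float = 15.0
    sd_cutoff: float = 0.7
    #: statistic the IQR rule is applied to ("mean" or "median" per axis)
    iqr_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0 or self.median_depth_cutoff <= 0 or self.sd_cutoff <= 0:
            raise ValidationError("QC parameters must be strictly positive")
        if self.iqr_statistic not in ("mean", "median"):
            raise ValidationError("iqr_statistic must be 'mean' or 'median'")


@dataclass
class QCReport:
    """Stage-by-stage bookkeeping of the QC cascade.

    The derived fields satisfy the conservation identities
    ``qualified_sts = initial_sts - iqr_removed_sts - depth_cutoff_removed_sts``
    and ``qualified_samples = initial_samples - iqr_removed_samples -
    sd_removed_samples``; retention percentages are half-up rounded to one
    decimal.
    """

    initial_sts: int
    initial_samples: int
    iqr_removed_sts: int = 0
    iqr_removed_samples: int = 0
    depth_cutoff_removed_sts: int = 0
    sd_removed_samples: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def qualified_sts(self) -> int:
        return self.initial_sts - self.iqr_removed_sts - self.depth_cutoff_removed_sts

    @property
    def qualified_samples(self) -> int:
        return self.initial_samples - self.iqr_removed_samples - self.sd_removed_samples

    @property
    def sts_retention_pct(self) -> float:
        return round_half_up(100.0 * self.qualified_sts / self.initial_sts, 1)

    @property
    def sample_retention_pct(self) -> float:
        return round_half_up(100.0 * self.qualified_samples / self.initial_samples, 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            qualified_sts=self.qualified_sts,
            qualified_samples=self.qualified_samples,
            sts_retention_pct=self.sts_retention_pct,
            sample_retention_pct=self.sample_retention_pct,
        )
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _iqr_fences(values: np.ndarray, multiplier: float) -> tuple[float, float]:
    # linear interpolation between order statistics (numpy's default)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def iqr_outlier_filter(
    matrix: DepthMatrix, params: QCParams = QCParams()
) -> tuple[DepthMatrix, list[str], list[str]]:
    """Remove samples and STSs whose per-axis summary depth is outside the
    ``[Q1 - k*IQR, Q3 + k*IQR]`` fences.

    Both removal sets are derived from the initial matrix, then applied
    jointly. Returns ``(filtered, removed_sample_ids, removed_sts_ids)``.
    """
    if matrix.normalized:
        raise ContractError("iqr_outlier_filter expects a raw depth matrix")
    if matrix.n_samples < 4 or matrix.n_sts < 4:
        raise ValidationError(
            "IQR filter needs at least 4 samples and 4 STSs to define quartiles"
        )
    agg = np.mean if params.iqr_statistic == "mean" else np.median
    depth = matrix.values()
    sample_stat = agg(depth, axis=1)
    sts_stat = agg(depth, axis=0)
    s_lo, s_hi = _iqr_fences(sample_stat, params.iqr_multiplier)
    t_lo, t_hi = _iqr_fences(sts_stat, params.iqr_multiplier)
    bad_samples = [
        sid
        for sid, v in zip(matrix.sample_ids, sample_stat)
        if v < s_lo or v > s_hi
    ]
    bad_sts = [
        tid for tid, v in zip(matrix.sts_ids, sts_stat) if v < t_lo or v > t_hi
    ]
    return matrix.drop(samples=bad_samples, sts=bad_sts), bad_samples, bad_sts


def median_depth_filter(
    matrix: DepthMatrix, params: QCParams = QCParams()
) -> tuple[DepthMatrix, list[str]]:
    """Remove STSs whose raw median depth across samples is ``< cutoff``.

    A median exactly at the cutoff is kept.
    """
    if matrix.normalized:
        raise ContractError("median_depth_filter expects a raw depth matrix")
    if matrix.n_samples == 0 or matrix.n_sts == 0:
        return matrix, []
    medians = np.median(matrix.values(), axis=0)
    bad = [
        tid
        for tid, m in zip(matrix.sts_ids, medians)
        if m < params.median_depth_cutoff
    ]
    return matrix.drop(sts=bad), bad


def normalize(matrix: DepthMatrix) -> DepthMatrix:
    """Divide each entry by its sample's mean depth over the current STSs.

    Every row of the result has mean exactly 1. Normalizing a normalized
    matrix is the identity.
    """
    depth = matrix.values()
    means = depth.mean(axis=1)
    zero = np.flatnonzero(means == 0)
    if zero.size:
        bad = matrix.sample_ids[zero[0]]
        raise ValidationError(f"sample {bad!r} has zero mean depth; cannot normalize")
    frame = matrix.frame.div(pd.Series(means, index=matrix.frame.index), axis=0)
    return DepthMatrix(frame, normalized=True)


def sd_filter(
    matrix: DepthMatrix, params: QCParams = QCParams()
) -> tuple[DepthMatrix, list[str]]:
    """Remove samples whose SD of normalized depth across STSs is ``> cutoff``.

    Uses the n-1 (sample) denominator; a SD exactly at the cutoff is kept.
    """
    if not matrix.normalized:
        raise ContractError("sd_filter expects a normalized depth matrix")
    sds = matrix.frame.std(axis=1, ddof=1).to_numpy()
    bad = [sid for sid, s in zip(matrix.sample_ids, sds) if s > params.sd_cutoff]
    return matrix.drop(samples=bad), bad


def run_qc(
    matrix: DepthMatrix, params: QCParams = QCParams()
) -> tuple[DepthMatrix, QCReport]:
    """Run the full cascade and return (qualified normalized matrix, report).

    The raw-scale stages (IQR outliers, median-depth cutoff) are screens for
    capture and library artefacts; when the input is already normalized they
    are skipped, which makes the cascade idempotent on its own output.
    """
    report = QCReport(
        initial_sts=matrix.n_sts,
        initial_samples=matrix.n_samples,
        removed_ids={
            "iqr_samples": [],
            "iqr_sts": [],
            "depth_cutoff_sts": [],
            "sd_samples": [],
        },
    )
    current = matrix
    if not matrix.normalized:
        current, bad_samples, bad_sts = iqr_outlier_filter(current, params)
        report.iqr_removed_samples = len(bad_samples)
        report.iqr_removed_sts = len(bad_sts)
        report.removed_ids["iqr_samples"] = bad_samples
        report.removed_ids["iqr_sts"] = bad_sts
        current, bad_sts = median_depth_filter(current, params)
        report.depth_cutoff_removed_sts = len(bad_sts)
        report.removed_ids["depth_cutoff_sts"] = bad_sts
    current = normalize(current)
    current, bad_samples = sd_filter(current, params)
    report.sd_removed_samples = len(bad_samples)
    report.removed_ids["sd_samples"] = bad_samples
    return current, report
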