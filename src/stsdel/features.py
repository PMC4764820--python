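"""The three depth-derived predictors computed per (sample, STS) pair.

All features operate on the *normalized* depth ``d_ij`` (QC output):

* ``f1`` — log standard-normal density of the z-score
  ``(d_ij - mu_j) / sigma_j``, where ``mu_j``/``sigma_j`` are the mean and SD
  of STS j across qualified samples. A log lower-tail probability variant is
  available via ``kind="tail"``.
* ``f2`` — ``d_ij / rmd_j``, the ratio to the STS's median across samples.
* ``f3`` — ``d_ij / smd_i``, the ratio to the sample's median across STSs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from stsdel.errors import ContractError, ValidationError
from stsdel.qc import DepthMatrix

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

FEATURE_COLUMNS = ("f1", "f2", "f3")


def sts_stats(matrix: DepthMatrix) -> pd.DataFrame:
    """Per-STS mean, SD (n-1 denominator) and median of normalized depth.

    Returns a frame indexed by sts_id with columns ``mu``, ``sigma``, ``rmd``
    and a boolean ``degenerate`` flag for zero-variance STSs.
    """
    if not matrix.normalized:
        raise ContractError("sts_stats expects a normalized, QC-passed matrix")
    depth = matrix.values()
    stats = pd.DataFrame(
        {
            "mu": depth.mean(axis=0),
            "sigma": depth.std(axis=0, ddof=1),
            "rmd": np.median(depth, axis=0),
        },
        index=pd.Index(matrix.sts_ids, name="sts_id"),
    )
    stats["degenerate"] = stats["sigma"] == 0.0
    return stats


def sample_stats(matrix: DepthMatrix) -> pd.Series:
    """Per-sample median of normalized depth across STSs (SMD)."""
    if not matrix.normalized:
        raise ContractError("sample_stats expects a normalized matrix")
    return pd.Series(
        np.median(matrix.values(), axis=1),
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        name="smd",
    )


@dataclass
class FeatureMatrix:
    """Long-format predictors: one row per qualified (sample, STS) pair."""

    table: pd.DataFrame  # columns: sample_id, sts_id, f1, f2, f3
    kind: str = "density"
    excluded_sts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"sample_id", "sts_id", *FEATURE_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"feature table missing columns {sorted(missing)}")
        vals = self.table[list(FEATURE_COLUMNS)].to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("feature table contains non-finite values")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kind: str = "density") -> "FeatureMatrix":
        table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sts_id": str})
        return cls(table, kind=kind)

    def X(self) -> np.ndarray:
        return self.table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def log_normal_score(z: np.ndarray, kind: str = "density") -> np.ndarray:
    """log phi(z) (default) or log Phi(z) of the standardized depth."""
    z = np.asarray(z, dtype=float)
    if kind == "density":
        return -LOG_SQRT_2PI - 0.5 * z * z
    if kind == "tail":
        return norm.logcdf(z)
    raise ValidationError(f"unknown f1 kind {kind!r}; use 'density' or 'tail'")


def compute_features(
    matrix: DepthMatrix,
    stats: pd.DataFrame | None = None,
    kind: str = "density",
) -> FeatureMatrix:
    """Compute f1/f2/f3 for every qualified (sample, STS) pair.

    Degenerate STSs (sigma = 0) carry no classification signal and are
    excluded with a warning; a sample whose median normalized depth is zero
    is an error (its f3 denominator vanishes).
    """
    if stats is None:
        stats = sts_stats(matrix)
    missing = set(matrix.sts_ids) - set(stats.index)
    if missing:
        raise ContractError(
            f"stats were not computed from this matrix; missing {sorted(missing)[:3]}"
        )
    degenerate = [t for t in matrix.sts_ids if bool(stats.loc[t, "degenerate"])]
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance STS(s) from features: "
            f"{degenerate[:5]}",
            stacklevel=2,
        )
    keep = [t for t in matrix.sts_ids if t not in set(degenerate)]
    depth = matrix.frame[keep].to_numpy(dtype=float)

    smd = sample_stats(matrix)
    zero_smd = smd.index[smd.to_numpy() == 0.0]
    if len(zero_smd):
        raise ValidationError(
            f"sample {zero_smd[0]!r} has zero median normalized depth (SMD)"
        )

    mu = stats.loc[keep, "mu"].to_numpy()
    sigma = stats.loc[keep, "sigma"].to_numpy()
    rmd = stats.loc[keep, "rmd"].to_numpy()
    z = (depth - mu) / sigma
    f1 = log_normal_score(z, kind=kind)
    f2 = depth / rmd
    f3 = depth / smd.to_numpy()[:, None]

    n_samples, n_sts = depth.shape
    table = pd.DataFrame(
        {
            "sample_id": np.repeat(matrix.sample_ids, n_sts),
            "sts_id": np.tile(keep, n_samples),
            "f1": f1.ravel(),
            "f2": f2.ravel(),
            "f3": f3.ravel(),
        }
    )
    return FeatureMatrix(table, kind=kind, excluded_sts=tuple(degenerate))
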