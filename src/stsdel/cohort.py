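"""Cohort-level summaries and tests: per-group deletion statistics,
frequency/recurrence spectra and annotation-category enrichment.

Conventions used for every reported figure:

* one-decimal means and percentages are rounded half-up;
* fold changes are ratios of the already-rounded means, rounded again;
* chi-square tests use the Pearson statistic without continuity correction
  (a Yates-corrected variant is available via ``correction=True``);
* unique deletions are keyed by STS id before merging and by exact
  member-STS set after merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, kruskal

from stsdel._round import round_half_up
from stsdel.catalog import STSCatalog
from stsdel.errors import ValidationError
from stsdel.merge import DeletionInterval
from stsdel.svm import DELETED, CallMatrix

#: Fig-4-style annotation categories; "intragenic" pools the gene-overlapping ones
ENRICHMENT_CATEGORIES = ("coding", "UTR", "intron", "intragenic", "intergenic")


def mean_per_carrier(total: int, carriers: int) -> float | None:
    """Mean events per carrying individual, one decimal half-up; None if no
    carriers (undefined, never reported as zero)."""
    if carriers == 0:
        return None
    return round_half_up(total / carriers, 1)


def fold_ratio(numerator_mean: float, denominator_mean: float) -> float:
    """Fold change between two already-rounded means, one decimal half-up."""
    if denominator_mean == 0:
        raise ValidationError("fold ratio undefined for zero denominator")
    return round_half_up(numerator_mean / denominator_mean, 1)


def carrier_frequency_pct(carriers: int, n_samples: int) -> float:
    """Carrier frequency as a one-decimal half-up percentage."""
    if n_samples <= 0:
        raise ValidationError("cohort size must be positive")
    return round_half_up(100.0 * carriers / n_samples, 1)


@dataclass
class GroupSummary:
    """Per-group deletion bookkeeping with derived one-decimal means."""

    group: str
    n_samples: int
    n_deleted_individuals: int
    n_total_deletions: int
    n_unique_deleted_sts: int
    n_post_merge_unique: int
    sd_deletions_per_deleted_individual: float | None = None
    sd_unique_per_deleted_individual: float | None = None
    sd_individuals_per_unique_deletion: float | None = None

    def __post_init__(self) -> None:
        if self.n_deleted_individuals > self.n_samples:
            raise ValidationError("more deletion carriers than samples")

    @property
    def mean_deletions_per_deleted_individual(self) -> float | None:
        return mean_per_carrier(self.n_total_deletions, self.n_deleted_individuals)

    @property
    def mean_unique_per_deleted_individual(self) -> float | None:
        return mean_per_carrier(self.n_unique_deleted_sts, self.n_deleted_individuals)

    @property
    def mean_individuals_per_unique_deletion(self) -> float | None:
        return mean_per_carrier(self.n_total_deletions, self.n_unique_deleted_sts)

    @property
    def pct_deleted_individuals(self) -> float:
        return carrier_frequency_pct(self.n_deleted_individuals, self.n_samples)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_samples": self.n_samples,
            "n_deleted_individuals": self.n_deleted_individuals,
            "pct_deleted_individuals": self.pct_deleted_individuals,
            "n_total_deletions": self.n_total_deletions,
            "n_unique_deleted_sts": self.n_unique_deleted_sts,
            "n_post_merge_unique": self.n_post_merge_unique,
            "mean_deletions_per_deleted_individual": self.mean_deletions_per_deleted_individual,
            "mean_unique_per_deleted_individual": self.mean_unique_per_deleted_individual,
            "mean_individuals_per_unique_deletion": self.mean_individuals_per_unique_deletion,
            "sd_deletions_per_deleted_individual": self.sd_deletions_per_deleted_individual,
            "sd_unique_per_deleted_individual": self.sd_unique_per_deleted_individual,
            "sd_individuals_per_unique_deletion": self.sd_individuals_per_unique_deletion,
        }


def _per_sample_deletion_counts(calls: CallMatrix, samples: list[str]) -> pd.Series:
    deleted = calls.table[
        (calls.table["state"] == DELETED) & calls.table["sample_id"].isin(samples)
    ]
    counts = deleted.groupby("sample_id").size()
    return counts.reindex(samples, fill_value=0)


def _recurrence_counts(calls: CallMatrix, samples: list[str]) -> pd.Series:
    """Per unique deleted STS, how many of the group's samples carry it."""
    deleted = calls.table[
        (calls.table["state"] == DELETED) & calls.table["sample_id"].isin(samples)
    ]
    return deleted.groupby("sts_id")["sample_id"].nunique()


def summarize_group(
    calls: CallMatrix,
    merged: dict[str, list[DeletionInterval]],
    metadata: pd.DataFrame,
    group: str,
) -> GroupSummary:
    """Compute the full :class:`GroupSummary` for one cohort group."""
    samples = list(
        metadata.loc[metadata["group"] == group, "sample_id"].astype(str)
    )
    if not samples:
        raise ValidationError(f"unknown or empty group {group!r}")
    per_sample = _per_sample_deletion_counts(calls, samples)
    recurrence = _recurrence_counts(calls, samples)
    carriers = per_sample[per_sample > 0]
    unique_per_carrier = None
    sd_del = sd_rec = None
    if len(carriers) > 1:
        sd_del = float(np.std(carriers, ddof=1))
    if len(recurrence) > 1:
        sd_rec = float(np.std(recurrence, ddof=1))
    deleted = calls.table[
        (calls.table["state"] == DELETED) & calls.table["sample_id"].isin(samples)
    ]
    uniq_by_sample = deleted.groupby("sample_id")["sts_id"].nunique()
    if len(uniq_by_sample) > 1:
        unique_per_carrier = float(np.std(uniq_by_sample, ddof=1))
    post_merge = len(
        {iv.key() for s in samples for iv in merged.get(s, [])}
    )
    return GroupSummary(
        group=group,
        n_samples=len(samples),
        n_deleted_individuals=int((per_sample > 0).sum()),
        n_total_deletions=int(per_sample.sum()),
        n_unique_deleted_sts=int(len(recurrence)),
        n_post_merge_unique=post_merge,
        sd_deletions_per_deleted_individual=sd_del,
        sd_unique_per_deleted_individual=unique_per_carrier,
        sd_individuals_per_unique_deletion=sd_rec,
    )


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; returns (statistic, p).

    Degenerate margins (a zero row or column) raise; callers should skip the
    test with a reason. A table with zero statistic returns p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("chi_square_2x2 needs a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("degenerate margin (zero row/column total)")
    stat, p, _, _ = chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def compare_groups(
    calls: CallMatrix,
    metadata: pd.DataFrame,
    group_a: str = "case",
    group_b: str = "control",
    correction: bool = False,
) -> pd.DataFrame:
    """The four headline between-group tests.

    chi-square: deleted-vs-not individuals; unique-deleted vs other qualified
    STSs. Kruskal-Wallis: per-carrier deletion counts; per-unique-deletion
    recurrence counts. Degenerate inputs yield a skipped row with a reason.
    """
    rows = []
    samples = {
        g: list(metadata.loc[metadata["group"] == g, "sample_id"].astype(str))
        for g in (group_a, group_b)
    }
    per_sample = {g: _per_sample_deletion_counts(calls, s) for g, s in samples.items()}
    recurrence = {g: _recurrence_counts(calls, s) for g, s in samples.items()}
    all_sts = calls.table["sts_id"].nunique()

    def add(test, quantity, stat, p, note=""):
        rows.append(
            {"test": test, "quantity": quantity, "statistic": stat, "p_value": p, "note": note}
        )

    carriers = {g: int((c > 0).sum()) for g, c in per_sample.items()}
    table = [
        [carriers[group_a], len(samples[group_a]) - carriers[group_a]],
        [carriers[group_b], len(samples[group_b]) - carriers[group_b]],
    ]
    try:
        stat, p = chi_square_2x2(table, correction)
        add("chi_square", "deleted_individuals", stat, p)
    except ValidationError as exc:
        add("chi_square", "deleted_individuals", math.nan, math.nan, str(exc))

    uniq = {g: len(r) for g, r in recurrence.items()}
    table = [
        [uniq[group_a], all_sts - uniq[group_a]],
        [uniq[group_b], all_sts - uniq[group_b]],
    ]
    try:
        stat, p = chi_square_2x2(table, correction)
        add("chi_square", "unique_deleted_sts", stat, p)
    except ValidationError as exc:
        add("chi_square", "unique_deleted_sts", math.nan, math.nan, str(exc))

    for quantity, vectors in (
        ("deletions_per_carrier", {g: c[c > 0].to_numpy() for g, c in per_sample.items()}),
        ("recurrence_per_unique_deletion", {g: r.to_numpy() for g, r in recurrence.items()}),
    ):
        va, vb = vectors[group_a], vectors[group_b]
        if len(va) == 0 or len(vb) == 0:
            add("kruskal_wallis", quantity, math.nan, math.nan, "empty group vector")
            continue
        try:
            with np.errstate(invalid="ignore"):
                stat, p = kruskal(va, vb)
            if math.isnan(stat):  # complete ties: no ranks to compare
                add("kruskal_wallis", quantity, math.nan, math.nan, "all values tied")
            else:
                add("kruskal_wallis", quantity, float(stat), float(p))
        except ValueError as exc:  # all values identical
            add("kruskal_wallis", quantity, math.nan, math.nan, str(exc))
    return pd.DataFrame(rows)


def deletion_spectra(
    calls: CallMatrix, metadata: pd.DataFrame
) -> dict[str, dict[str, pd.Series]]:
    """Per-group histograms: deletions per individual and recurrence per
    unique deleted STS."""
    out: dict[str, dict[str, pd.Series]] = {}
    for group in dict.fromkeys(metadata["group"].astype(str)):
        samples = list(
            metadata.loc[metadata["group"] == group, "sample_id"].astype(str)
        )
        per_sample = _per_sample_deletion_counts(calls, samples)
        recurrence = _recurrence_counts(calls, samples)
        out[group] = {
            "per_individual": per_sample.value_counts().sort_index(),
            "recurrence": recurrence.value_counts().sort_index(),
        }
    return out


def annotation_enrichment(
    unique_deleted: dict[str, set[str]],
    catalog: STSCatalog,
    group_a: str = "case",
    group_b: str = "control",
    correction: bool = False,
) -> pd.DataFrame:
    """Per annotation category, 2x2 chi-square of unique deleted STS counts.

    ``unique_deleted`` maps group -> set of unique deleted STS ids. The
    "intragenic" category pools coding, UTR and intron. Categories absent
    from the catalog produce a zero row with the test skipped.
    """
    for g in (group_a, group_b):
        if g not in unique_deleted:
            raise ValidationError(f"missing group {g!r}")
        unknown = unique_deleted[g] - set(catalog.sts_ids)
        if unknown:
            raise ValidationError(f"deleted STS not in catalog: {sorted(unknown)[:5]}")

    def in_category(sts_id: str, category: str) -> bool:
        ann = catalog[sts_id].annotation
        if category == "intragenic":
            return ann in ("coding", "UTR", "intron")
        return ann == category

    rows = []
    na, nb = len(unique_deleted[group_a]), len(unique_deleted[group_b])
    catalog_has = {
        cat: any(in_category(t, cat) for t in catalog.sts_ids)
        for cat in ENRICHMENT_CATEGORIES
    }
    for cat in ENRICHMENT_CATEGORIES:
        a = sum(in_category(t, cat) for t in unique_deleted[group_a])
        b = sum(in_category(t, cat) for t in unique_deleted[group_b])
        row = {
            "category": cat,
            f"{group_a}_count": a,
            f"{group_b}_count": b,
            "statistic": math.nan,
            "p_value": math.nan,
            "note": "",
        }
        if not catalog_has[cat]:
            row["note"] = "category absent from catalog"
        else:
            try:
                stat, p = chi_square_2x2([[a, na - a], [b, nb - b]], correction)
                row["statistic"], row["p_value"] = stat, p
            except ValidationError as exc:
                row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
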