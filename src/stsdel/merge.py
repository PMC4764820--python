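"""Connect per-STS deletion calls into genomic deletion intervals.

Two consecutive deleted STSs are joined iff their gap (end-to-start) is below
``max_gap`` (default 100 kb) AND every catalog STS strictly between them is
either itself called deleted or is a non-deleted multi-copy STS. A
non-deleted single-copy STS always breaks the run: multi-copy sites may lose
copies without a depth dropout, single-copy sites may not.

Each maximal run becomes one :class:`DeletionInterval` with a minimal (inner)
extent spanned by the outermost deleted members and a maximal (outer) extent
bounded by the nearest flanking non-deleted STS or the merge-window edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from stsdel.catalog import STSCatalog, STSRecord
from stsdel.errors import LookupError_, ValidationError
from stsdel.svm import DELETED, CallMatrix


@dataclass(frozen=True)
class MergeParams:
    max_gap: int = 100_000

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValidationError("max_gap must be positive")


@dataclass
class DeletionInterval:
    """One merged deletion in one sample.

    ``inner_*`` is the minimal extent (outermost deleted STSs); ``outer_*``
    the maximal extent (flanking non-deleted STSs or window edge).
    """

    sample_id: str
    chrom: str
    inner_start: int
    inner_end: int
    outer_start: int
    outer_end: int
    member_sts: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.outer_start <= self.inner_start < self.inner_end <= self.outer_end):
            raise ValidationError(
                f"interval {self.sample_id}:{self.member_sts}: inner extent "
                "must be contained in outer extent"
            )
        if not self.member_sts:
            raise ValidationError("deletion interval must have >= 1 member STS")

    @property
    def n_sts(self) -> int:
        return len(self.member_sts)

    def key(self) -> tuple[str, ...]:
        """Identity of the merged deletion: its member-STS set."""
        return tuple(sorted(self.member_sts))


def _joinable(
    a: STSRecord, b: STSRecord, deleted: set[str], catalog: STSCatalog, max_gap: int
) -> bool:
    if a.chrom != b.chrom:
        return False
    if b.start - a.end >= max_gap:
        return False
    for rec in catalog.neighbors_between(a.sts_id, b.sts_id):
        if rec.sts_id in deleted:
            continue
        if not rec.is_multi_copy():
            return False
    return True


def merge_sample(
    deleted_sts: Iterable[str],
    catalog: STSCatalog,
    params: MergeParams = MergeParams(),
    sample_id: str = "sample",
) -> list[DeletionInterval]:
    """Merge one sample's deleted STS ids into deletion intervals."""
    deleted = set(deleted_sts)
    unknown = deleted - set(catalog.sts_ids)
    if unknown:
        raise LookupError_(f"deleted STS not in catalog: {sorted(unknown)[:5]}")
    records = [r for r in catalog if r.sts_id in deleted]
    if not records:
        return []

    runs: list[list[STSRecord]] = [[records[0]]]
    for rec in records[1:]:
        if _joinable(runs[-1][-1], rec, deleted, catalog, params.max_gap):
            runs[-1].append(rec)
        else:
            runs.append([rec])

    intervals = []
    for run in runs:
        inner_start, inner_end = run[0].start, run[-1].end
        chrom = run[0].chrom
        upstream = [
            r.end
            for r in catalog
            if r.chrom == chrom
            and r.end <= inner_start
            and r.sts_id not in deleted
            and r.end >= inner_start - params.max_gap
        ]
        downstream = [
            r.start
            for r in catalog
            if r.chrom == chrom
            and r.start >= inner_end
            and r.sts_id not in deleted
            and r.start <= inner_end + params.max_gap
        ]
        outer_start = max(upstream) if upstream else max(inner_start - params.max_gap, 0)
        outer_end = min(downstream) if downstream else inner_end + params.max_gap
        intervals.append(
            DeletionInterval(
                sample_id=sample_id,
                chrom=chrom,
                inner_start=inner_start,
                inner_end=inner_end,
                outer_start=outer_start,
                outer_end=outer_end,
                member_sts=tuple(r.sts_id for r in run),
            )
        )
    return intervals


def merge_calls(
    calls: CallMatrix, catalog: STSCatalog, params: MergeParams = MergeParams()
) -> dict[str, list[DeletionInterval]]:
    """Merge every sample of a call matrix; returns sample_id -> intervals."""
    out: dict[str, list[DeletionInterval]] = {}
    deleted = calls.table[calls.table["state"] == DELETED]
    for sample_id, group in deleted.groupby("sample_id", sort=False):
        out[str(sample_id)] = merge_sample(
            group["sts_id"], catalog, params, sample_id=str(sample_id)
        )
    return out


def unique_deletion_census(
    calls: CallMatrix,
    catalog: STSCatalog,
    metadata: pd.DataFrame,
    params: MergeParams = MergeParams(),
) -> dict[str, dict[str, int]]:
    """Per-group unique deletion counts before and after merging.

    Pre-merge: distinct STS ids deleted in >= 1 sample of the group.
    Post-merge: distinct merged intervals keyed by exact member-STS set.
    """
    groups = dict(zip(metadata["sample_id"].astype(str), metadata["group"].astype(str)))
    unknown = set(calls.table["sample_id"].astype(str)) - set(groups)
    if unknown:
        raise ValidationError(f"samples without group label: {sorted(unknown)[:5]}")
    merged = merge_calls(calls, catalog, params)
    census: dict[str, dict[str, int]] = {}
    for group in dict.fromkeys(groups.values()):
        members = [s for s, g in groups.items() if g == group]
        deleted = calls.table[
            (calls.table["state"] == DELETED)
            & calls.table["sample_id"].isin(members)
        ]
        pre = deleted["sts_id"].nunique()
        post = len(
            {iv.key() for s in members for iv in merged.get(s, [])}
        )
        census[group] = {"pre_merge": int(pre), "post_merge": post}
    return census


def intervals_to_bed(intervals: Iterable[DeletionInterval]) -> str:
    """BED6+ export: outer extent as the interval, inner extent and members
    as extra columns."""
    lines = []
    for k, iv in enumerate(intervals):
        name = f"{iv.sample_id}:{k}"
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.outer_start),
                    str(iv.outer_end),
                    name,
                    str(iv.n_sts),
                    ".",
                    str(iv.inner_start),
                    str(iv.inner_end),
                    ",".join(iv.member_sts),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
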