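import itertools

import numpy as np
import pandas as pd
import pytest

from stsdel.catalog import STSCatalog, STSRecord
from stsdel.errors import LookupError_
from stsdel.merge import (
    DeletionInterval,
    MergeParams,
    intervals_to_bed,
    merge_calls,
    merge_sample,
    unique_deletion_census,
)
from stsdel.svm import CallMatrix


def cat(*records) -> STSCatalog:
    return STSCatalog(list(records))


def rec(sts_id, start, end, copy_class="single"):
    return STSRecord(sts_id, "chrY", start, end, copy_class)


def brute_force_merge(deleted_ids, catalog, max_gap):
    """Independent oracle: pairwise joinability matrix over consecutive
    deleted records + transitive closure by explicit union passes."""
    deleted = set(deleted_ids)
    recs = [r for r in catalog if r.sts_id in deleted]
    if not recs:
        return []
    joins = []
    for a, b in zip(recs, recs[1:]):
        ok = (b.start - a.end) < max_gap
        if ok:
            for r in catalog:
                if r.start >= a.end and r.end <= b.start and r.sts_id not in deleted:
                    if r.copy_class != "multi":
                        ok = False
                        break
        joins.append(ok)
    runs, current = [], [recs[0]]
    for joined, r in zip(joins, recs[1:]):
        if joined:
            current.append(r)
        else:
            runs.append(current)
            current = [r]
    runs.append(current)
    return [tuple(r.sts_id for r in run) for run in runs]


class TestMergeRules:
    def test_small_gap_joined(self):
        c = cat(rec("a", 10_000, 10_200), rec("b", 60_000, 60_200))
        out = merge_sample(["a", "b"], c)
        assert len(out) == 1
        assert out[0].member_sts == ("a", "b")
        assert out[0].n_sts == 2

    def test_large_gap_split(self):
        c = cat(rec("a", 10_000, 10_200), rec("b", 160_200, 160_400))
        out = merge_sample(["a", "b"], c)
        assert len(out) == 2

    def test_gap_exactly_at_cutoff_splits(self):
        c = cat(rec("a", 0, 200), rec("b", 100_200, 100_400))
        assert len(merge_sample(["a", "b"], c)) == 2
        c = cat(rec("a", 0, 200), rec("b", 100_199, 100_399))
        assert len(merge_sample(["a", "b"], c)) == 1

    def test_non_deleted_multi_copy_skipped(self):
        c = cat(
            rec("a", 0, 200),
            rec("skip", 30_000, 30_200, copy_class="multi"),
            rec("b", 80_000, 80_200),
        )
        out = merge_sample(["a", "b"], c)
        assert len(out) == 1
        assert out[0].member_sts == ("a", "b")  # skipped STS is not a member

    def test_non_deleted_single_copy_breaks(self):
        c = cat(
            rec("a", 0, 200),
            rec("block", 30_000, 30_200),
            rec("b", 80_000, 80_200),
        )
        out = merge_sample(["a", "b"], c)
        assert len(out) == 2

    def test_deleted_multi_copy_is_full_member(self):
        c = cat(
            rec("a", 0, 200),
            rec("m", 30_000, 30_200, copy_class="multi"),
            rec("b", 80_000, 80_200),
        )
        out = merge_sample(["a", "m", "b"], c)
        assert len(out) == 1
        assert out[0].member_sts == ("a", "m", "b")

    def test_unknown_deleted_id(self):
        c = cat(rec("a", 0, 200))
        with pytest.raises(LookupError_, match="zzz"):
            merge_sample(["zzz"], c)


class TestBoundaries:
    def test_inner_extent_spans_outermost_members(self):
        c = cat(rec("a", 10_000, 10_200), rec("b", 60_000, 60_200))
        iv = merge_sample(["a", "b"], c)[0]
        assert iv.inner_start == 10_000
        assert iv.inner_end == 60_200

    def test_outer_bounded_by_flanking_non_deleted(self):
        c = cat(
            rec("left", 0, 500),
            rec("a", 10_000, 10_200),
            rec("b", 60_000, 60_200),
            rec("right", 70_000, 70_500),
        )
        iv = merge_sample(["a", "b"], c)[0]
        assert iv.outer_start == 500
        assert iv.outer_end == 70_000

    def test_outer_falls_back_to_window_edge(self):
        c = cat(rec("a", 500_000, 500_200))
        iv = merge_sample(["a"], c)[0]
        assert iv.outer_start == 400_000
        assert iv.outer_end == 600_200

    def test_outer_clamped_at_zero(self):
        c = cat(rec("a", 10_000, 10_200))
        iv = merge_sample(["a"], c)[0]
        assert iv.outer_start == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_random_small_catalogs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 31))
        gaps = rng.choice([5_000, 40_000, 90_000, 120_000], size=n)
        starts = np.cumsum(gaps)
        records = [
            rec(
                f"r{k}",
                int(starts[k]),
                int(starts[k] + 200),
                copy_class="multi" if rng.random() < 0.3 else "single",
            )
            for k in range(n)
        ]
        c = cat(*records)
        deleted = [f"r{k}" for k in range(n) if rng.random() < 0.4]
        got = [iv.member_sts for iv in merge_sample(deleted, c)]
        expected = brute_force_merge(deleted, c, 100_000)
        assert got == expected

    @pytest.mark.parametrize("trial", range(5))
    def test_partition_property(self, trial):
        rng = np.random.default_rng(100 + trial)
        starts = np.cumsum(rng.choice([5_000, 50_000, 150_000], size=25))
        c = cat(*[rec(f"r{k}", int(s), int(s) + 100) for k, s in enumerate(starts)])
        deleted = [f"r{k}" for k in range(25) if rng.random() < 0.5]
        out = merge_sample(deleted, c)
        members = [t for iv in out for t in iv.member_sts]
        assert sorted(members) == sorted(deleted)  # each deleted STS exactly once

    def test_monotone_in_max_gap(self):
        rng = np.random.default_rng(77)
        starts = np.cumsum(rng.choice([10_000, 60_000, 130_000], size=30))
        c = cat(*[rec(f"r{k}", int(s), int(s) + 100) for k, s in enumerate(starts)])
        deleted = [f"r{k}" for k in range(0, 30, 2)]
        counts = [
            len(merge_sample(deleted, c, MergeParams(max_gap=g)))
            for g in (20_000, 50_000, 100_000, 200_000, 10**7)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_idempotent_under_repetition(self):
        c = cat(rec("a", 0, 100), rec("b", 50_000, 50_100), rec("x", 300_000, 300_100))
        first = merge_sample(["a", "b", "x"], c)
        second = merge_sample(["a", "b", "x"], c)
        assert first == second


class TestCensus:
    def make_calls(self, rows):
        return CallMatrix(pd.DataFrame(rows, columns=["sample_id", "sts_id", "state"]))

    def test_contiguous_run_collapses(self):
        starts = [k * 20_000 for k in range(5)]
        c = cat(*[rec(f"r{k}", s, s + 100) for k, s in enumerate(starts)])
        calls = self.make_calls([("p1", f"r{k}", "deleted") for k in range(5)])
        meta = pd.DataFrame({"sample_id": ["p1"], "group": ["case"]})
        census = unique_deletion_census(calls, c, meta)
        assert census["case"] == {"pre_merge": 5, "post_merge": 1}

    def test_identical_deletions_deduplicated(self):
        c = cat(rec("r0", 0, 100))
        calls = self.make_calls(
            [("p1", "r0", "deleted"), ("p2", "r0", "deleted")]
        )
        meta = pd.DataFrame({"sample_id": ["p1", "p2"], "group": ["case", "case"]})
        census = unique_deletion_census(calls, c, meta)
        assert census["case"] == {"pre_merge": 1, "post_merge": 1}

    def test_case_shrinkage_exceeds_control(self):
        # long aggregated runs in cases, scattered singletons in controls:
        # merging collapses the case count, barely touches the control count
        from stsdel.simulate import SimScenario, simulate_cohort

        scenario = SimScenario(
            seed=13,
            n_cases=40,
            n_controls=40,
            n_sts=120,
            case_long_deletion_rate=0.6,
            case_singleton_mean=0.0,
            control_singleton_mean=1.5,
        )
        cohort = simulate_cohort(scenario)
        truth = cohort.truth.deleted.stack()
        truth.index.names = ["sample_id", "sts_id"]
        table = truth.reset_index()
        table["state"] = np.where(table[0], "deleted", "not_deleted")
        calls = CallMatrix(table[["sample_id", "sts_id", "state"]])
        census = unique_deletion_census(calls, cohort.catalog, cohort.metadata)
        case, ctrl = census["case"], census["control"]
        assert case["post_merge"] / case["pre_merge"] < ctrl["post_merge"] / ctrl["pre_merge"]


def test_bed_export_shape(default_result):
    sample = next(iter(default_result.intervals))
    text = intervals_to_bed(default_result.intervals[sample])
    for line in text.strip().split("\n"):
        fields = line.split("\t")
        assert len(fields) == 9
        assert int(fields[1]) <= int(fields[6]) < int(fields[7]) <= int(fields[2])
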