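import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from stsdel._round import round_half_up
from stsdel.catalog import STSCatalog, STSRecord
from stsdel.cohort import (
    annotation_enrichment,
    carrier_frequency_pct,
    chi_square_2x2,
    compare_groups,
    deletion_spectra,
    fold_ratio,
    mean_per_carrier,
    summarize_group,
)
from stsdel.errors import ValidationError
from stsdel.merge import merge_calls
from stsdel.simulate import SimScenario, simulate_cohort
from stsdel.svm import CallMatrix


def chi2_oracle(table):
    """Pearson statistic by explicit summation; p via erfc (df=1)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat, math.erfc(math.sqrt(stat / 2.0))


class TestDerivedMeans:
    def test_case_deletions_per_carrier(self):
        assert mean_per_carrier(1020, 87) == 11.7

    def test_control_deletions_per_carrier(self):
        assert mean_per_carrier(264, 71) == 3.7

    def test_case_unique_per_carrier(self):
        assert mean_per_carrier(481, 87) == 5.5

    def test_control_unique_per_carrier(self):
        assert mean_per_carrier(98, 71) == 1.4

    def test_case_individuals_per_unique(self):
        assert mean_per_carrier(1020, 481) == 2.1

    def test_control_individuals_per_unique(self):
        assert mean_per_carrier(264, 98) == 2.7

    def test_fold_ratio_of_rounded_means(self):
        assert fold_ratio(11.7, 3.7) == 3.2

    def test_no_carriers_undefined_not_zero(self):
        assert mean_per_carrier(0, 0) is None

    def test_carrier_frequencies(self):
        assert carrier_frequency_pct(54, 766) == 7.0
        assert carrier_frequency_pct(42, 683) == 6.1
        assert carrier_frequency_pct(87, 766) == 11.4
        assert carrier_frequency_pct(71, 683) == 10.4

    def test_rounding_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(3.15, 1) == 3.2
        assert round_half_up(2.649999, 1) == 2.6


class TestChiSquare:
    def test_identical_groups_p_one(self):
        stat, p = chi_square_2x2([[50, 50], [50, 50]])
        assert stat == 0.0
        assert p == 1.0

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])

    @pytest.mark.parametrize("trial", range(30))
    def test_oracle_equivalence_small_tables(self, trial):
        rng = np.random.default_rng(trial)
        while True:
            table = rng.integers(0, 14, size=(2, 2))
            if table.sum() <= 50 and (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
                break
        stat, p = chi_square_2x2(table)
        stat_o, p_o = chi2_oracle(table)
        assert stat == pytest.approx(stat_o, rel=1e-12)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_yates_variant_exposed(self):
        table = [[10, 20], [20, 10]]
        stat_plain, _ = chi_square_2x2(table, correction=False)
        stat_yates, _ = chi_square_2x2(table, correction=True)
        assert stat_yates < stat_plain


def truth_calls(cohort) -> CallMatrix:
    truth = cohort.truth.deleted.stack()
    truth.index.names = ["sample_id", "sts_id"]
    table = truth.reset_index()
    table["state"] = np.where(table[0], "deleted", "not_deleted")
    return CallMatrix(table[["sample_id", "sts_id", "state"]])


class TestSummaries:
    def test_empty_call_matrix(self):
        calls = CallMatrix(
            pd.DataFrame(
                [("p1", "x", "not_deleted")], columns=["sample_id", "sts_id", "state"]
            )
        )
        meta = pd.DataFrame({"sample_id": ["p1"], "group": ["case"]})
        s = summarize_group(calls, {}, meta, "case")
        assert s.n_total_deletions == 0
        assert s.mean_deletions_per_deleted_individual is None

    def test_counts_reconcile_with_raw_vectors(self, default_cohort, default_result):
        meta = default_cohort.metadata
        merged = default_result.intervals
        for group in ("case", "control"):
            s = summarize_group(default_result.calls, merged, meta, group)
            samples = set(meta.loc[meta["group"] == group, "sample_id"])
            deleted = default_result.calls.table.query("state == 'deleted'")
            deleted = deleted[deleted["sample_id"].isin(samples)]
            assert s.n_total_deletions == len(deleted)
            assert s.n_deleted_individuals == deleted["sample_id"].nunique()
            assert s.n_unique_deleted_sts == deleted["sts_id"].nunique()
            if s.n_deleted_individuals:
                assert s.mean_deletions_per_deleted_individual == round_half_up(
                    s.n_total_deletions / s.n_deleted_individuals, 1
                )

    def test_unknown_group(self, default_cohort, default_result):
        with pytest.raises(ValidationError):
            summarize_group(
                default_result.calls, {}, default_cohort.metadata, "martians"
            )


class TestCompareGroups:
    def test_identical_groups_chi2_zero(self):
        rows = []
        for g, prefix in (("case", "p"), ("control", "c")):
            for i in range(10):
                state = "deleted" if i < 5 else "not_deleted"
                rows.append((f"{prefix}{i}", "sts1", state))
        calls = CallMatrix(pd.DataFrame(rows, columns=["sample_id", "sts_id", "state"]))
        meta = pd.DataFrame(
            {
                "sample_id": [r[0] for r in rows],
                "group": ["case"] * 10 + ["control"] * 10,
            }
        )
        out = compare_groups(calls, meta).set_index("quantity")
        row = out.loc["deleted_individuals"]
        assert row["statistic"] == 0.0
        assert row["p_value"] == 1.0

    def test_kruskal_matches_rank_arithmetic(self):
        # {1,1,1,2} vs {3,3,3,3}: tie-corrected H = 6.4 by hand
        rows = []
        for i, k in enumerate([1, 1, 1, 2]):
            for j in range(k):
                rows.append((f"p{i}", f"sts{j}", "deleted"))
        for i, k in enumerate([3, 3, 3, 3]):
            for j in range(k):
                rows.append((f"c{i}", f"sts{j}", "deleted"))
        calls = CallMatrix(pd.DataFrame(rows, columns=["sample_id", "sts_id", "state"]))
        meta = pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(4)] + [f"c{i}" for i in range(4)],
                "group": ["case"] * 4 + ["control"] * 4,
            }
        )
        out = compare_groups(calls, meta).set_index("quantity")
        assert out.loc["deletions_per_carrier", "statistic"] == pytest.approx(6.4)

    def test_burden_contrast_power(self):
        # with a 3x-ish planted case burden the carrier-count chi-square
        # should fire on nearly every seed
        hits = 0
        for seed in range(10):
            cohort = simulate_cohort(
                SimScenario(seed=seed, n_cases=60, n_controls=60, n_sts=60)
            )
            calls = truth_calls(cohort)
            out = compare_groups(calls, cohort.metadata).set_index("quantity")
            if out.loc["unique_deleted_sts", "p_value"] < 0.01:
                hits += 1
        assert hits >= 9


class TestSpectra:
    def test_histograms_conserve_totals(self, default_cohort, default_result):
        spectra = deletion_spectra(default_result.calls, default_cohort.metadata)
        for group in ("case", "control"):
            meta = default_cohort.metadata
            n_samples = int((meta["group"] == group).sum())
            per_ind = spectra[group]["per_individual"]
            assert per_ind.sum() == n_samples
            deleted = default_result.calls.table.query("state == 'deleted'")
            samples = set(meta.loc[meta["group"] == group, "sample_id"])
            deleted = deleted[deleted["sample_id"].isin(samples)]
            rec = spectra[group]["recurrence"]
            assert rec.sum() == deleted["sts_id"].nunique()
            assert (rec.index * rec).sum() == len(
                deleted.drop_duplicates(["sample_id", "sts_id"])
            )

    def test_permutation_invariance(self, default_cohort, default_result):
        meta = default_cohort.metadata
        shuffled = meta.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = deletion_spectra(default_result.calls, meta)
        b = deletion_spectra(default_result.calls, shuffled)
        for g in a:
            assert a[g]["per_individual"].equals(b[g]["per_individual"])


class TestAnnotationEnrichment:
    def catalog_with(self, annotations):
        return STSCatalog(
            [
                STSRecord(
                    f"e{k}", "chrY", k * 1000, k * 1000 + 100, "single",
                    annotation=ann,
                    gene=None if ann == "intergenic" else f"G{k}",
                )
                for k, ann in enumerate(annotations)
            ]
        )

    def test_all_intergenic_skipped_or_p_one(self):
        cat = self.catalog_with(["intergenic"] * 10)
        unique = {"case": {"e0", "e1"}, "control": {"e2", "e3"}}
        out = annotation_enrichment(unique, cat).set_index("category")
        for cat_name in ("coding", "UTR", "intron", "intragenic"):
            row = out.loc[cat_name]
            assert row["note"] != "" or row["p_value"] == 1.0

    def test_planted_intragenic_contrast(self):
        # 100 unique STSs per group: cases 80% intragenic, controls 10%
        annotations = ["intron"] * 100 + ["intergenic"] * 100
        cat = self.catalog_with(annotations)
        case = {f"e{k}" for k in range(80)} | {f"e{k}" for k in range(100, 120)}
        control = {f"e{k}" for k in range(80, 90)} | {
            f"e{k}" for k in range(110, 200)
        }
        out = annotation_enrichment(
            {"case": case, "control": control}, cat
        ).set_index("category")
        assert out.loc["intragenic", "p_value"] < 0.001
        stat_o, p_o = chi2_oracle([[80, 20], [10, 90]])
        assert out.loc["intragenic", "statistic"] == pytest.approx(stat_o)

    def test_control_without_genic_deletions(self):
        annotations = ["coding"] * 5 + ["UTR"] * 5 + ["intergenic"] * 20
        cat = self.catalog_with(annotations)
        case = {"e0", "e5", "e10"}
        control = {"e12", "e15"}
        out = annotation_enrichment(
            {"case": case, "control": control}, cat
        ).set_index("category")
        assert out.loc["coding", "control_count"] == 0
        assert out.loc["UTR", "control_count"] == 0

    def test_counts_partition_unique_deletions(self, default_cohort, default_result):
        calls = default_result.calls.table
        meta = default_cohort.metadata
        unique = {}
        for g in ("case", "control"):
            samples = set(meta.loc[meta["group"] == g, "sample_id"])
            deleted = calls[(calls["state"] == "deleted") & calls["sample_id"].isin(samples)]
            unique[g] = set(deleted["sts_id"])
        out = annotation_enrichment(unique, default_cohort.catalog).set_index("category")
        for g in ("case", "control"):
            base = sum(
                out.loc[cat_name, f"{g}_count"]
                for cat_name in ("coding", "UTR", "intron", "intergenic")
            )
            assert base == len(unique[g])
            assert out.loc["intragenic", f"{g}_count"] == len(unique[g]) - out.loc[
                "intergenic", f"{g}_count"
            ]
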