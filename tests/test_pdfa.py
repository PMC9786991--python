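"""Balanced resampling, design-respecting permutation, and pDFA p-values."""

import numpy as np
import pandas as pd
import pytest

from panthoot.data import apply_inclusion_filters, published_counts_table
from panthoot.errors import DesignError
from panthoot.pdfa import (
    PDFAConfig,
    PDFADesign,
    PDFAResult,
    balance_split,
    permute_labels,
    run_pairwise_pdfa,
    run_pdfa,
)

from conftest import crossed_table, make_table, nested_table

CROSSED = PDFADesign(test_factor="context", control_factor="individual", design="crossed")
NESTED = PDFADesign(test_factor="community", control_factor="individual", design="nested")


class TestDesignValidation:
    def test_crossed_requires_control(self):
        with pytest.raises(DesignError):
            PDFADesign(test_factor="context", design="crossed")

    def test_restriction_only_with_nested(self):
        with pytest.raises(DesignError):
            PDFADesign(test_factor="x", control_factor="y",
                       restriction_factor="z", design="crossed")

    def test_crossed_empty_cell_detected(self):
        rows = [dict(individual="a", context="feed", f1=1.0)] * 4
        rows += [dict(individual="a", context="travel", f1=1.0)] * 4
        rows += [dict(individual="b", context="feed", f1=1.0)] * 4  # no travel
        t = make_table(rows, ["f1"])
        with pytest.raises(DesignError, match="cell"):
            CROSSED.validate(t.df)

    def test_nested_control_spanning_test_levels_rejected(self):
        rows = [dict(community="c1", individual="m1", f1=1.0)] * 3
        rows += [dict(community="c2", individual="m1", f1=1.0)] * 3
        t = make_table(rows, ["f1"])
        with pytest.raises(DesignError, match="span"):
            NESTED.validate(t.df)


class TestBalanceSplit:
    def test_crossed_uses_min_cell_per_control_level(self, rng):
        rows = [dict(individual="A", context="feed", f1=float(i)) for i in range(7)]
        rows += [dict(individual="A", context="travel", f1=float(i)) for i in range(3)]
        rows += [dict(individual="B", context="feed", f1=float(i)) for i in range(5)]
        rows += [dict(individual="B", context="travel", f1=float(i)) for i in range(5)]
        t = make_table(rows, ["f1"])
        sel, out = balance_split(t, CROSSED, rng)
        df = t.df.loc[sel]
        counts = df.groupby(["individual", "context"]).size()
        assert counts.loc[("A", "feed")] == 3 and counts.loc[("A", "travel")] == 3
        assert counts.loc[("B", "feed")] == 5 and counts.loc[("B", "travel")] == 5
        assert len(sel) + len(out) == t.n_calls

    def test_nested_uses_global_minimum_on_published_counts(self, rng):
        t, _ = apply_inclusion_filters(published_counts_table(), 8)
        sel, out = balance_split(t, NESTED, rng)
        per_ind = t.df.loc[sel].groupby("individual").size()
        assert (per_ind == 8).all()  # global per-individual minimum
        assert len(sel) == 8 * 18

    def test_all_cells_at_quota_leaves_nothing_out(self, rng):
        t = crossed_table(n_ind=4, calls_per_cell=(3, 3), seed=1)
        sel, out = balance_split(t, CROSSED, rng)
        assert len(out) == 0

    def test_quota_override(self, rng):
        t = crossed_table(n_ind=4, calls_per_cell=(5, 5), seed=1)
        sel, _ = balance_split(t, CROSSED, rng, n_select_per_cell=2)
        assert len(sel) == 4 * 2 * 2
        with pytest.raises(DesignError):
            balance_split(t, CROSSED, rng, n_select_per_cell=6)


class TestPermuteLabels:
    def test_nested_preserves_units_per_level_and_unity_of_units(self, rng):
        t = nested_table(ind_per_comm=(6, 5, 7), seed=2)
        observed_counts = t.df.groupby("community")["individual"].nunique().sort_index()
        for _ in range(25):
            perm = permute_labels(t, NESTED, rng)
            counts = perm.groupby("community")["individual"].nunique().sort_index()
            pd.testing.assert_series_equal(counts, observed_counts)
            # all calls of an individual share one (possibly new) label
            assert (perm.groupby("individual")["community"].nunique() == 1).all()

    def test_crossed_conserves_within_block_counts(self, rng):
        t = crossed_table(n_ind=1, calls_per_cell=(3, 3), seed=0)
        for _ in range(25):
            perm = permute_labels(t, CROSSED, rng)
            assert (perm["context"] == "feed").sum() == 3
            assert (perm["context"] == "travel").sum() == 3

    def test_restriction_confines_unit_reassignment(self, rng):
        t = nested_table(ind_per_comm=(3, 3), seed=3)
        t.df["site"] = np.where(t.df["community"] == "comm0", "siteA", "siteB")
        design = PDFADesign(
            test_factor="community",
            control_factor="individual",
            restriction_factor="site",
            design="nested",
        )
        for _ in range(10):
            perm = permute_labels(t, design, rng)
            # with one community per site, labels cannot move across sites
            pd.testing.assert_series_equal(perm["community"], t.df["community"])

    def test_identity_permutation_frequency_matches_combinatorics(self, rng):
        # one individual, 2 feed + 2 travel calls: P(identical labeling) =
        # 2!·2!/4! = 1/6 under uniform within-block permutation
        t = crossed_table(n_ind=1, calls_per_cell=(2, 2), seed=0)
        orig = t.df["context"].to_numpy()
        hits = sum(
            np.array_equal(permute_labels(t, CROSSED, rng)["context"].to_numpy(), orig)
            for _ in range(3000)
        )
        assert hits / 3000 == pytest.approx(1 / 6, abs=0.03)


class TestRunPDFA:
    def test_perfect_separation_gives_minimal_p(self):
        t = crossed_table(n_ind=5, calls_per_cell=(6, 6), effect=50.0,
                          seed=4, cell_jitter=3)
        res = run_pdfa(t, CROSSED, PDFAConfig(n_perm=100, seed=0))
        assert res.observed_accuracy_cv == 100.0
        assert res.p_cv == pytest.approx(1 / 100)

    def test_chance_level_under_null(self):
        t = crossed_table(n_ind=8, calls_per_cell=(8, 8), effect=0.0,
                          seed=5, cell_jitter=4)
        res = run_pdfa(t, CROSSED, PDFAConfig(n_perm=200, seed=1))
        assert res.expected_accuracy_cv == pytest.approx(50.0, abs=5.0)
        assert res.p_cv > 0.01  # no evidence of signal

    def test_p_bounded_below_by_one_over_nperm(self):
        t = crossed_table(n_ind=4, calls_per_cell=(4, 4), effect=10.0,
                          seed=6, cell_jitter=2)
        res = run_pdfa(t, CROSSED, PDFAConfig(n_perm=50, seed=2))
        assert 1 / 50 <= res.p_cv <= 1.0
        assert 1 / 50 <= res.p_selected <= 1.0

    def test_exact_reproducibility_under_fixed_seed(self):
        t = nested_table(ind_per_comm=(4, 4), seed=7)
        design = NESTED
        r1 = run_pdfa(t, design, PDFAConfig(n_perm=60, seed=9))
        r2 = run_pdfa(t, design, PDFAConfig(n_perm=60, seed=9))
        assert np.array_equal(r1.perm_accuracy_cv, r2.perm_accuracy_cv)
        assert r1.p_cv == r2.p_cv and r1.p_selected == r2.p_selected

    def test_degenerate_balance_flags_cv_unavailable(self):
        t = crossed_table(n_ind=4, calls_per_cell=(3, 3), seed=8)
        res = run_pdfa(t, CROSSED, PDFAConfig(n_perm=20, seed=3))
        assert not res.cv_available
        assert np.isnan(res.p_cv)

    def test_nested_permutation_never_splits_an_individual(self, rng):
        t = nested_table(ind_per_comm=(5, 4), seed=9)
        for _ in range(50):
            perm = permute_labels(t, NESTED, rng)
            assert (perm.groupby("individual")["community"].nunique() == 1).all()

    def test_non_finite_features_rejected(self):
        t = crossed_table(n_ind=4, calls_per_cell=(4, 4), seed=10)
        t.df.loc[0, "f1"] = np.nan
        with pytest.raises(ValueError):
            run_pdfa(t, CROSSED, PDFAConfig(n_perm=10, seed=0))


class TestPairwise:
    def test_enumerates_all_pairs(self):
        t = nested_table(ind_per_comm=(3, 3, 3), ind_effect=0.5, seed=11)
        pairs = [("comm0", "comm1"), ("comm0", "comm2"), ("comm1", "comm2")]
        results = run_pairwise_pdfa(
            t, "community", pairs, NESTED, PDFAConfig(n_perm=30, seed=4)
        )
        assert set(results) == set(pairs)
        assert all(isinstance(r, PDFAResult) for r in results.values())

    def test_pair_equals_manual_subset_run(self):
        t = nested_table(ind_per_comm=(3, 3, 3), seed=12)
        cfg = PDFAConfig(n_perm=40, seed=5)
        res_pair = run_pairwise_pdfa(
            t, "community", [("comm0", "comm2")], NESTED, cfg
        )[("comm0", "comm2")]
        sub = t.subset_rows(t.df["community"].isin(["comm0", "comm2"]).to_numpy())
        res_direct = run_pdfa(sub, NESTED, cfg)
        assert res_pair.p_cv == res_direct.p_cv
        assert np.array_equal(res_pair.perm_accuracy_cv, res_direct.perm_accuracy_cv)

    def test_unknown_level_rejected(self):
        t = nested_table(seed=13)
        with pytest.raises(ValueError):
            run_pairwise_pdfa(
                t, "community", [("comm0", "nope")], NESTED, PDFAConfig(n_perm=10)
            )
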