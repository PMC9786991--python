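"""Feature-table parsing, context resolution, and the inclusion filters."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from panthoot.data import (
    FeatureSetSpec,
    FeatureTable,
    apply_context_filters,
    apply_inclusion_filters,
    published_counts_table,
    read_feature_table,
    resolve_context,
    select_feature_set,
    spectrogram_resolution,
    write_feature_table,
)
from panthoot.errors import IntegrityError, SchemaError

from conftest import make_table


CSV_SMALL = textwrap.dedent(
    """\
    call_id,site,community,individual,context,dur,n_elem
    c1,gombe,kasekela,FU,feed,4.25,3
    c2,gombe,kasekela,FU,travel,5.5,
    c3,gombe,mitumba,EDG,feed,3.125,7
    """
)


class TestReadWrite:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "calls.csv"
        p.write_text(CSV_SMALL)
        t = read_feature_table(p)
        assert t.n_calls == 3
        assert t.feature_names == ["dur", "n_elem"]
        assert t.feature_family == {"dur": "continuous", "n_elem": "count"}

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "calls.csv"
        p.write_text(CSV_SMALL)
        t = read_feature_table(p)
        assert np.isnan(t.df.loc[t.df["call_id"] == "c2", "n_elem"].iloc[0])

    def test_round_trip_bit_exact_for_decimal_text(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text(CSV_SMALL)
        t = read_feature_table(p1)
        write_feature_table(t, p2)
        t2 = read_feature_table(p2)
        pd.testing.assert_frame_equal(t.df, t2.df)

    def test_missing_factor_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("call_id,individual,context,f1\nc1,m1,feed,1.0\n")
        with pytest.raises(SchemaError):
            read_feature_table(p)

    def test_duplicate_call_id_is_integrity_error(self):
        df = pd.DataFrame(
            {
                "call_id": ["c1", "c1"],
                "site": "s",
                "community": "c",
                "individual": "m",
                "context": "feed",
                "f1": [1.0, 2.0],
            }
        )
        with pytest.raises(IntegrityError):
            FeatureTable(df, ["f1"], {"f1": "continuous"})

    def test_sidecar_family_declaration(self, tmp_path):
        p = tmp_path / "calls.csv"
        p.write_text(CSV_SMALL)
        t = read_feature_table(p, families={"n_elem": "continuous"})
        assert t.feature_family["n_elem"] == "continuous"


class TestResolveContext:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ({"feed", "travel"}, "travel"),
            ({"rest"}, "rest"),
            ({"display", "rest", "feed"}, "feed"),
            ({"travel", "feed", "display", "rest"}, "travel"),
            (set(), "unknown"),
        ],
    )
    def test_priority_hierarchy(self, flags, expected):
        assert resolve_context(flags) == expected

    def test_case_insensitive(self):
        assert resolve_context({"Feed", "TRAVEL"}) == "travel"

    def test_unknown_tag_rejected(self):
        with pytest.raises(SchemaError):
            resolve_context({"grooming"})


class TestInclusionFilter:
    def test_threshold_boundary(self):
        rows = [dict(individual="a", f1=1.0) for _ in range(7)]
        rows += [dict(individual="b", f1=1.0) for _ in range(8)]
        t = make_table(rows, ["f1"])
        out, rep = apply_inclusion_filters(t, min_calls=8)
        assert out.individuals == ["b"]
        assert rep.n_input_calls == 15 and rep.n_output_calls == 8
        assert [e[0] for e in rep.excluded_individuals] == ["a"]

    def test_min_calls_one_is_identity(self):
        t = make_table([dict(individual="a", f1=1.0)], ["f1"])
        out, rep = apply_inclusion_filters(t, min_calls=1)
        assert out.n_calls == t.n_calls and rep.excluded_individuals == []

    def test_published_per_individual_totals(self):
        t = published_counts_table()
        out, _ = apply_inclusion_filters(t, min_calls=8)
        per_comm = out.df.groupby("community").size()
        assert per_comm["kasekela"] == 128
        assert per_comm["mitumba"] == 86
        assert per_comm["kanyawara"] == 111
        assert out.df[out.df["site"] == "gombe"].shape[0] == 214

    def test_idempotent(self):
        rows = [dict(individual=f"m{i}", f1=float(i)) for i in range(5)] + [
            dict(individual="m0", f1=9.0) for _ in range(9)
        ]
        t = make_table(rows, ["f1"])
        once, _ = apply_inclusion_filters(t, min_calls=8)
        twice, rep2 = apply_inclusion_filters(once, min_calls=8)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert rep2.n_dropped_calls == 0


class TestContextFilter:
    def _table(self):
        rows = []
        for ctx, n in [("feed", 3), ("travel", 3)]:
            rows += [dict(individual="ok", context=ctx, f1=1.0)] * n
        for ctx, n in [("feed", 2), ("travel", 9)]:
            rows += [dict(individual="skewed", context=ctx, f1=1.0)] * n
        rows += [dict(individual="ok", context="rest", f1=1.0)]
        return make_table(rows, ["f1"])

    def test_min_per_context_rule(self):
        out, rep = apply_context_filters(self._table(), ("feed", "travel"), 3)
        assert out.individuals == ["ok"]
        assert set(out.df["context"]) == {"feed", "travel"}
        assert [e[0] for e in rep.excluded_individuals] == ["skewed"]

    def test_zero_threshold_keeps_all_individuals(self):
        out, _ = apply_context_filters(self._table(), ("feed", "travel"), 0)
        assert set(out.individuals) == {"ok", "skewed"}
        assert "rest" not in set(out.df["context"])

    def test_empty_input(self):
        t = make_table([dict(individual="a", context="feed", f1=1.0)], ["f1"])
        empty = t.subset_rows(np.zeros(1, dtype=bool))
        out, rep = apply_context_filters(empty)
        assert out.n_calls == 0 and rep.n_input_calls == 0


class TestFeatureSet:
    def _table(self):
        rows = [
            dict(individual="a", f_dur=1.0, n_drum=2.0, has_climax=True, has_buildup=True),
            dict(individual="a", f_dur=2.0, n_drum=0.0, has_climax=False, has_buildup=True),
            dict(individual="b", f_dur=np.nan, n_drum=1.0, has_climax=True, has_buildup=True),
        ]
        return make_table(rows, ["f_dur", "n_drum"],
                          {"f_dur": "continuous", "n_drum": "count"})

    def test_excluded_features_removed(self):
        spec = FeatureSetSpec(name="structural", features=["f_dur", "n_drum"],
                              excluded_features=["n_drum"])
        out, rep = select_feature_set(self._table(), spec)
        assert out.feature_names == ["f_dur"]
        assert "n_drum" in rep.dropped_features

    def test_phase_requirement_drops_flagged_absent(self):
        spec = FeatureSetSpec(name="climax", features=["f_dur"],
                              required_phases=frozenset({"climax"}))
        out, _ = select_feature_set(self._table(), spec)
        # row 2 lacks the climax phase, row 3 has a missing value
        assert out.n_calls == 1

    def test_identity_when_unconstrained(self):
        t = make_table([dict(individual="a", f1=1.0), dict(individual="b", f1=2.0)], ["f1"])
        out, rep = select_feature_set(t, FeatureSetSpec(name="all", features=["f1"]))
        pd.testing.assert_frame_equal(out.df, t.df)
        assert rep.n_dropped_calls == 0

    def test_unknown_feature_is_schema_error(self):
        with pytest.raises(SchemaError):
            select_feature_set(self._table(),
                               FeatureSetSpec(name="x", features=["nope"]))

    def test_report_counts_additive(self):
        spec = FeatureSetSpec(name="climax", features=["f_dur"],
                              required_phases=frozenset({"climax"}))
        out, rep = select_feature_set(self._table(), spec)
        assert rep.n_input_calls == rep.n_output_calls + rep.n_dropped_calls


class TestSpectrogramArithmetic:
    def test_study_settings(self):
        fr, tr, rng_ = spectrogram_resolution(24000, 1024, 0.9375)
        assert round(fr) == 23
        assert round(tr, 1) == 2.7
        assert rng_ == 12000

    def test_no_overlap(self):
        fr, tr, _ = spectrogram_resolution(48000, 256, 0.0)
        assert tr == pytest.approx(1000 * 256 / 48000)

    def test_hand_arithmetic(self):
        fr, tr, rng_ = spectrogram_resolution(44100, 512, 0.5)
        assert fr == pytest.approx(86.1328125)
        assert tr == pytest.approx(5.80498866, abs=1e-6)
        assert rng_ == 22050

    @pytest.mark.parametrize("args", [(-1, 512, 0.5), (44100, 1, 0.5), (44100, 512, 1.0)])
    def test_domain_violations(self, args):
        with pytest.raises(ValueError):
            spectrogram_resolution(*args)
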