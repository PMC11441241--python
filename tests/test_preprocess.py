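"""Preprocessing chain: quality/blank/presence filters and normalizations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_samples, make_table
from lipidflow.preprocess import (
    ConfigurationError,
    DataError,
    IntensityTable,
    PipelineError,
    StandardMap,
    blank_filter,
    collapse_technical_replicates,
    internal_standard_normalize,
    median_normalize,
    merge_adducts,
    presence_filter,
    quality_filter,
)


def _records(rows, columns):
    return pd.DataFrame(rows, columns=["name", "adduct", "grade", "ppm"] + columns)


class TestQualityFilter:
    def test_grade_and_ppm_rules(self):
        recs = _records(
            [
                ["PC 34:2", "+H", "A", 3.0, 10.0],
                ["PC 34:2", "+Na", "C", 1.0, 10.0],
                ["PC 36:2", "+H", "B", 6.5, 10.0],
            ],
            ["s1"],
        )
        out = quality_filter(recs, {"A", "B"}, max_ppm=5.0)
        assert list(out["grade"]) == ["A"]

    def test_empty_input(self):
        recs = _records([], ["s1"])
        assert quality_filter(recs).empty

    def test_empty_grades_rejected(self):
        with pytest.raises(ConfigurationError):
            quality_filter(_records([], ["s1"]), set())


class TestMergeAdducts:
    samples = pd.DataFrame(
        {"condition": ["control", "control"], "set_id": ["set1", "set1"],
         "replicate": [1, 2], "is_blank": [False, False]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )

    def test_adduct_sum_with_missing(self):
        recs = _records(
            [
                ["PC 16:0_18:2", "+H", "A", 1.0, 100.0, 200.0],
                ["PC 16:0_18:2", "+Na", "A", 1.0, 50.0, np.nan],
            ],
            ["s1", "s2"],
        )
        table = merge_adducts(recs, self.samples)
        assert table.values.loc["PC 16:0_18:2"].tolist() == [150.0, 200.0]

    def test_single_adduct_identity_and_zero_coercion(self):
        recs = _records(
            [["TG 16:0_18:1_18:2", "+NH4", "A", 1.0, 42.0, 0.0]], ["s1", "s2"]
        )
        table = merge_adducts(recs, self.samples)
        row = table.values.loc["TG 16:0_18:1_18:2"]
        assert row["s1"] == 42.0 and np.isnan(row["s2"])

    def test_total_area_conserved(self, rng):
        names = ["PC 16:0_18:2", "PC 16:0_18:1", "TG 16:0_18:1_18:2"]
        rows = []
        for name in names:
            for adduct in ("+H", "+Na"):
                areas = rng.uniform(10, 100, 4)
                areas[rng.random(4) < 0.3] = np.nan
                rows.append([name, adduct, "A", 0.5, *areas])
        cols = ["s1", "s2", "s3", "s4"]
        samples = pd.DataFrame(
            {"condition": "control", "set_id": "set1",
             "replicate": range(4), "is_blank": False},
            index=pd.Index(cols, name="sample_id"),
        )
        recs = _records(rows, cols)
        table = merge_adducts(recs, samples)
        assert np.isclose(
            np.nansum(table.values.to_numpy()),
            np.nansum(recs[cols].to_numpy()),
        )
        # names merged across adducts and order-canonicalized
        assert table.n_species == 3

    def test_unparseable_name_reports_row(self):
        recs = _records([["BOGUS 1:2", "+H", "A", 1.0, 5.0, 5.0]], ["s1", "s2"])
        with pytest.raises(DataError, match="BOGUS"):
            merge_adducts(recs, self.samples)


class TestBlankFilter:
    def _with_blanks(self, sample_mean, blank_vals):
        samples = pd.DataFrame(
            {"condition": ["control", "control", "blank"],
             "set_id": ["set1", "set1", "set1"],
             "replicate": [1, 2, 1], "is_blank": [False, False, True]},
            index=pd.Index(["s1", "s2", "b1"], name="sample_id"),
        )
        return make_table(
            {"PC 16:0_18:2": [sample_mean, sample_mean, blank_vals]},
            samples, stage="merged",
        )

    def test_below_fold_excluded(self):
        table = self._with_blanks(100.0, 25.0)
        out = blank_filter(table, min_fold=5.0)
        assert out.n_species == 0
        assert out.log[0]["statistic"] == pytest.approx(4.0)

    def test_at_or_above_fold_retained(self):
        assert blank_filter(self._with_blanks(100.0, 10.0)).n_species == 1
        assert blank_filter(self._with_blanks(100.0, 20.0)).n_species == 1

    def test_absent_from_blanks_retained(self):
        table = self._with_blanks(100.0, np.nan)
        assert blank_filter(table).n_species == 1

    def test_min_fold_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            blank_filter(self._with_blanks(1.0, 1.0), min_fold=1.0)


class TestStandardNormalize:
    def _table(self):
        samples = make_samples(n_sets=1, n_reps=1)
        return make_table(
            {"PC 16:0_18:2": [300.0, 600.0],
             "PC 15:0_18:1": [150.0, 300.0]},
            samples, stage="blank_filtered",
        )

    def _map(self):
        return StandardMap(by_class={"PC": "PC 15:0_18:1"})

    def test_ratio_and_standard_removal(self):
        out = internal_standard_normalize(self._table(), self._map())
        assert out.values.loc["PC 16:0_18:2"].tolist() == [2.0, 2.0]
        assert "PC 15:0_18:1" not in out.values.index

    def test_scale_invariance(self):
        # proportional drift of a whole sample cancels
        table = self._table()
        drifted = table.advance("blank_filtered",
                                values=table.values * [1.0, 7.3])
        a = internal_standard_normalize(table, self._map())
        b = internal_standard_normalize(drifted, self._map())
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_unmapped_class_is_config_error(self):
        with pytest.raises(ConfigurationError):
            internal_standard_normalize(self._table(), StandardMap(by_class={}))

    def test_surrogate_fallback(self):
        samples = make_samples(n_sets=1, n_reps=1)
        table = make_table(
            {"MGDG 18:2_18:2": [300.0, 600.0], "DG 15:0_18:1": [100.0, 200.0]},
            samples, stage="blank_filtered",
        )
        smap = StandardMap(by_class={"DG": "DG 15:0_18:1"},
                           surrogates={"MGDG": "DG"})
        out = internal_standard_normalize(table, smap)
        assert out.values.loc["MGDG 18:2_18:2"].tolist() == [3.0, 3.0]

    def test_standard_missing_in_sample_names_it(self):
        table = self._table()
        table.values.loc["PC 15:0_18:1", table.values.columns[1]] = np.nan
        with pytest.raises(DataError, match="missing in samples"):
            internal_standard_normalize(table, self._map())


class TestMedianNormalize:
    def test_two_sample_example(self):
        samples = make_samples(n_sets=1, n_reps=1)
        table = make_table(
            {"PC 16:0_18:2": [1.0, 4.0], "PC 16:0_18:1": [2.0, 8.0],
             "PC 18:1_18:2": [3.0, 16.0]},
            samples, stage="std_normalized",
        )
        out = median_normalize(table)
        # medians 2 and 8 -> reference 5 -> factors 2.5 and 0.625
        assert out.values["set1_control_1"].tolist() == [2.5, 5.0, 7.5]
        assert out.values["set1_hypoxia_1"].tolist() == [2.5, 5.0, 10.0]

    def test_idempotence(self):
        samples = make_samples(n_sets=1, n_reps=2)
        rng = np.random.default_rng(5)
        vals = {f"PC {14 + i}:0_18:1": rng.uniform(1, 50, 4).tolist()
                for i in range(6)}
        once = median_normalize(make_table(vals, samples, "std_normalized"))
        twice = median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_missing_sample_is_error(self):
        samples = make_samples(n_sets=1, n_reps=1)
        table = make_table({"PC 16:0_18:2": [np.nan, 3.0]},
                           samples, "std_normalized")
        with pytest.raises(DataError):
            median_normalize(table)


@given(
    arrays(np.float64, (6, 5), elements=st.floats(0.1, 1e4)),
    st.floats(0.2, 5.0),
)
@settings(max_examples=100, deadline=None)
def test_median_normalize_equalizes_medians(values, factor):
    """Defining property: all per-sample medians equal afterwards."""
    samples = pd.DataFrame(
        {"condition": "control", "set_id": "set1",
         "replicate": range(5), "is_blank": False},
        index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"),
    )
    frame = pd.DataFrame(values * factor, columns=samples.index,
                         index=[f"PC {10 + i}:0_18:1" for i in range(6)])
    table = IntensityTable(
        frame, samples,
        {n: None for n in frame.index}, stage="std_normalized",
    )
    out = median_normalize(table)
    medians = out.values.median(axis=0)
    assert np.allclose(medians, medians.iloc[0], rtol=0, atol=1e-12 * medians.iloc[0])


class TestPresenceFilter:
    def _table(self, control_hits, hypoxia_hits, sets_for_species=("set1", "set2")):
        samples = make_samples(n_sets=2, n_reps=9)
        values = {}
        row = []
        for sid, meta in samples.iterrows():
            idx = meta["replicate"] - 1
            hits = control_hits if meta["condition"] == "control" else hypoxia_hits
            present = idx < hits and meta["set_id"] in sets_for_species
            row.append(100.0 if present else np.nan)
        values["PC 16:0_18:2"] = row
        return make_table(values, samples, stage="median_normalized")

    def test_half_presence_in_one_condition_retained(self):
        table = self._table(control_hits=2, hypoxia_hits=9)
        assert presence_filter(table).n_species == 1

    def test_44_percent_both_conditions_excluded(self):
        table = self._table(control_hits=4, hypoxia_hits=4)
        assert presence_filter(table).n_species == 0

    def test_single_set_excluded_when_both_required(self):
        table = self._table(control_hits=0, hypoxia_hits=6,
                            sets_for_species=("set1",))
        assert presence_filter(table).n_species == 0
        assert presence_filter(table, require_both_sets=False).n_species == 1


class TestStageOrderAndProvenance:
    def test_backwards_transition_rejected(self):
        samples = make_samples(n_sets=1, n_reps=1)
        table = make_table({"PC 16:0_18:2": [1.0, 2.0]}, samples,
                           stage="median_normalized")
        with pytest.raises(PipelineError):
            table.advance("merged")

    def test_negative_values_rejected(self):
        samples = make_samples(n_sets=1, n_reps=1)
        with pytest.raises(DataError):
            make_table({"PC 16:0_18:2": [-1.0, 2.0]}, samples)

    def test_filters_never_alter_surviving_values(self):
        samples = make_samples(n_sets=2, n_reps=2)
        vals = {
            "PC 16:0_18:2": [10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0],
            "PC 16:0_18:1": [np.nan] * 7 + [5.0],
        }
        table = make_table(vals, samples, stage="median_normalized")
        out = presence_filter(table)
        assert out.values.loc["PC 16:0_18:2"].tolist() == vals["PC 16:0_18:2"]
        assert "PC 16:0_18:1" not in out.values.index


def test_collapse_technical_replicates_averages():
    injections = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "condition": "control", "set_id": "set1",
            "replicate": [1, 1, 2, 2], "is_blank": False,
        },
        index=pd.Index(["s1_t1", "s1_t2", "s2_t1", "s2_t2"], name="injection_id"),
    )
    frame = pd.DataFrame(
        [[10.0, 14.0, np.nan, 8.0]], index=["PC 16:0_18:2"],
        columns=injections.index,
    )
    table = IntensityTable(frame, injections,
                           {"PC 16:0_18:2": None}, stage="merged")
    out = collapse_technical_replicates(table)
    assert out.values.loc["PC 16:0_18:2"].tolist() == [12.0, 8.0]
    assert list(out.values.columns) == ["s1", "s2"]
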