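"""De-identification binning: age caps, closure conventions, fitted schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from openexposures.binning import (AgeExcluded, BinningScheme, Deidentifier, bin_age,
                                   apply_explicit, default_schemes,
                                   fit_frequency_quantiles, fit_value_cut)
from openexposures.errors import ConfigurationError, DegenerateInputError, \
    ValidationError


def scheme_by_name(name):
    return {s.feature: s for s in default_schemes()}[name]


class TestAgeBinning:
    @pytest.mark.parametrize("age, label", [
        (0, "<5"), (4, "<5"), (5, "5-17"), (17, "5-17"), (18, "18-44"),
        (44, "18-44"), (45, "45-64"), (64, "45-64"), (65, "65-89"), (89, "65-89"),
    ])
    def test_bin_boundaries(self, age, label):
        birth = pd.Timestamp(f"{2016 - age}-01-01")
        assert bin_age(birth, 2016).label == label

    def test_age_is_completed_years_on_jan1(self):
        # born Jan 2: the birthday has not yet occurred on the reference day
        assert bin_age(pd.Timestamp("2011-01-02"), 2016).label == "<5"
        assert bin_age(pd.Timestamp("2011-01-01"), 2016).label == "5-17"

    def test_over_hipaa_cap_excluded(self):
        assert bin_age(pd.Timestamp("1920-06-01"), 2016) == AgeExcluded()

    def test_missing_birth_date(self):
        assert bin_age(None, 2016) is None

    def test_future_birth_date_rejected(self):
        with pytest.raises(ValidationError):
            bin_age(pd.Timestamp("2016-06-01"), 2016)


class TestExplicitBinning:
    def test_roadway_left_closure(self):
        sch = scheme_by_name("MajorRoadwayHighwayExposure")
        assert apply_explicit(49.9, sch).label == "0-49"
        assert apply_explicit(50.0, sch).label == "50-99"
        assert apply_explicit(250.0, sch).label == ">=250"
        assert apply_explicit(1e6, sch).label == ">=250"

    def test_pm25_first_interval_closed_both_ends(self):
        sch = scheme_by_name("AvgDailyPM25Exposure")
        assert apply_explicit(3.27, sch).index == 0
        assert apply_explicit(6.30, sch).index == 0   # 6.30 closes the first bin
        assert apply_explicit(6.31, sch).index == 1

    def test_missing_and_out_of_range_propagate(self):
        sch = scheme_by_name("AvgDailyPM25Exposure")
        assert apply_explicit(None, sch) is None
        assert apply_explicit(float("nan"), sch) is None
        with pytest.warns(UserWarning):
            assert apply_explicit(99.0, sch) is None

    def test_edges_must_increase(self):
        with pytest.raises(ConfigurationError):
            BinningScheme(feature="x", strategy="explicit_edges", edges=(1, 1, 2))

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=3.27, max_value=10.83, allow_nan=False))
    def test_partition_property(self, value):
        """Every in-range value lands in exactly one bin."""
        sch = scheme_by_name("AvgDailyPM25Exposure")
        hits = [lbl for i, lbl in enumerate(sch.labels)
                if apply_explicit(value, sch) and apply_explicit(value, sch).index == i]
        assert len(hits) == 1


class TestShippedDefaultEdges:
    """The shipped schemes must carry the published bin edges exactly."""

    @pytest.mark.parametrize("feature, edges", [
        ("EstHouseholdIncome", (7470, 36635, 46750, 59566, 78355, 250001)),
        ("EstProbabilityNoHealthIns", (0.0, 0.0637, 0.1121, 0.1644, 0.5548)),
        ("AvgDailyPM25Exposure", (3.27, 6.30, 7.81, 10.83)),
        ("MaxDailyOzoneExposure", (27.80, 39.00, 42.73, 46.45)),
        ("MajorRoadwayHighwayExposure", (0, 50, 100, 150, 200, 250, np.inf)),
    ])
    def test_edges(self, feature, edges):
        assert scheme_by_name(feature).edges == pytest.approx(edges)

    def test_age_labels(self):
        assert scheme_by_name("AgeStudyStart").labels == \
            ("<5", "5-17", "18-44", "45-64", "65-89")


class TestFrequencyQuantiles:
    def test_uniform_distinct_exact_split(self):
        sch = fit_frequency_quantiles(list(range(1, 11)), 5)
        counts = sch.assign(range(1, 11)).value_counts()
        assert sorted(counts) == [2, 2, 2, 2, 2]

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_frequency_quantiles([3.0] * 50, 4)

    def test_edges_match_quantile_oracle_and_occupancy(self):
        rng = np.random.default_rng(11)
        vals = rng.lognormal(0, 1, 10_000)
        sch = fit_frequency_quantiles(vals, 4)
        # independent sorting-based quantile oracle
        s = np.sort(vals)
        oracle = [s[0]] + [s[int(q * (len(s) - 1))]
                           if (q * (len(s) - 1)).is_integer()
                           else np.interp(q * (len(s) - 1),
                                          np.arange(len(s)), s)
                           for q in (0.25, 0.5, 0.75)] + [s[-1]]
        assert np.allclose(sch.edges, oracle)
        counts = sch.assign(vals).value_counts()
        assert all(abs(c - 2500) <= 1 for c in counts)

    def test_tied_data_merges_edges(self):
        vals = [0.0] * 90 + list(range(10))
        with pytest.warns(UserWarning, match="duplicate quantile edges"):
            sch = fit_frequency_quantiles(vals, 4)
        assert len(sch.labels) < 4


class TestValueCut:
    def test_equal_width_edges(self):
        sch = fit_value_cut([0, 1, 2, 9, 5, 3], 3)
        assert sch.edges == pytest.approx((0, 3, 6, 9))

    def test_minimum_lands_in_first_bin(self):
        sch = fit_value_cut([0.0, 9.0, 4.5], 3)
        assert apply_explicit(0.0, sch).index == 0

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_value_cut([5.0, 5.0, 5.0], 3)

    def test_counts_match_membership_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 2000)
        sch = fit_value_cut(vals, 4)
        labels = sch.assign(vals)
        for i, lbl in enumerate(sch.labels):
            lo, hi = sch.edges[i], sch.edges[i + 1]
            expected = ((vals >= lo) & (vals <= hi)).sum() if i == 0 else \
                ((vals > lo) & (vals <= hi)).sum()
            assert (labels == lbl).sum() == expected


class TestDeidentifier:
    def raw_frame(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "birth_date": ["1980-06-15"] * n,
            "sex": rng.choice(["female", "male"], n),
            "race": ["Caucasian"] * n,
            "ethnicity": ["Not Hispanic"] * n,
            "x_m": rng.uniform(0, 1000, n),
            "y_m": rng.uniform(0, 1000, n),
            "blockgroup_id": ["BG0000"] * n,
            "density_class": ["rural"] * n,
            "prob_no_insurance": rng.uniform(0.01, 0.5, n),
            "median_income": rng.uniform(8000, 240000, n),
            "roadway_distance": rng.uniform(0, 600, n),
            "avg_daily_pm25": rng.uniform(3.3, 10.8, n),
            "avg_max_daily_ozone": rng.uniform(28, 46, n),
            "TotalEDInpatientVisits": rng.integers(0, 3, n),
            "TotalPrednisoneRx": rng.integers(0, 2, n),
        })

    def test_identifiers_and_raw_estimates_stripped(self):
        table = Deidentifier(study_year=2016).fit().transform(self.raw_frame())
        forbidden = {"patient_id", "birth_date", "x_m", "y_m", "blockgroup_id",
                     "avg_daily_pm25", "avg_max_daily_ozone", "roadway_distance",
                     "prob_no_insurance", "median_income"}
        assert not forbidden & set(table.df.columns)
        assert "AvgDailyPM25Exposure" in table.df.columns

    def test_missing_scheme_column_is_configuration_error(self):
        raw = self.raw_frame().drop(columns=["avg_daily_pm25"])
        with pytest.raises(ConfigurationError, match="avg_daily_pm25"):
            Deidentifier(study_year=2016).fit().transform(raw)

    def test_empty_input_gives_empty_table_with_schema(self):
        table = Deidentifier(study_year=2016).fit().transform(self.raw_frame(0))
        assert table.n == 0
        assert "Sex" in table.feature_names

    def test_age_exclusion_and_cap_policies(self):
        raw = self.raw_frame(3)
        raw.loc[0, "birth_date"] = "1920-01-01"  # age 96
        excl = Deidentifier(study_year=2016).fit().transform(raw)
        assert excl.n == 2 and excl.meta["n_excluded_age"] == 1
        cap = Deidentifier(study_year=2016, age_policy="cap").fit().transform(raw)
        assert cap.n == 3
        assert cap.df["AgeStudyStart"].iloc[0] == "65-89"

    def test_cells_match_per_row_rebinning_oracle(self):
        """Every binned cell equals a straightforward per-row re-binning."""
        raw = self.raw_frame(500, seed=9)
        table = Deidentifier(study_year=2016).fit().transform(raw)
        pm = scheme_by_name("AvgDailyPM25Exposure")
        inc = scheme_by_name("EstHouseholdIncome")
        road = scheme_by_name("MajorRoadwayHighwayExposure")

        def oracle_right(v, edges, labels):
            if v < edges[0] or v > edges[-1]:
                return None
            for i in range(len(labels)):
                lo, hi = edges[i], edges[i + 1]
                inside = (lo <= v <= hi) if i == 0 else (lo < v <= hi)
                if inside:
                    return labels[i]

        def oracle_left(v, edges, labels):
            for i in range(len(labels)):
                if edges[i] <= v < edges[i + 1]:
                    return labels[i]
            return None

        for row_idx in range(len(raw)):
            r = raw.iloc[row_idx]
            assert table.df["AvgDailyPM25Exposure"].iloc[row_idx] == \
                oracle_right(r["avg_daily_pm25"], pm.edges, pm.labels)
            assert table.df["EstHouseholdIncome"].iloc[row_idx] == \
                oracle_right(r["median_income"], inc.edges, inc.labels)
            assert table.df["MajorRoadwayHighwayExposure"].iloc[row_idx] == \
                oracle_left(r["roadway_distance"], road.edges, road.labels)
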