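"""Association battery: Pearson chi-square, contingency construction,
Bonferroni correction, bin collapsing, cohort constraints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from openexposures.errors import DegenerateTableError, ValidationError
from openexposures.stats import (AssociationBattery, ContingencyTable, OutcomeFeature,
                                 associations_to_all_features, bonferroni_alpha,
                                 build_contingency, chi_square, collapse_bins,
                                 define_cohort)
from openexposures.table import FeatureDef, FeatureTable


def pearson_oracle(obs):
    """Direct textbook formula: sum (O-E)^2/E with E from the marginals."""
    obs = np.asarray(obs, dtype=float)
    rs = obs.sum(axis=1, keepdims=True)
    cs = obs.sum(axis=0, keepdims=True)
    expected = rs * cs / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def ct(counts, cols=None):
    counts = np.asarray(counts)
    cols = cols or tuple(f"b{i}" for i in range(counts.shape[1]))
    return ContingencyTable(row_labels=("yes", "no"), col_labels=tuple(cols),
                            counts=counts)


def toy_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    schema = [
        FeatureDef("Sex", "categorical", ("female", "male")),
        FeatureDef("Income", "binned_ordinal", ("low", "mid", "high")),
        FeatureDef("Flat", "categorical", ("only",)),
        FeatureDef("TotalEDInpatientVisits", "count"),
    ]
    df = pd.DataFrame({
        "Sex": rng.choice(["female", "male", None], n, p=[0.45, 0.45, 0.1]),
        "Income": rng.choice(["low", "mid", "high", None], n),
        "Flat": ["only"] * n,
        "TotalEDInpatientVisits": rng.integers(0, 3, n),
    })
    return FeatureTable(df=df, schema=schema, study_year=2016)


class TestChiSquare:
    def test_published_sex_table(self):
        """The 2x2 female/male vs >=1 ED-visit table reproduces chi2=69.4
        without continuity correction."""
        obs = [[15587, 73944], [10743, 57132]]
        stat, df, p = chi_square(ct(obs))
        assert stat == pytest.approx(69.4, abs=0.05)
        assert df == 1 and p < 0.001

    def test_proportional_rows_independent(self):
        stat, df, p = chi_square(ct([[10, 20], [30, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            r, c = rng.integers(2, 6, 2)
            obs = rng.integers(1, 60, (r, c))
            stat, df, _ = chi_square(ct(obs) if r == 2 else ContingencyTable(
                row_labels=tuple(f"r{i}" for i in range(r)),
                col_labels=tuple(f"c{j}" for j in range(c)), counts=obs))
            assert stat == pytest.approx(pearson_oracle(obs), abs=1e-9)
            assert df == (r - 1) * (c - 1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        obs = rng.integers(1, 40, (3, 4))
        stat, _, _ = chi_square(ContingencyTable(("a", "b", "c"), ("w", "x", "y", "z"),
                                                 obs))
        perm = obs[[2, 0, 1]][:, [3, 1, 0, 2]]
        stat2, _, _ = chi_square(ContingencyTable(("a", "b", "c"),
                                                  ("w", "x", "y", "z"), perm))
        assert stat == pytest.approx(stat2, abs=1e-12)

    def test_all_zero_lines_pruned_df_reflects_it(self):
        obs = [[10, 0, 20], [30, 0, 15]]
        stat, df, _ = chi_square(ct(obs))
        assert df == 1
        assert stat == pytest.approx(pearson_oracle([[10, 20], [30, 15]]), abs=1e-12)

    def test_degenerate_after_pruning(self):
        with pytest.raises(DegenerateTableError):
            chi_square(ct([[5, 0], [3, 0]]))


class TestBonferroni:
    def test_alpha_001_at_50_features(self):
        """alpha=.05 over a 50-feature battery adjusts to .001."""
        assert bonferroni_alpha(0.05, 50) == pytest.approx(0.001)

    def test_significant_set_is_subset_of_uncorrected(self, feature_table):
        outcome = OutcomeFeature("TotalEDInpatientVisits", "=", 0)
        corr, _, _, _ = associations_to_all_features(feature_table, None, outcome)
        uncorr, _, _, _ = associations_to_all_features(feature_table, None, outcome,
                                                       correction="none")
        sig_corr = {r.feature for r in corr if r.significant}
        sig_uncorr = {r.feature for r in uncorr if r.significant}
        assert sig_corr <= sig_uncorr


class TestDefineCohort:
    def test_empty_constraints_whole_table(self):
        t = toy_table()
        definition, size = define_cohort(t, [])
        assert size == t.n
        assert definition.cohort_id.startswith("COHORT:")

    def test_unmatched_label_size_zero(self):
        t = toy_table()
        _, size = define_cohort(t, [("Income", "=", "high")])
        assert size == (t.df["Income"] == "high").sum()

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValidationError):
            define_cohort(toy_table(), [("Nope", "=", "x")])

    def test_matches_brute_force_filter(self):
        t = toy_table(200, seed=5)
        constraints = [("Sex", "=", "female"), ("TotalEDInpatientVisits", ">=", 1)]
        _, size = define_cohort(t, constraints)
        brute = sum(1 for _, row in t.df.iterrows()
                    if row["Sex"] == "female"
                    and pd.notna(row["TotalEDInpatientVisits"])
                    and row["TotalEDInpatientVisits"] >= 1)
        assert size == brute

    def test_id_is_deterministic(self):
        t = toy_table()
        a, _ = define_cohort(t, [("Sex", "=", "male")])
        b, _ = define_cohort(t, [("Sex", "=", "male")])
        assert a.cohort_id == b.cohort_id


class TestBuildContingency:
    def test_hand_built_counts(self):
        schema = [FeatureDef("Sex", "categorical", ("female", "male")),
                  FeatureDef("TotalEDInpatientVisits", "count")]
        df = pd.DataFrame({"Sex": ["female", "female", "male", "male", "female", None],
                           "TotalEDInpatientVisits": [0, 2, 0, 1, np.nan, 0]})
        t = FeatureTable(df, schema, 2016)
        c = build_contingency(t, None, OutcomeFeature("TotalEDInpatientVisits", "=", 0),
                              "Sex")
        # rows: visits=0 vs complement; cols: female, male
        assert c.counts.tolist() == [[1, 1], [1, 1]]
        assert c.n_excluded_missing == 2  # one missing outcome, one missing sex

    def test_all_missing_feature_degenerate(self):
        schema = [FeatureDef("X", "categorical", ("a", "b")),
                  FeatureDef("TotalEDInpatientVisits", "count")]
        df = pd.DataFrame({"X": [None, None], "TotalEDInpatientVisits": [0, 1]})
        t = FeatureTable(df, schema, 2016)
        with pytest.raises(DegenerateTableError):
            build_contingency(t, None,
                              OutcomeFeature("TotalEDInpatientVisits", "=", 0), "X")

    def test_matches_double_loop_oracle(self):
        t = toy_table(150, seed=11)
        outcome = OutcomeFeature("TotalEDInpatientVisits", "=", 0)
        c = build_contingency(t, None, outcome, "Income")
        for j, label in enumerate(("low", "mid", "high")):
            yes = no = 0
            for _, row in t.df.iterrows():
                if pd.isna(row["TotalEDInpatientVisits"]) or row["Income"] is None:
                    continue
                if row["Income"] != label:
                    continue
                if row["TotalEDInpatientVisits"] == 0:
                    yes += 1
                else:
                    no += 1
            assert c.counts[0, j] == yes and c.counts[1, j] == no

    def test_grand_total_accounts_for_missing(self):
        t = toy_table(150, seed=11)
        c = build_contingency(t, None, OutcomeFeature("TotalEDInpatientVisits", "=", 0),
                              "Income")
        assert c.total + c.n_excluded_missing == t.n


class TestCollapseBins:
    def test_collapse_all_preserves_row_sums(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(0, 30, (2, 5))
        c = collapse_bins(ct(obs), [list(range(5))])
        assert c.counts[:, 0].tolist() == obs.sum(axis=1).tolist()

    def test_non_adjacent_grouping_rejected(self):
        with pytest.raises(ValidationError):
            collapse_bins(ct([[1, 2, 3], [4, 5, 6]]), [[0, 2], [1]])

    def test_partition_must_cover(self):
        with pytest.raises(ValidationError):
            collapse_bins(ct([[1, 2, 3], [4, 5, 6]]), [[0, 1]])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_collapsed_chi_square_equals_summed_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(3, 7))
        obs = rng.integers(1, 50, (2, n_cols))
        # random contiguous partition
        cuts = sorted(rng.choice(np.arange(1, n_cols),
                                 size=int(rng.integers(0, n_cols - 1)), replace=False))
        bounds = [0] + list(cuts) + [n_cols]
        groups = [list(range(a, b)) for a, b in zip(bounds, bounds[1:])]
        collapsed = collapse_bins(ct(obs), groups)
        summed = np.column_stack([obs[:, g].sum(axis=1) for g in groups])
        assert collapsed.counts.tolist() == summed.tolist()
        if (summed.sum(axis=0) > 0).sum() >= 2:
            stat, _, _ = chi_square(collapsed)
            assert stat == pytest.approx(pearson_oracle(
                summed[:, summed.sum(axis=0) > 0]), abs=1e-9)


class TestBattery:
    def test_maximum_p_value_one_returns_every_eligible_feature(self, feature_table):
        outcome = OutcomeFeature("TotalEDInpatientVisits", "=", 0)
        results, m, _, skipped = associations_to_all_features(
            feature_table, None, outcome, maximum_p_value=1.0)
        eligible = [f.name for f in feature_table.schema
                    if f.kind != "count" and f.name != outcome.name]
        assert len(results) == m == len(eligible) - len(skipped)

    def test_constant_feature_skipped_others_unaffected(self):
        t = toy_table(80, seed=3)
        outcome = OutcomeFeature("TotalEDInpatientVisits", "=", 0)
        results, m, _, skipped = associations_to_all_features(t, None, outcome)
        assert "Flat" in skipped
        assert {r.feature for r in results} == {"Sex", "Income"}
        assert m == 2

    def test_results_sorted_by_p(self, feature_table):
        results, _, _, _ = associations_to_all_features(
            feature_table, None, OutcomeFeature("TotalEDInpatientVisits", "=", 0))
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_maximum_p_value_zero_empty(self, feature_table):
        results, m, _, _ = associations_to_all_features(
            feature_table, None, OutcomeFeature("TotalEDInpatientVisits", "=", 0),
            maximum_p_value=0.0)
        assert results == [] and m > 0

    def test_estimator_interface(self, feature_table):
        batt = AssociationBattery(outcome=("TotalEDInpatientVisits", "=", 0))
        batt.fit(feature_table)
        frame = batt.to_frame()
        assert list(frame.columns) == ["feature", "bins", "counts", "percentages",
                                       "chi_square", "df", "p_value",
                                       "alpha_adjusted", "significant"]
        assert batt.alpha_adjusted_ == pytest.approx(0.05 / batt.m_)
        params = batt.get_params()
        assert params["correction"] == "bonferroni"
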