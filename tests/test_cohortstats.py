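"""Statistical machinery: ANCOVA designs and dfs, LSD contrasts against
hand computation, Cohen's d identities, rank statistics, demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsvft.config import SimulationConfig
from nirsvft.cohortstats import (
    ancova,
    ancova_null_rejection_rate,
    cohens_d,
    demographic_table,
    fh_grouping,
    lsd_posthoc,
    nested_f,
    spearman_correlations,
)
from nirsvft.io import cohort_to_frame
from nirsvft.synthgen import generate_cohort


@pytest.fixture(scope="module")
def default_subjects() -> pd.DataFrame:
    return cohort_to_frame(generate_cohort(SimulationConfig()))


def random_features(subjects: pd.DataFrame, rng, qc_pass=True) -> pd.DataFrame:
    n = len(subjects)
    return pd.DataFrame({
        "subject_id": subjects["id"],
        "integral_value": rng.normal(80, 25, n),
        "centroid_value_s": rng.uniform(20, 90, n),
        "n_valid_channels": 11,
        "qc_pass": qc_pass,
        "exclusion_reason": None,
    })


class TestAncova:
    def test_four_group_design_df(self, default_subjects, rng):
        """45/26/22/51 subjects, diagnosis factor, 3 covariates: F_{3,137}."""
        features = random_features(default_subjects, rng)
        res = ancova(features, default_subjects, "integral_value", "diagnosis")
        assert (res.df_num, res.df_den) == (3, 137)
        assert res.n_used == 144
        assert res.df_den == res.n_used - len(res.factor_levels) - 3

    def test_pooled_family_history_design_df(self, default_subjects, rng):
        features = random_features(default_subjects, rng)
        grouping = fh_grouping(default_subjects, level="any")
        res = ancova(features, default_subjects, "integral_value", grouping)
        assert sorted(res.factor_levels) == ["HC", "PSY+", "PSY-"]
        assert (res.df_num, res.df_den) == (2, 138)

    def test_single_diagnosis_family_history_design_df(self, default_subjects,
                                                       rng):
        features = random_features(default_subjects, rng)
        grouping = fh_grouping(default_subjects, level="any", diagnosis="SCZ")
        res = ancova(features, default_subjects, "integral_value", grouping)
        assert sorted(res.factor_levels) == ["HC", "SCZ+", "SCZ-"]
        assert (res.df_num, res.df_den) == (2, 90)
        assert res.n_used == 96

    def test_qc_failures_and_missing_covariates_dropped(self, default_subjects,
                                                        rng):
        features = random_features(default_subjects, rng)
        features.loc[:4, "qc_pass"] = False
        subjects = default_subjects.copy()
        subjects.loc[subjects.index[-3:], "age_years"] = np.nan
        res = ancova(features, subjects, "integral_value", "diagnosis")
        assert res.n_used == 144 - 5 - 3
        assert res.n_dropped == 8
        assert res.df_den == res.n_used - 4 - 3

    def test_degenerate_group_raises(self, rng):
        subjects = cohort_to_frame(generate_cohort(SimulationConfig(
            group_sizes={"SCZ": 1, "MDD": 5, "BIP": 5, "HC": 5},
            fh_fraction={"SCZ": 0, "MDD": 0, "BIP": 0, "HC": 0})))
        features = random_features(subjects, rng)
        with pytest.raises(ValueError, match="degenerate"):
            ancova(features, subjects, "integral_value", "diagnosis")

    def test_f_matches_projection_computation(self, default_subjects, rng):
        """The reported omnibus F equals the nested-design projection F
        computed independently from the same matrices."""
        features = random_features(default_subjects, rng)
        res = ancova(features, default_subjects, "integral_value", "diagnosis")

        merged = features.merge(default_subjects, left_on="subject_id",
                                right_on="id")
        y = merged["integral_value"].to_numpy()
        dummies = pd.get_dummies(merged["diagnosis"], dtype=float)
        dummies = dummies[sorted(dummies.columns)].iloc[:, 1:].to_numpy()
        covs = np.column_stack([
            merged["age_years"],
            merged["gender"].map({"female": 0.0, "male": 1.0}),
            merged["vft_performance"],
        ]).astype(float)
        ones = np.ones((len(y), 1))
        f, df_num, df_den = nested_f(y, np.hstack([ones, dummies, covs]),
                                     np.hstack([ones, covs]))
        assert res.F == pytest.approx(float(f[0]), rel=1e-10)
        assert (res.df_num, res.df_den) == (df_num, df_den)


class TestLsdPosthoc:
    @staticmethod
    def two_group_tables(rng, gap=0.0):
        n = 30
        subjects = pd.DataFrame({
            "id": [f"s{i}" for i in range(2 * n)],
            "diagnosis": ["HC"] * n + ["SCZ"] * n,
            "age_years": rng.normal(35, 8, 2 * n),
            "gender": rng.choice(["male", "female"], 2 * n),
            "vft_performance": rng.integers(5, 25, 2 * n),
        })
        features = pd.DataFrame({
            "subject_id": subjects["id"],
            "integral_value": np.concatenate([
                rng.normal(80, 20, n), rng.normal(80 + gap, 20, n)]),
            "qc_pass": True,
        })
        return features, subjects

    def test_two_groups_lsd_equals_omnibus(self, rng):
        """With two groups, the LSD t test is the omnibus F (F = t^2)."""
        features, subjects = self.two_group_tables(rng, gap=10.0)
        res = ancova(features, subjects, "integral_value", "diagnosis")
        (ph,) = lsd_posthoc(res)
        assert ph.lsd_p == pytest.approx(res.p, rel=1e-10)

    def test_identical_groups_give_zero_difference(self, rng):
        n = 20
        values = rng.normal(50, 10, n)
        subjects = pd.DataFrame({
            "id": [f"s{i}" for i in range(2 * n)],
            "diagnosis": ["HC"] * n + ["SCZ"] * n,
        })
        features = pd.DataFrame({
            "subject_id": subjects["id"],
            "integral_value": np.concatenate([values, values]),
            "qc_pass": True,
        })
        res = ancova(features, subjects, "integral_value", "diagnosis",
                     covariates=())
        (ph,) = lsd_posthoc(res)
        assert ph.adjusted_mean_diff == pytest.approx(0.0, abs=1e-10)
        assert ph.lsd_p == pytest.approx(1.0, abs=1e-10)
        assert ph.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_t_on_fixed_fixture(self):
        """Printed three-group fixture: the LSD t is recomputed here from
        the normal equations and residual MSE, independently of statsmodels."""
        subjects = pd.DataFrame({
            "id": list("abcdefghijkl"),
            "diagnosis": ["HC"] * 4 + ["SCZ"] * 4 + ["MDD"] * 4,
            "age_years": [30, 41, 35, 28, 44, 39, 31, 37, 29, 46, 38, 33],
        })
        features = pd.DataFrame({
            "subject_id": subjects["id"],
            "integral_value": [92.0, 85.0, 101.0, 88.0,
                               61.0, 70.0, 55.0, 66.0,
                               72.0, 80.0, 69.0, 77.0],
            "qc_pass": True,
        })
        res = ancova(features, subjects, "integral_value", "diagnosis",
                     covariates=("age_years",))
        results = {ph.pair: ph for ph in lsd_posthoc(res)}

        # independent recomputation: X = [1, I(MDD), I(SCZ), age]
        y = features["integral_value"].to_numpy()
        x = np.column_stack([
            np.ones(12),
            (subjects["diagnosis"] == "MDD").astype(float),
            (subjects["diagnosis"] == "SCZ").astype(float),
            subjects["age_years"].astype(float),
        ])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        mse = resid @ resid / (12 - 4)
        xtx_inv = np.linalg.inv(x.T @ x)
        c = np.array([0.0, 1.0, -1.0, 0.0])        # MDD minus SCZ
        t_hand = (c @ beta) / np.sqrt(mse * c @ xtx_inv @ c)
        p_hand = 2 * stats.t.sf(abs(t_hand), 12 - 4)

        ph = results[("MDD", "SCZ")]
        assert ph.adjusted_mean_diff == pytest.approx(c @ beta, rel=1e-10)
        assert ph.lsd_p == pytest.approx(p_hand, rel=1e-10)

    def test_unknown_level_raises(self, rng):
        features, subjects = self.two_group_tables(rng)
        res = ancova(features, subjects, "integral_value", "diagnosis")
        with pytest.raises(ValueError, match="unknown group level"):
            lsd_posthoc(res, pairs=[("HC", "BIP")])


class TestCohensD:
    def test_identical_samples_zero(self):
        x = [3.0, 4.0, 5.0, 6.0]
        assert cohens_d(x, x) == 0.0

    def test_unit_gap_unit_pooled_sd(self):
        assert cohens_d([0, 1, 2], [1, 2, 3]) == pytest.approx(-1.0)

    def test_antisymmetric(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_equals_t_statistic_identity(self, rng):
        """d = t * sqrt(1/n1 + 1/n2) for the pooled-variance two-sample t."""
        for _ in range(5):
            x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 17)
            t, _ = stats.ttest_ind(x, y, equal_var=True)
            assert cohens_d(x, y) == pytest.approx(
                t * np.sqrt(1 / 12 + 1 / 17), rel=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestSpearman:
    @staticmethod
    def tables(feature_vals, var_vals):
        n = len(feature_vals)
        subjects = pd.DataFrame({
            "id": [f"s{i}" for i in range(n)],
            "cpz_eq_mg_day": var_vals,
        })
        features = pd.DataFrame({
            "subject_id": subjects["id"],
            "integral_value": feature_vals,
            "centroid_value_s": feature_vals,
            "qc_pass": True,
        })
        return features, subjects

    def test_monotone_pairs(self):
        features, subjects = self.tables([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        out = spearman_correlations(features, subjects, ["cpz_eq_mg_day"])
        assert np.allclose(out["rho"], 1.0)

    def test_reversed_pairs(self):
        features, subjects = self.tables([1, 2, 3, 4], [8, 6, 4, 2])
        out = spearman_correlations(features, subjects, ["cpz_eq_mg_day"])
        assert np.allclose(out["rho"], -1.0)

    def test_eight_pair_fixture_matches_rank_oracle(self):
        """Tie-corrected rho equals the Pearson correlation of hand-assigned
        mid-ranks on a printed fixture with ties."""
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        v = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 9.0]
        features, subjects = self.tables(x, v)
        out = spearman_correlations(features, subjects, ["cpz_eq_mg_day"])

        def midranks(a):
            a = np.asarray(a)
            order = np.argsort(a, kind="mergesort")
            ranks = np.empty(len(a))
            i = 0
            while i < len(a):
                j = i
                while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, rv = midranks(x), midranks(v)
        expected = np.corrcoef(rx, rv)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_all_tied_variable_flagged_undefined(self):
        features, subjects = self.tables([1, 2, 3, 4], [5, 5, 5, 5])
        out = spearman_correlations(features, subjects, ["cpz_eq_mg_day"])
        assert out["rho"].isna().all()


class TestDemographics:
    def test_perfectly_separated_two_by_two_chi2(self):
        subjects = pd.DataFrame({
            "id": [f"s{i}" for i in range(20)],
            "diagnosis": ["HC"] * 10 + ["SCZ"] * 10,
            "gender": ["male"] * 10 + ["female"] * 10,
        })
        table = demographic_table(subjects, continuous=(),
                                  categorical=("gender",))
        row = table.tests.iloc[0]
        assert row["statistic"] == pytest.approx(20.0)
        assert row["df"] == 1

    def test_four_group_gender_df_three(self, default_subjects):
        table = demographic_table(default_subjects, continuous=(),
                                  categorical=("gender",))
        assert table.tests.iloc[0]["df"] == 3

    def test_continuous_variables_use_rank_tests(self, default_subjects):
        table = demographic_table(default_subjects)
        tests = table.tests.set_index("variable")
        assert tests.loc["age_years", "test"] == "Kruskal-Wallis"
        assert tests.loc["age_years", "df"] == 3
        # CPZ-eq exists only in the three patient groups
        assert tests.loc["cpz_eq_mg_day", "test"] == "Kruskal-Wallis"
        assert 0 <= tests.loc["age_years", "p"] <= 1
        assert np.isfinite(tests.loc["age_years", "normality_p"])

    def test_two_group_comparison_uses_mann_whitney(self, rng):
        subjects = pd.DataFrame({
            "id": [f"s{i}" for i in range(30)],
            "diagnosis": ["HC"] * 15 + ["SCZ"] * 15,
            "age_years": rng.normal(35, 10, 30),
        })
        table = demographic_table(subjects, continuous=("age_years",),
                                  categorical=())
        assert table.tests.iloc[0]["test"] == "Mann-Whitney U"

    def test_null_groups_give_unremarkable_statistics(self, rng):
        """Identically distributed groups should not produce extreme tests."""
        ps = []
        for i in range(40):
            local = np.random.default_rng(i)
            subjects = pd.DataFrame({
                "id": [f"s{i}" for i in range(60)],
                "diagnosis": np.repeat(["HC", "SCZ", "MDD"], 20),
                "age_years": local.normal(35, 10, 60),
            })
            table = demographic_table(subjects, continuous=("age_years",),
                                      categorical=())
            ps.append(table.tests.iloc[0]["p"])
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() < 0.25
        assert ps.mean() > 0.25


class TestFhGrouping:
    def test_pooled_and_restricted_labels(self, default_subjects):
        pooled = fh_grouping(default_subjects, level="any")
        assert set(pooled.dropna().unique()) == {"HC", "PSY+", "PSY-"}
        assert (pooled == "PSY+").sum() == 37
        assert (pooled == "PSY-").sum() == 56
        scz = fh_grouping(default_subjects, level="any", diagnosis="SCZ")
        assert (scz == "SCZ+").sum() == 17
        assert scz.isna().sum() == 26 + 22    # other patients excluded

    def test_unknown_family_history_becomes_nan(self):
        subjects = cohort_to_frame(generate_cohort(SimulationConfig(
            group_sizes={"SCZ": 10, "MDD": 0, "BIP": 0, "HC": 5},
            fh_fraction={"SCZ": 0.4, "MDD": 0, "BIP": 0, "HC": 0},
            fh_unknown_rate=0.5, seed=4)))
        labels = fh_grouping(subjects, level="any")
        n_unknown = sum(v is None for v in subjects["fh_any_psychiatric"])
        assert n_unknown > 0
        assert labels.isna().sum() == n_unknown


class TestNullCalibration:
    def test_quick_type_one_error_sanity(self, rng):
        """Small null Monte Carlo: rejection rate near alpha (full 5000-rep
        calibration lives in the acceptance suite)."""
        rate = ancova_null_rejection_rate(n_groups=3, n_per_group=20,
                                          n_covariates=3, n_rep=800, rng=rng)
        assert 0.03 < rate < 0.08
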