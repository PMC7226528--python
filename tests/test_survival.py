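import numpy as np
import pandas as pd
import pytest

from cyclinpair.core_io import ClinicalTable, CohortError
from cyclinpair.survival import (
    cox_univariate,
    km_fit,
    logrank,
    survival_at,
    survival_by_deregulation,
)

from _oracles import (
    cox_score_statistic_at_zero,
    grid_search_cox,
    km_by_hand,
    logrank_by_hand,
)


def _records(times, events, groups=None):
    df = pd.DataFrame({"time": times, "event": events})
    if groups is not None:
        df["group"] = groups
    return df


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """(10,e)(20,e)(30,c)(40,e)(50,c): S = 0.8 * 0.75 * 0.5 = 0.3."""
        curve = km_fit(pd.Series([10, 20, 30, 40, 50]), pd.Series([1, 1, 0, 1, 0]))
        at = survival_at(curve, 60)
        assert at["estimate"] == pytest.approx(0.3)
        assert at["beyond_follow_up"]
        assert survival_at(curve, 0)["estimate"] == 1.0

    def test_all_events_at_once(self):
        curve = km_fit(pd.Series([10] * 4), pd.Series([1] * 4))
        assert survival_at(curve, 10)["estimate"] == 0.0

    def test_all_censored_stays_at_one(self):
        curve = km_fit(pd.Series([5, 15, 25]), pd.Series([0, 0, 0]))
        assert survival_at(curve, 30)["estimate"] == 1.0
        assert curve.n_events == 0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 40, size=25).astype(float)
        curve = km_fit(pd.Series(t), pd.Series(np.ones_like(t)))
        for q in [5.0, 10.0, 20.0, 39.0]:
            assert survival_at(curve, q)["estimate"] == pytest.approx(
                (t > q).mean()
            )

    def test_matches_hand_oracle_with_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 30, size=40).astype(float)
        e = rng.integers(0, 2, size=40)
        curve = km_fit(pd.Series(t), pd.Series(e))
        for when, s in km_by_hand(t, e).items():
            assert survival_at(curve, when)["estimate"] == pytest.approx(s)

    def test_ci_contains_estimate_and_is_bounded(self):
        curve = km_fit(
            pd.Series([3, 6, 6, 9, 12, 15, 20]), pd.Series([1, 1, 0, 1, 0, 1, 0])
        )
        at = survival_at(curve, 18)
        assert 0 <= at["ci_lower"] <= at["estimate"] <= at["ci_upper"] <= 1

    def test_greenwood_variance_by_hand(self):
        curve = km_fit(pd.Series([10, 20, 30]), pd.Series([1, 1, 0]))
        # after t=20: S = 1/3; var = S^2 (1/(3*2) + 1/(2*1))
        s = 1 / 3
        expected = s**2 * (1 / 6 + 1 / 2)
        assert curve.variance.asof(20) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(CohortError):
            km_fit(pd.Series([-1.0]), pd.Series([1]))


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [5, 10, 15, 20]
        df = _records(t + t, [1, 1, 0, 1] * 2, ["a"] * 4 + ["b"] * 4)
        res = logrank(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        df = _records(
            [6, 13, 21, 30, 31, 37], [1, 1, 1, 1, 0, 1],
            ["a", "b", "a", "a", "b", "b"],
        )
        res = logrank(df)
        oracle = logrank_by_hand(
            df["time"].to_numpy(), df["event"].to_numpy(), df["group"].to_numpy()
        )
        assert res.statistic == pytest.approx(oracle, abs=1e-9)
        assert res.df == 1

    def test_three_groups_df(self):
        df = _records(
            [5, 8, 12, 20, 25, 33], [1, 1, 1, 1, 1, 0],
            ["a", "a", "b", "b", "c", "c"],
        )
        assert logrank(df).df == 2

    def test_single_group_rejected(self):
        with pytest.raises(CohortError):
            logrank(_records([1, 2], [1, 1], ["a", "a"]))


# toy fixtures for Cox oracle comparison; ties included deliberately
COX_FIXTURES = [
    ([6, 6, 8, 12, 15, 20], [1, 1, 1, 0, 1, 1], [1, 1, 0, 0, 1, 0]),
    ([3, 5, 5, 5, 9, 11, 14], [1, 0, 1, 1, 1, 1, 0], [0, 1, 1, 0, 1, 0, 0]),
    ([10, 10, 10, 20, 20, 30], [1, 1, 0, 1, 1, 1], [1, 0, 1, 1, 0, 0]),
    ([2, 4, 6, 8, 10, 12, 14, 16], [1, 1, 1, 1, 0, 1, 1, 0], [1, 1, 1, 0, 0, 0, 1, 0]),
    ([7, 7, 9, 9, 13, 13, 17], [1, 0, 1, 1, 1, 1, 1], [0, 0, 1, 1, 0, 1, 1]),
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [1, 0, 1, 0, 1, 0]),
]


class TestCox:
    def test_symmetric_groups_give_unit_hazard_ratio(self):
        t = [5, 10, 15, 20, 25]
        e = [1, 1, 0, 1, 0]
        df = _records(t + t, e + e, ["ref"] * 5 + ["other"] * 5)
        res = cox_univariate(df, reference="ref")
        assert res.table.loc["other", "hr"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("times,events,x", COX_FIXTURES)
    def test_matches_efron_grid_search_oracle(self, times, events, x):
        groups = np.where(np.asarray(x) == 1, "exposed", "ref")
        df = _records(times, events, groups)
        res = cox_univariate(df, reference="ref")
        beta_hat = res.table.loc["exposed", "coef"]
        beta_grid = grid_search_cox(
            np.asarray(times, float), np.asarray(events), np.asarray(x, float)
        )
        assert beta_hat == pytest.approx(beta_grid, abs=2e-3)

    def test_two_group_logrank_equals_squared_score_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            n = 30
            t = rng.permutation(np.arange(1, n + 1)).astype(float)  # tie-free
            e = rng.integers(0, 2, size=n)
            e[0] = 1
            x = rng.integers(0, 2, size=n)
            if len(np.unique(x[e == 1])) < 2:
                continue
            df = _records(t, e, np.where(x == 1, "b", "a"))
            lr = logrank(df).statistic
            score = cox_score_statistic_at_zero(t, e, x.astype(float))
            assert lr == pytest.approx(score, abs=1e-6)

    def test_order_invariance(self):
        times, events, x = COX_FIXTURES[1]
        groups = np.where(np.asarray(x) == 1, "exposed", "ref")
        df = _records(times, events, groups)
        res1 = cox_univariate(df, reference="ref")
        res2 = cox_univariate(df.iloc[::-1].reset_index(drop=True), reference="ref")
        assert res1.table.loc["exposed", "coef"] == pytest.approx(
            res2.table.loc["exposed", "coef"], abs=1e-10
        )

    def test_missing_reference_rejected(self):
        df = _records([1, 2], [1, 1], ["a", "b"])
        with pytest.raises(CohortError):
            cox_univariate(df, reference="zzz")


class TestSurvivalByDeregulation:
    @staticmethod
    def _inputs(default_cohort, default_gene_matrix):
        from cyclinpair.deregulation import deregulation_calls

        calls = deregulation_calls(
            default_gene_matrix, default_cohort.samples, ["CCND1"]
        )
        return calls, default_cohort.clinical, default_cohort.samples

    def test_null_simulation_covers_unit_hazard(self, default_cohort, default_gene_matrix):
        """Simulated group log-HRs are all zero: fitted HRs near 1."""
        calls, clinical, samples = self._inputs(default_cohort, default_gene_matrix)
        report = survival_by_deregulation(
            calls, clinical, samples, gene="CCND1", stratum="all", endpoint="os"
        )
        assert report.cox is not None
        for _, row in report.cox.table.iterrows():
            assert row["ci_lower"] < 1.0 < row["ci_upper"]

    def test_small_groups_reported_without_cox(self, default_cohort, default_gene_matrix):
        calls, clinical, samples = self._inputs(default_cohort, default_gene_matrix)
        report = survival_by_deregulation(
            calls, clinical, samples, gene="CCND1", stratum="all",
            endpoint="os", min_group_size=1000,
        )
        assert report.cox is None and report.logrank is None
        assert len(report.group_table) >= 1

    def test_five_year_column_is_percent(self, default_cohort, default_gene_matrix):
        calls, clinical, samples = self._inputs(default_cohort, default_gene_matrix)
        report = survival_by_deregulation(
            calls, clinical, samples, gene="CCND1", stratum="hpv_neg", endpoint="os"
        )
        assert (report.group_table["five_year_pct"] <= 100).all()
        assert (report.group_table["five_year_pct"] >= 0).all()

    def test_dfs_endpoint_uses_collapsed_events(self, default_cohort, default_gene_matrix):
        calls, clinical, samples = self._inputs(default_cohort, default_gene_matrix)
        report = survival_by_deregulation(
            calls, clinical, samples, gene="CCND1", stratum="all", endpoint="dfs"
        )
        assert report.endpoint == "dfs"
        assert report.group_table["n_events"].sum() > 0

    def test_missing_endpoint_columns_error(self, default_cohort, default_gene_matrix):
        calls, _, samples = self._inputs(default_cohort, default_gene_matrix)
        bare = ClinicalTable(
            pd.DataFrame(
                {"patient_id": ["P0001"], "os_months": [10], "os_event": [1]}
            )
        )
        with pytest.raises(CohortError):
            survival_by_deregulation(
                calls, bare, samples, gene="CCND1", stratum="all", endpoint="dfs"
            )
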