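"""Response table, outlier screen, exact tests, network and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crmetab import cohort_stats as S


class TestPercentChange:
    def test_group_mean_example(self):
        # body-mass group means 90.0 -> 77.2 g is a -14.2% response
        assert S.percent_change(90.0, 77.2) == pytest.approx(-14.222, abs=1e-3)
        assert round(S.percent_change(90.0, 77.2), 1) == -14.2

    def test_ration_cut(self):
        # the designed 60% energy restriction from the ration energies
        assert S.percent_change(24.48, 9.79) == pytest.approx(-60.0, abs=0.01)

    def test_no_change_and_zero_pre(self):
        assert S.percent_change(5.0, 5.0) == 0.0
        assert np.isnan(S.percent_change(0.0, 5.0))

    def test_mean_of_individual_vs_v_of_means(self):
        # equal whenever all individuals share the same pre value ...
        df = pd.DataFrame(
            dict(
                animal_id=list("abc"),
                sex="F",
                variable="x",
                value_ctl=[10.0, 10.0, 10.0],
                value_cr=[8.0, 9.0, 13.0],
            )
        )
        t = S.build_response_table(df).summaries.iloc[0]
        assert t["v_mean"] == pytest.approx(t["v_of_means"])
        # ... and generally different (frozen counterexample)
        df2 = df.assign(value_ctl=[5.0, 10.0, 20.0])
        t2 = S.build_response_table(df2).summaries.iloc[0]
        v_ind = np.mean([100 * (8 - 5) / 5, 100 * (9 - 10) / 10, 100 * (13 - 20) / 20])
        assert t2["v_mean"] == pytest.approx(v_ind)
        assert t2["v_mean"] != pytest.approx(t2["v_of_means"], abs=1.0)


class TestDixonQ:
    def test_outlier_detected(self):
        res = S.dixon_q([1, 2, 3, 4, 100])
        assert res.variant == "r10"
        assert res.q == pytest.approx(96 / 99, rel=1e-9)
        assert res.critical == 0.710
        assert res.is_outlier and res.suspect == 100

    def test_uniform_spacing_no_outlier(self):
        res = S.dixon_q([1, 2, 3, 4, 5])
        assert res.q == pytest.approx(0.25)
        assert not res.is_outlier

    def test_all_equal_undefined(self):
        res = S.dixon_q([7.0] * 5)
        assert res.q is None and not res.is_outlier

    def test_low_end_suspect(self):
        res = S.dixon_q([-100, 1, 2, 3, 4])
        assert res.is_outlier and res.suspect == -100

    @pytest.mark.parametrize("n,variant", [(3, "r10"), (7, "r10"), (8, "r11"), (10, "r11"), (11, "r22"), (13, "r22")])
    def test_variant_by_sample_size(self, n, variant):
        assert S.dixon_q(np.arange(n, dtype=float)).variant == variant

    def test_size_limits(self):
        with pytest.raises(S.CohortStatsError):
            S.dixon_q([1.0, 2.0])
        with pytest.raises(S.CohortStatsError):
            S.dixon_q(list(range(14)))

    def test_false_positive_rate_near_alpha(self):
        # screening normal samples should flag ~5%
        rng = np.random.default_rng(12)
        hits = sum(S.dixon_q(rng.normal(size=6)).is_outlier for _ in range(2000))
        assert 0.02 < hits / 2000 < 0.09


def recursive_signed_rank_p(d):
    """Independent recursive enumeration of the signed-rank null."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [0.0]
    for r in ranks:
        sums = [s for s in sums] + [s + r for s in sums]
    sums = np.array(sums)
    p_le = (sums <= w_obs + 1e-12).mean()
    p_ge = (sums >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestExactTests:
    def test_all_positive_pairs(self):
        res = S.exact_signed_rank(np.zeros(6), np.arange(1.0, 7.0))
        assert res.p_value == pytest.approx(2 / 64)

    def test_complete_separation_two_groups(self):
        res = S.exact_rank_sum([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        assert res.p_value == pytest.approx(2 / 924, rel=1e-12)

    def test_identical_groups_p_one(self):
        assert S.exact_rank_sum([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        res = S.exact_signed_rank(np.ones(5), np.ones(5))
        assert res.p_value == 1.0 and res.degenerate

    def test_signed_rank_matches_enumeration_all_small_n(self):
        rng = np.random.default_rng(21)
        for n in range(3, 9):
            for _ in range(20):
                d = rng.normal(size=n)
                mine = S.exact_signed_rank(d).p_value
                assert mine == pytest.approx(recursive_signed_rank_p(d), rel=1e-12)
                scipy_p = sps.wilcoxon(d, method="exact").pvalue
                assert mine == pytest.approx(scipy_p, rel=1e-12)

    def test_rank_sum_matches_scipy_exact_all_small_n(self):
        rng = np.random.default_rng(22)
        for n1 in range(3, 9):
            for n2 in range(3, 9):
                a, b = rng.normal(size=n1), rng.normal(size=n2) + 0.5
                mine = S.exact_rank_sum(a, b).p_value
                scipy_p = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
                assert mine == pytest.approx(scipy_p, rel=1e-12)

    def test_tied_data_uses_midranks(self):
        # ties force enumeration over the observed midrank structure
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0])
        res = S.exact_signed_rank(d)
        assert res.p_value == pytest.approx(recursive_signed_rank_p(d), rel=1e-12)


class TestSignificanceLadder:
    @pytest.mark.parametrize(
        "p,mark",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "°"), (0.5, "-")],
    )
    def test_annotation(self, p, mark):
        assert S.significance_ladder(p) == mark


class TestCorrelationNetwork:
    def test_perfect_linear_edges(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x, "w": rng.normal(size=12)})
        edges = S.correlation_network(df, threshold=0.95)
        pairs = {(r.var1, r.var2): r.r for r in edges.itertuples()}
        assert pairs[("x", "y")] == pytest.approx(1.0)
        assert pairs[("x", "z")] == pytest.approx(-1.0)  # sign retained

    def test_constant_variable_excluded(self):
        df = pd.DataFrame({"x": np.arange(6.0), "c": 5.0, "y": np.arange(6.0) ** 2})
        edges = S.correlation_network(df, threshold=0.1)
        assert not {"c"} & set(edges["var1"]).union(edges["var2"])

    def test_null_rarely_exceeds_threshold(self):
        # independent variables, n=12: |r| >= 0.5 in well under 10% of draws
        rng = np.random.default_rng(8)
        xs = rng.normal(size=(1000, 12))
        ys = rng.normal(size=(1000, 12))
        r = np.array([np.corrcoef(x, y)[0, 1] for x, y in zip(xs, ys)])
        assert (np.abs(r) < 0.5).mean() >= 0.90


class TestPca:
    def test_two_correlated_variables_single_component(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 3 * x + 2})
        res = S.pca_describe(df)
        assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction_orthogonality_and_unit_loadings(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        res = S.pca_describe(df)
        Z = (df - df.mean()) / df.std(ddof=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0, atol=1e-10
        )
        assert np.all(np.diff(res.variance_pct) <= 1e-9)
        assert res.variance_pct.sum() <= 100.0 + 1e-9

    def test_identity_covariance_equal_shares(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        res = S.pca_describe(df)
        np.testing.assert_allclose(res.variance_pct, 25.0, atol=5.0)

    def test_v_statistic_zero_for_grand_mean_category(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        # a category equal to the whole sample has the grand mean
        res = S.pca_describe(df, groups=["all"] * 20)
        assert np.allclose(res.category_description["v"], 0.0)

    def test_mean_imputation_and_zero_variance_drop(self):
        df = pd.DataFrame(
            {"a": [1.0, np.nan, 3.0, 4.0], "b": [2.0, 1.0, 0.0, -1.0], "c": 7.0}
        )
        res = S.pca_describe(df)
        assert res.imputed_cells == 1
        assert res.dropped_columns == ["c"]

    def test_group_centroids_separate_along_pc1(self):
        # two groups shifted on every variable must discriminate on PC1
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, size=(15, 4))
        b = rng.normal(3, 1, size=(15, 4))
        df = pd.DataFrame(np.vstack([a, b]), columns=list("abcd"))
        groups = ["g1"] * 15 + ["g2"] * 15
        res = S.pca_describe(df, groups=groups)
        cats = res.category_description.query("component == 'PC1'").set_index("category")
        assert np.sign(cats.loc["g1", "v"]) != np.sign(cats.loc["g2", "v"])
        assert min(cats.loc["g1", "p"], cats.loc["g2", "p"]) < 0.001


class TestGroupReport:
    def test_report_structure_and_annotations(self):
        rng = np.random.default_rng(10)
        rows = []
        for sex in ("F", "M"):
            for i in range(6):
                aid = f"{sex}{i}"
                base = 100 + rng.normal(0, 5)
                rows.append(dict(animal_id=aid, sex=sex, condition="CTL", variable="bm", value=base))
                rows.append(dict(animal_id=aid, sex=sex, condition="CR", variable="bm", value=base * 0.85))
        report = S.build_group_report(pd.DataFrame(rows))
        assert len(report) == 1
        row = report.iloc[0]
        # every animal lost mass: the paired contrast is the enumeration floor
        assert row["p_cr_F"] == pytest.approx(2 / 64)
        assert row["sig_cr_F"] == "*"
        assert row["v_f_pct"] == pytest.approx(-15.0, abs=1e-6)
        assert {"F_ctl", "M_ctl", "F_cr", "M_cr", "v_m_pct", "sig_sex_response"} <= set(report.columns)
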