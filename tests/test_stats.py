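import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from erpdecode.stats import (age_compare, cd_diagram, cd_over_time,
                             compare_classifiers, friedman,
                             max_auroc_per_participant, nemenyi_cd,
                             pairwise_wilcoxon_holm, significant_intervals)


class TestFriedman:
    def test_identical_columns_give_zero_stat(self):
        M = np.tile([0.7], (6, 4))
        stat, p = friedman(M)
        assert stat == 0.0 and p == 1.0

    def test_strict_dominance_gives_maximal_statistic(self, rng):
        n, k = 8, 5
        M = rng.normal(size=(n, k))
        M[:, 0] += 100  # classifier 0 wins every row
        M = np.sort(M, axis=1)  # perfectly consistent ranking everywhere
        stat, p = friedman(M)
        # the maximal chi-square-form value for perfectly consistent ranks
        expected_max = n * (k - 1)
        assert stat == pytest.approx(expected_max)
        assert p < 1e-4

    def test_matches_scipy_on_random_matrices(self, rng):
        for _ in range(100):
            M = rng.normal(size=(rng.integers(4, 12), rng.integers(3, 7)))
            stat, p = friedman(M)
            ref = sps.friedmanchisquare(*M.T)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_too_few_classifiers_rejected(self):
        with pytest.raises(ValueError):
            friedman(np.zeros((5, 2)))


class TestPairwiseWilcoxonHolm:
    def cols(self, M):
        return pd.DataFrame(M, columns=[f"c{i}" for i in range(M.shape[1])])

    def test_identical_columns_all_one(self):
        M = np.tile(np.arange(8.0)[:, None], (1, 4))
        adj = pairwise_wilcoxon_holm(self.cols(M))
        assert all(p == 1.0 for p in adj.values())

    def test_holm_adjustment_matches_manual_stepdown(self, rng):
        M = rng.normal(size=(12, 4))
        M[:, 0] += 1.0
        df = self.cols(M)
        adj = pairwise_wilcoxon_holm(df)
        # manual Holm on the raw Wilcoxon p-values
        raw = {}
        names = list(df.columns)
        for i in range(4):
            for j in range(i + 1, 4):
                raw[(names[i], names[j])] = sps.wilcoxon(
                    M[:, i], M[:, j], zero_method="wilcox").pvalue
        order = sorted(raw, key=raw.get)
        m = len(order)
        running = 0.0
        expected = {}
        for rank, pair in enumerate(order):
            val = min(1.0, (m - rank) * raw[pair])
            running = max(running, val)
            expected[pair] = running
        for pair, p in expected.items():
            assert adj[pair] == pytest.approx(p, rel=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        M = rng.normal(size=(10, 5))
        df = self.cols(M)
        adj = pairwise_wilcoxon_holm(df)
        names = list(df.columns)
        for (a, b), p in adj.items():
            raw = sps.wilcoxon(df[a], df[b], zero_method="wilcox").pvalue
            assert p >= raw - 1e-15


class TestNemenyiCd:
    def test_nine_classifiers_seventy_participants(self):
        assert 1.34 <= nemenyi_cd(9, 70, 0.05) <= 1.56

    def test_two_methods_scale_with_inverse_sqrt_n(self):
        a, b = nemenyi_cd(2, 10), nemenyi_cd(2, 40)
        assert a / b == pytest.approx(2.0, rel=1e-9)

    def test_quadrupling_n_halves_cd(self):
        assert nemenyi_cd(6, 30) / nemenyi_cd(6, 120) == pytest.approx(2.0)

    def test_matches_published_q_table(self):
        # Nemenyi q_0.05 values (studentized range / sqrt(2)), k = 2..10
        published = [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031,
                     3.102, 3.164]
        for k, q in zip(range(2, 11), published):
            ours = nemenyi_cd(k, 1, 0.05) / np.sqrt(k * (k + 1) / 6.0)
            assert ours == pytest.approx(q, abs=2e-3)

    def test_untabulated_alpha_rejected(self):
        with pytest.raises(ValueError, match="not tabulated"):
            nemenyi_cd(5, 20, alpha=0.2)


class TestCdDiagram:
    def make_comparison(self, M, names):
        return compare_classifiers(pd.DataFrame(M, columns=names))

    def test_three_separated_clusters_recovered(self, rng):
        n = 20
        M = np.column_stack([
            rng.normal(0.9, 0.01, n), rng.normal(0.9, 0.01, n),
            rng.normal(0.7, 0.01, n), rng.normal(0.7, 0.01, n),
            rng.normal(0.5, 0.01, n), rng.normal(0.5, 0.01, n),
        ])
        comp = self.make_comparison(M, list("abcdef"))
        groups = cd_diagram(comp)["groups"]
        assert {frozenset(g) for g in groups} == {
            frozenset({"a", "b"}), frozenset({"c", "d"}),
            frozenset({"e", "f"})}

    def test_no_differences_single_group(self, rng):
        M = rng.normal(0.7, 0.001, size=(6, 4)) + rng.normal(
            0, 0.2, size=(6, 1))
        comp = self.make_comparison(M, list("abcd"))
        # with pure row effects, columns are exchangeable: one big group
        groups = cd_diagram(comp)["groups"]
        assert any(len(g) == 4 for g in groups)

    def test_mean_ranks_sum_invariant(self, rng):
        M = rng.normal(size=(15, 6))
        comp = self.make_comparison(M, list("abcdef"))
        k = 6
        assert comp.mean_ranks.sum() == pytest.approx(k * (k + 1) / 2)


class TestCdOverTime:
    def test_equal_classifiers_no_markers(self, rng):
        mats = []
        for _ in range(4):
            base = rng.normal(0.7, 0.1, size=(10, 1))
            mats.append(pd.DataFrame(
                np.repeat(base, 4, axis=1)
                + rng.normal(0, 1e-4, size=(10, 4)),
                columns=["lda", "rf", "xgb", "knn"]))
        trc = cd_over_time(mats, np.arange(4.0))
        for member in trc.clusters.values():
            sig_times = trc.friedman_p <= 0.05
            assert not member.to_numpy()[~sig_times].any()

    def test_dominance_window_clusters_with_lda(self, rng):
        cols = ["lda", "logreg", "rf", "knn"]
        quiet = [pd.DataFrame(rng.normal(0.5, 0.05, size=(12, 4)),
                              columns=cols) for _ in range(2)]
        strong = []
        for _ in range(2):
            M = rng.normal(0.5, 0.02, size=(12, 4))
            M[:, 0] += 0.3  # lda dominant
            M[:, 1] += 0.3  # logreg indistinguishable from lda
            strong.append(pd.DataFrame(M, columns=cols))
        trc = cd_over_time(quiet + strong, np.arange(4.0),
                           representatives=("lda",))
        member = trc.clusters["lda"].to_numpy()
        assert not member[:2].any()  # quiet times: no markers
        assert member[2:, 1].all()  # logreg joins lda's cluster
        assert not member[2:, 2].any()  # rf does not


class TestAgeCompare:
    def test_equal_groups_p_near_one(self):
        vals = np.linspace(0.6, 0.9, 10)
        df = pd.DataFrame({
            "value": np.concatenate([vals, vals]),
            "group": ["young"] * 10 + ["older"] * 10,
        })
        res = age_compare(df)
        (pair, p), = res.pairwise_p.items()
        assert p == pytest.approx(1.0)

    def test_group_swap_flips_t_same_p(self, rng):
        a = rng.normal(0.8, 0.05, 20)
        b = rng.normal(0.7, 0.05, 20)
        df1 = pd.DataFrame({"value": np.r_[a, b],
                            "group": ["young"] * 20 + ["older"] * 20})
        df2 = pd.DataFrame({"value": np.r_[b, a],
                            "group": ["young"] * 20 + ["older"] * 20})
        r1, r2 = age_compare(df1), age_compare(df2)
        (t1,), (t2,) = r1.pairwise_t.values(), r2.pairwise_t.values()
        (p1,), (p2,) = r1.pairwise_p.values(), r2.pairwise_p.values()
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_at_reported_effect_scale(self):
        # analytic oracle: two-sample t power for gap 0.06, sd 0.1,
        # n = 27/43 via the noncentral t distribution
        n1, n2, gap, sd = 27, 43, 0.06, 0.1
        df_ = n1 + n2 - 2
        ncp = gap / (sd * np.sqrt(1 / n1 + 1 / n2))
        crit = sps.t.ppf(0.975, df_)
        power = (1 - sps.nct.cdf(crit, df_, ncp)
                 + sps.nct.cdf(-crit, df_, ncp))
        hits = 0
        reps = 100
        rng = np.random.default_rng(202)
        for _ in range(reps):
            y = rng.normal(0.8, sd, n1)
            o = rng.normal(0.8 - gap, sd, n2)
            df = pd.DataFrame({"value": np.r_[y, o],
                               "group": ["young"] * n1 + ["older"] * n2})
            res = age_compare(df)
            (_, p), = res.pairwise_p.items()
            hits += p < 0.05
        # empirical rate consistent with the analytic power (99% binomial)
        half = 2.576 * np.sqrt(reps * power * (1 - power))
        assert abs(hits - reps * power) <= half
        assert hits / reps > 0.5

    def test_single_member_cell_rejected(self):
        df = pd.DataFrame({"value": [0.7, 0.8, 0.9],
                           "group": ["young", "young", "older"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            age_compare(df)


class TestMaxAuroc:
    def timecourse(self, series):
        rows = []
        for t, v in enumerate(series):
            for fold in range(3):
                rows.append({"participant": "p0", "group": "young",
                             "classifier": "lda", "time_ms": float(t),
                             "fold": fold, "auroc": v})
        return pd.DataFrame(rows)

    def test_constant_series(self):
        out = max_auroc_per_participant(self.timecourse([0.7, 0.7, 0.7]))
        assert out["max_auroc"].iloc[0] == pytest.approx(0.7)

    def test_monotone_series_takes_final(self):
        out = max_auroc_per_participant(self.timecourse([0.5, 0.6, 0.9]))
        assert out["max_auroc"].iloc[0] == pytest.approx(0.9)

    def test_max_at_least_time_mean(self, rng):
        series = rng.uniform(0.4, 0.9, size=12)
        out = max_auroc_per_participant(self.timecourse(series))
        assert out["max_auroc"].iloc[0] >= series.mean() - 1e-12


class TestSignificantIntervals:
    def test_no_significant_points(self):
        assert significant_intervals(np.arange(5.0), np.full(5, 0.5)) == []

    def test_single_point_degenerate_interval(self):
        p = np.array([0.5, 0.001, 0.5])
        assert significant_intervals(np.array([0.0, 10.0, 20.0]), p) == [
            (10.0, 10.0)]

    def test_two_constructed_runs(self):
        times = np.arange(8.0) * 10
        p = np.array([0.5, 0.001, 0.002, 0.5, 0.5, 0.003, 0.004, 0.5])
        assert significant_intervals(times, p) == [(10.0, 20.0), (50.0, 60.0)]
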