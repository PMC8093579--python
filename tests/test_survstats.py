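"""Survival and shared statistical kernel."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, kstest

from crcsig.survstats import (
    bh_fdr,
    cox_fit,
    fisher_or_chisq,
    km_estimate,
    logrank_test,
    methylation_binarize,
    silencing_screen,
    wilcoxon_tests,
)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = km_estimate([2, 3, 5], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km.survival_at([1, 2, 4, 5]),
                                   [1.0, 2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_single_event_step(self):
        km = km_estimate([1, 2, 3, 4], [0, 1, 0, 0])
        assert km.survival_at(2.0) == pytest.approx(2 / 3)  # 3 at risk at t=2

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        km = km_estimate(t, np.ones(50, dtype=int))
        grid = np.quantile(t, [0.1, 0.5, 0.9])
        emp = [(t > g).mean() for g in grid]
        np.testing.assert_allclose(km.survival_at(grid), emp, atol=1e-12)

    def test_negative_time_fatal(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        stat, p = logrank_test(t + t, e + e, [0] * 6 + [1] * 6)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = rng.integers(0, 2, 60)
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2)

    def test_power_against_planted_hazard(self):
        """HR=3 at n=200/arm is detected at p<0.01 in nearly all runs."""
        hits = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            g = np.repeat([0, 1], 200)
            lam = np.where(g == 1, 0.3, 0.1)
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 20, 400)
            time_, ev = np.minimum(t, c), (t <= c).astype(int)
            _, p = logrank_test(time_, ev, g)
            hits += p < 0.01
        assert hits >= 0.95 * n_sim

    def test_equals_cox_score_test(self, rng):
        """Two-group log-rank equals the Cox score test on tie-free data."""
        for s in range(5):
            r = np.random.default_rng(s)
            t = r.exponential(1, 50)
            e = r.integers(0, 2, 50)
            e[:5] = 1
            g = r.integers(0, 2, 50).astype(float)
            stat, _ = logrank_test(t, e, g)
            fit = cox_fit(t, e, g[:, None])
            assert stat == pytest.approx(fit.score_stat, abs=1e-6)


class TestCox:
    def test_matches_lifelines_on_fixture(self):
        """Log HR agrees with an independent implementation to 1e-6."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        n = 20
        x = rng.integers(0, 2, n).astype(float)
        t = np.round(rng.exponential(1 / (0.2 * np.exp(0.8 * x))), 1) + 0.1
        e = rng.integers(0, 2, n)
        e[:4] = 1
        fit = cox_fit(t, e, x[:, None], names=["x"])
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
        assert fit.params[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.bse[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_null_wald_p_uniform(self):
        """Under the null the Wald p-values are U(0,1) (KS check)."""
        ps = []
        for s in range(500):
            rng = np.random.default_rng(20_000 + s)
            n = 60
            x = rng.normal(size=n)
            t = rng.exponential(1, n)
            c = rng.uniform(0, 3, n)
            fit = cox_fit(np.minimum(t, c), (t <= c).astype(int), x[:, None])
            if not fit.non_estimable:
                ps.append(fit.pvalues[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_non_estimable(self):
        fit = cox_fit([1, 2, 3, 4], [1, 1, 0, 1], np.zeros((4, 1)))
        assert fit.non_estimable
        assert np.isnan(fit.pvalues).all()

    def test_separation_flagged(self):
        # all events in one level -> monotone likelihood
        t = [1, 2, 3, 4, 5, 6, 7, 8]
        e = [1, 1, 1, 1, 0, 0, 0, 0]
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        fit = cox_fit(t, e, x[:, None])
        assert fit.non_estimable

    def test_collinear_covariate_dropped(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        t = rng.exponential(1, n)
        fit = cox_fit(t, np.ones(n, dtype=int), X)
        assert "b" in fit.dropped
        assert np.isfinite(fit.params[0])


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_definition(self, rng):
        """Equality with the literal step-up definition on random vectors."""
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            out = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, p[i] * m / rank_from_top)
                out[i] = val
                prev = val
            return out

        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_output_bounds_and_order(self, p):
        adj = bh_fdr(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_fatal(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFisherChisq:
    def test_balanced_table(self):
        res = fisher_or_chisq([[5, 5], [5, 5]])
        assert res["p"] == pytest.approx(1.0)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_diagonal_table_exact(self):
        from scipy.special import comb

        res = fisher_or_chisq([[10, 0], [0, 10]])
        assert res["test"] == "fisher"
        assert res["p"] == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_zero_margin(self):
        res = fisher_or_chisq([[0, 0], [3, 4]])
        assert res["p"] == 1.0
        assert np.isnan(res["odds_ratio"])

    def test_expected_count_rule_picks_chisq(self):
        res = fisher_or_chisq([[20, 30], [25, 25]])
        assert res["test"] == "chi2"

    def test_fisher_matches_enumeration_oracle(self):
        """Two-sided Fisher p equals exhaustive hypergeometric enumeration
        for all tables with margins <= 15."""
        checked = 0
        for r1, c1, n in itertools.product([4, 7, 11, 15], repeat=3):
            if r1 > n or c1 > n or n > 15:
                continue
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                table = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                res = fisher_or_chisq(table)
                if res["test"] != "fisher":
                    continue
                support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                probs = {k: hypergeom.pmf(k, n, c1, r1) for k in support}
                p_obs = probs[a]
                p_two = sum(pv for pv in probs.values()
                            if pv <= p_obs * (1 + 1e-9))
                assert res["p"] == pytest.approx(min(1.0, p_two), rel=1e-9)
                checked += 1
        assert checked > 50


class TestWilcoxon:
    def test_identical_paired_p_one(self):
        x = np.arange(1.0, 9.0)
        stat, p = wilcoxon_tests(x, x, paired=True)
        assert p == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(1, 1, size=18)
        _, p1 = wilcoxon_tests(x, y)
        _, p2 = wilcoxon_tests(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_exact_p_matches_enumeration(self):
        """Exact rank-sum p for n=(5,5) equals full enumeration of the
        rank-sum null distribution."""
        x = np.array([1.2, 2.4, 3.1, 7.7, 9.3])
        y = np.array([0.5, 2.9, 4.4, 5.1, 6.2])
        _, p = wilcoxon_tests(x, y)
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:5].sum()
        null = [sum(combo) for combo in itertools.combinations(ranks, 5)]
        null = np.array(null)
        mean = null.mean()
        p_enum = np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-9)
        assert p == pytest.approx(p_enum, rel=1e-9)


class TestMethylation:
    @pytest.mark.parametrize("beta,expected", [(0.35, True), (0.29, False),
                                               (0.3, True)])
    def test_binarization_threshold(self, beta, expected):
        assert methylation_binarize(beta) is expected

    def test_threshold_zero_all_methylated(self):
        assert methylation_binarize(np.array([0.0, 0.5, 1.0]), 0.0).all()

    def test_beta_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            methylation_binarize(1.2)

    def test_silencing_screen_flags_planted_gene(self, rng):
        n = 50
        beta = pd.DataFrame(
            {f"s{i}": [0.7 if i < n else 0.05, 0.5 if i < n else 0.1]
             for i in range(2 * n)},
            index=["silenced", "active"],
        )
        expr = pd.DataFrame(
            {
                f"s{i}": [
                    rng.normal(2 if i < n else 8, 1),   # silenced when methylated
                    rng.normal(5, 1),                   # no expression difference
                ]
                for i in range(2 * n)
            },
            index=["silenced", "active"],
        )
        res = silencing_screen(expr, beta, min_abs_diff=1.0, p_max=0.05)
        assert res.loc["silenced", "silenced"]
        assert not res.loc["active", "silenced"]

    def test_direction_matters(self, rng):
        # methylated group HIGHER -> never flagged
        n = 30
        beta = pd.DataFrame({f"s{i}": [0.8 if i < n else 0.1]
                             for i in range(2 * n)}, index=["g"])
        expr = pd.DataFrame({f"s{i}": [rng.normal(9 if i < n else 2, 1)]
                             for i in range(2 * n)}, index=["g"])
        res = silencing_screen(expr, beta)
        assert not res.loc["g", "silenced"]
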