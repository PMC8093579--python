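"""Gene-pair encoding, filters, Cox screening and the consensus rule."""

import numpy as np
import pandas as pd
import pytest

from crcsig.pairs import (
    ExpressionCohort,
    assess_independence,
    build_pair_matrix,
    consensus_select,
    deg_screen,
    imbalance_filter,
    metastasis_association,
    screen_pairs,
)
from crcsig.simulate import BATCH_TRANSFORMS, CohortSimSpec, simulate_cohorts


def _expr(data, samples=None):
    df = pd.DataFrame(data).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestDegScreen:
    def test_log2fc_formula(self):
        # normalized group means 40 vs 10 with pseudocount 1
        assert np.log2(41 / 11) == pytest.approx(1.898, abs=1e-3)

    def test_identical_groups_not_selected(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(30, 20)),
                              index=[f"g{i}" for i in range(30)])
        labels = [0] * 10 + [1] * 10
        res = deg_screen(counts, labels)
        assert res["log2fc"].abs().max() < 1.0 or not res["selected"].any()

    def test_planted_up_genes_recovered(self):
        """20 planted 4-fold genes in 400 recovered; nulls controlled."""
        rng = np.random.default_rng(77)
        n_genes, n = 400, 60
        labels = np.repeat([0, 1], n // 2)
        base = rng.uniform(20, 80, n_genes)
        counts = rng.poisson(base[:, None], size=(n_genes, n)).astype(float)
        planted = np.arange(20)
        counts[np.ix_(planted, labels == 0)] = rng.poisson(
            4 * base[planted][:, None], size=(20, n // 2)
        )
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)])
        res = deg_screen(df, labels)
        recovered = res.iloc[planted]["selected"].sum()
        false = res.iloc[20:]["selected"].sum()
        assert recovered >= 18
        assert false <= 0.05 * (n_genes - 20)

    def test_small_group_fatal(self, rng):
        counts = pd.DataFrame(rng.poisson(10, size=(5, 6)))
        with pytest.raises(ValueError):
            deg_screen(counts, [0, 0, 1, 1, 1, 1])


class TestPairMatrix:
    def test_states_and_ties(self):
        expr = _expr({"A": [5.0, 3.0, 3.0], "B": [3.0, 3.0, 5.0]})
        pm = build_pair_matrix(expr, ["A", "B"])
        row = pm.loc["A|B"]
        assert row.iloc[0] == 1.0      # A > B
        assert np.isnan(row.iloc[1])   # tie -> sample discarded
        assert row.iloc[2] == 0.0      # B > A

    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, size=(10, 30)),
                            index=[f"g{i}" for i in range(10)])
        genes = list(expr.index)
        pm1 = build_pair_matrix(expr, genes)
        for name, f in BATCH_TRANSFORMS.items():
            pm2 = build_pair_matrix(expr.apply(f), genes)
            pd.testing.assert_frame_equal(pm1, pm2)

    def test_missing_gene_row_all_nan(self):
        expr = _expr({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        pm = build_pair_matrix(expr, ["A", "B", "ZZZ"])
        assert pm.loc["A|ZZZ"].isna().all()
        assert not pm.loc["A|B"].isna().any()

    def test_all_unordered_pairs_enumerated(self):
        expr = _expr({g: [1.0, 2.0] for g in "ABCD"})
        pm = build_pair_matrix(expr, list("ABCD"))
        assert len(pm) == 6


class TestImbalanceFilter:
    def _pm(self, n_a, n_b):
        vals = [1.0] * n_a + [0.0] * n_b
        return pd.DataFrame([vals], index=["A|B"],
                            columns=[f"s{i}" for i in range(n_a + n_b)])

    def test_95_percent_excluded(self):
        res = imbalance_filter(self._pm(95, 5))
        assert not res.loc["A|B", "retained"]

    def test_exactly_90_percent_retained(self):
        res = imbalance_filter(self._pm(90, 10))
        assert res.loc["A|B", "retained"]

    def test_balanced_retained(self):
        res = imbalance_filter(self._pm(50, 50))
        assert res.loc["A|B", "retained"]

    def test_no_informative_samples_not_evaluable(self):
        pm = pd.DataFrame([[np.nan, np.nan]], index=["A|B"],
                          columns=["s0", "s1"])
        res = imbalance_filter(pm)
        assert not res.loc["A|B", "evaluable"]
        assert not res.loc["A|B", "retained"]


class TestScreenPairs:
    def _cohort_pm(self, seed, hr=2.5, n=150):
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, n)
        lam = 0.05 * hr**z
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 40, n)
        clin = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int)},
            index=[f"s{i}" for i in range(n)],
        )
        pm = pd.DataFrame([z.astype(float)], index=["A|B"],
                          columns=clin.index)
        return pm, clin

    def test_planted_hr_estimated(self):
        pm, clin = self._cohort_pm(seed=0)
        res = screen_pairs(pm, clin)
        row = res.loc["A|B"]
        assert abs(row["log_hr"] - np.log(2.5)) < 0.35
        assert row["p"] < 0.05

    def test_null_type_one_error_calibrated(self):
        """1000 independent null pairs: raw p<0.05 fraction = 0.05 +/- 0.02."""
        rng = np.random.default_rng(99)
        n = 200
        t = rng.exponential(10, n)
        c = rng.uniform(0, 30, n)
        clin = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int)},
            index=[f"s{i}" for i in range(n)],
        )
        states = rng.integers(0, 2, size=(1000, n)).astype(float)
        pm = pd.DataFrame(states, index=[f"A{i}|B{i}" for i in range(1000)],
                          columns=clin.index)
        res = screen_pairs(pm, clin)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) <= 0.02

    def test_constant_state_non_estimable(self):
        pm, clin = self._cohort_pm(seed=1)
        pm.loc["A|B"] = 1.0
        res = screen_pairs(pm, clin)
        assert not res.loc["A|B", "retained"]  # 100% imbalance
        assert np.isnan(res.loc["A|B", "p"])

    def test_fdr_at_least_p(self):
        pm, clin = self._cohort_pm(seed=2)
        res = screen_pairs(pm, clin)
        ok = res["fdr"].notna()
        assert (res.loc[ok, "fdr"] >= res.loc[ok, "p"] - 1e-12).all()


class TestConsensusSelect:
    def _screen(self, fdr, log_hr=0.9, retained=True):
        return pd.DataFrame(
            {
                "log_hr": [log_hr], "p": [fdr / 2], "fdr": [fdr],
                "retained": [retained], "estimable": [retained],
            },
            index=pd.Index(["A|B"], name="pair"),
        )

    def test_six_of_eleven_is_cpgps(self):
        screens = {f"c{i}": self._screen(0.01 if i < 6 else 0.5)
                   for i in range(11)}
        res = consensus_select(screens, min_cohorts=6)
        assert "A|B" in res.index
        assert res.loc["A|B", "n_significant"] == 6

    def test_five_of_eleven_is_not(self):
        screens = {f"c{i}": self._screen(0.01 if i < 5 else 0.5)
                   for i in range(11)}
        res = consensus_select(screens, min_cohorts=6)
        assert "A|B" not in res.index

    def test_excluded_cohorts_never_counted(self):
        screens = {f"c{i}": self._screen(0.01) for i in range(6)}
        screens["c5"] = self._screen(0.01, retained=False)
        res = consensus_select(screens, min_cohorts=6)
        assert "A|B" not in res.index  # only 5 countable cohorts

    def test_empty_input(self):
        assert consensus_select({}, 6).empty

    def test_direction_consistency_flag(self):
        screens = {f"c{i}": self._screen(0.01, log_hr=0.9) for i in range(6)}
        screens["c0"] = self._screen(0.01, log_hr=-0.9)
        res = consensus_select(screens, min_cohorts=6)
        assert not res.loc["A|B", "direction_consistent"]


class TestMetastasis:
    def test_no_association(self):
        state = pd.Series([1.0] * 10 + [0.0] * 10,
                          index=[f"s{i}" for i in range(20)])
        met = pd.Series(["M1"] * 5 + ["M0"] * 5 + ["M1"] * 5 + ["M0"] * 5,
                        index=state.index)
        res = metastasis_association(state, met)
        assert res["p"] == pytest.approx(1.0)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_perfect_association_exact_p(self):
        from scipy.special import comb

        state = pd.Series([1.0] * 10 + [0.0] * 10,
                          index=[f"s{i}" for i in range(20)])
        met = pd.Series(["M1"] * 10 + ["M0"] * 10, index=state.index)
        res = metastasis_association(state, met)
        assert res["p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_absent_state_not_evaluable(self):
        state = pd.Series([1.0] * 10, index=[f"s{i}" for i in range(10)])
        met = pd.Series(["M0"] * 5 + ["M1"] * 5, index=state.index)
        res = metastasis_association(state, met)
        assert not res["evaluable"]

    def test_planted_rates_detected_in_most_cohorts(self, planted_cohorts):
        """40% vs 15% metastasis at n=150: significant in >= 6/7 cohorts."""
        cohorts, truth, spec = planted_cohorts
        # reuse 6 planted cohorts + 1 extra seed for the 7-cohort setting
        extra, _ = simulate_cohorts(
            CohortSimSpec(seed=703, n_cohorts=1)
        )
        hits = 0
        for c in cohorts + extra:
            pm = build_pair_matrix(c.expr, [truth.pair.split("|")[0],
                                            truth.pair.split("|")[1]])
            res = metastasis_association(pm.loc[truth.pair],
                                         c.clinical["metastasis"])
            hits += res["p"] < 0.05
        assert hits >= 6


class TestIndependence:
    def test_covariate_free_call_matches_screen(self, planted_cohorts):
        cohorts, truth, _ = planted_cohorts
        c = cohorts[0]
        pm = build_pair_matrix(c.expr, truth.pair.split("|"))
        screen = screen_pairs(pm, c.clinical)
        fit = assess_independence(pm.loc[truth.pair], c.clinical)
        assert fit.params[0] == pytest.approx(screen.loc[truth.pair, "log_hr"],
                                              abs=1e-9)

    def test_independent_of_uninformative_covariate(self, planted_cohorts):
        cohorts, truth, _ = planted_cohorts
        c = cohorts[0]
        rng = np.random.default_rng(0)
        pm = build_pair_matrix(c.expr, truth.pair.split("|"))
        covs = pd.DataFrame({"age": rng.normal(60, 10, len(c.samples))},
                            index=c.samples)
        fit = assess_independence(pm.loc[truth.pair], c.clinical, covs)
        assert fit.pvalues[0] < 0.05  # pair effect survives adjustment

    def test_mediated_effect_not_significant(self):
        """When the covariate fully drives hazard, the pair adds nothing."""
        rng = np.random.default_rng(8)
        n = 200
        stage = rng.integers(0, 2, n).astype(float)
        # pair state is a noisy copy of stage; hazard depends on stage only
        state = np.where(rng.uniform(size=n) < 0.9, stage, 1 - stage)
        lam = 0.05 * np.exp(1.2 * stage)
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 40, n)
        idx = [f"s{i}" for i in range(n)]
        clin = pd.DataFrame({"time": np.minimum(t, c),
                             "event": (t <= c).astype(int)}, index=idx)
        fit = assess_independence(
            pd.Series(state, index=idx), clin,
            pd.DataFrame({"stage": stage}, index=idx),
        )
        assert fit.pvalues[0] > 0.05


class TestEndToEnd:
    def test_planted_pair_recovered_as_cpgps(self, planted_cohorts):
        """Across 6 batch-distorted cohorts the planted pair is the CPGPS."""
        from crcsig.pairs import GenePairScreen

        cohorts, truth, _ = planted_cohorts
        res = GenePairScreen(cohorts, truth.candidate_genes).fit()
        assert truth.pair in res.cpgps.index
        assert len(res.cpgps) - 1 <= 1
        assert res.cpgps.loc[truth.pair, "direction_consistent"]

    def test_null_hazard_yields_no_cpgps(self):
        """With HR=1 and equal metastasis rates no CPGPS is reported."""
        from crcsig.pairs import GenePairScreen
        from crcsig.simulate import CohortSimSpec, PlantedPair, simulate_cohorts

        misses = 0
        n_seeds = 8
        for seed in range(300, 300 + n_seeds):
            spec = CohortSimSpec(
                seed=seed, n_samples=80, n_genes=60,
                n_candidate_noise_genes=6,
                pair=PlantedPair(hazard_ratio=1.0,
                                 metastasis_rates=(0.25, 0.25)),
            )
            cohorts, truth = simulate_cohorts(spec)
            res = GenePairScreen(cohorts, truth.candidate_genes).fit()
            misses += len(res.cpgps) == 0
        assert misses >= 0.95 * n_seeds


class TestCohortValidation:
    def test_mismatched_samples_aligned(self):
        expr = _expr({"A": [1.0, 2.0, 3.0], "B": [3.0, 2.0, 1.0]},
                     samples=["s0", "s1", "s2"])
        clin = pd.DataFrame({"time": [5.0, 6.0], "event": [1, 0]},
                            index=["s1", "s2"])
        c = ExpressionCohort("X", expr, clin)
        assert c.samples == ["s1", "s2"]

    def test_negative_time_fatal(self):
        expr = _expr({"A": [1.0], "B": [2.0]}, samples=["s0"])
        clin = pd.DataFrame({"time": [-1.0], "event": [1]}, index=["s0"])
        with pytest.raises(ValueError):
            ExpressionCohort("X", expr, clin)
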