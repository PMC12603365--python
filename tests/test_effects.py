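"""Effect estimation: 2x2 odds ratios, group tests, ML/Firth logistic."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

import strokemap as sm
from strokemap.effects import (
    ContingencyTable2x2,
    SeparationError,
    build_design,
    compare_groups,
    fit_logistic,
    odds_ratio_2x2,
)
from strokemap.pipeline import table_fixtures

# Published univariable odds ratios (point, 95% CI) for the nine
# low-vs-high-TMT outcome tables; recomputed here from the raw counts.
PUBLISHED_ORS = {
    "dysphagia": (2.29, 1.53, 3.42),
    "end": (2.44, 1.57, 3.80),
    "inhosp_recovery": (0.57, 0.38, 0.86),
    "postdischarge_recovery": (0.54, 0.35, 0.85),
    "chronic_recovery": (0.84, 0.53, 1.35),
    "mrs3_ge3": (3.02, 2.07, 4.42),
    "mrs3_ge4": (3.75, 2.45, 5.74),
    "mrs1y_ge3": (3.00, 2.03, 4.44),
    "mrs1y_ge4": (3.09, 2.01, 4.77),
}


class TestOddsRatio2x2:
    @pytest.mark.parametrize("outcome", sorted(PUBLISHED_ORS))
    def test_published_tables_reproduce(self, outcome):
        est = odds_ratio_2x2(table_fixtures()[outcome])
        point, lo, hi = PUBLISHED_ORS[outcome]
        assert round(est.or_point, 2) == point
        assert round(est.ci_low, 2) == lo
        assert round(est.ci_high, 2) == hi

    def test_unit_table_symmetry(self):
        est = odds_ratio_2x2(ContingencyTable2x2(1, 1, 1, 1))
        assert est.or_point == pytest.approx(1.0)

    def test_closed_form(self):
        est = odds_ratio_2x2(ContingencyTable2x2(12, 34, 5, 67))
        assert est.or_point == pytest.approx(12 * 67 / (34 * 5), rel=1e-14)

    def test_zero_cell_haldane_flagged(self):
        est = odds_ratio_2x2(ContingencyTable2x2(0, 10, 5, 5))
        assert est.continuity_corrected
        assert est.or_point == pytest.approx(0.5 * 5.5 / (10.5 * 5.5))

    def test_ci_shrinks_with_scale(self):
        small = odds_ratio_2x2(ContingencyTable2x2(5, 10, 9, 35))
        big = odds_ratio_2x2(ContingencyTable2x2(50, 100, 90, 350))
        assert big.or_point == pytest.approx(small.or_point)
        assert (big.ci_high / big.ci_low) < (small.ci_high / small.ci_low)


class TestCompareGroups:
    def test_identical_groups_null(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        g = np.r_[np.zeros(15), np.ones(15), np.zeros(15), np.ones(15)]
        res = compare_groups(x, g)
        assert res.p > 0.99

    def test_dysphagia_table_chi2(self):
        vals = np.r_[np.ones(55), np.zeros(96), np.ones(90), np.zeros(359)]
        grp = np.r_[np.ones(151), np.zeros(449)]
        res = compare_groups(vals, grp)
        assert res.test == "chi2"
        assert res.p < 0.001

    def test_fisher_matches_hypergeometric_tail_enumeration(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities no larger than the observed one."""
        a, b, c, d = 2, 8, 9, 1
        vals = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        grp = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = compare_groups(vals, grp)
        assert res.test == "fisher"
        n, K, N = a + b + c + d, a + c, a + b
        rv = stats.hypergeom(n, K, N)
        p_obs = rv.pmf(a)
        oracle = sum(
            rv.pmf(k) for k in range(max(0, N + K - n), min(K, N) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-10)
        )
        assert res.p == pytest.approx(oracle, rel=1e-8)

    def test_continuous_dispatch(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        g = np.r_[np.zeros(50), np.ones(50)]
        res = compare_groups(x, g)
        assert res.test in ("t", "mannwhitney")
        assert res.p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(10), np.ones(10))


def _expand_2x2(a, b, c, d):
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = np.column_stack([np.ones_like(x), x])
    return X, y


class TestFitLogistic:
    def test_saturated_2x2_equals_closed_form(self):
        a, b, c, d = 55, 96, 90, 359
        X, y = _expand_2x2(a, b, c, d)
        fit = fit_logistic(X, y, method="ml")
        assert np.exp(fit.beta[1]) == pytest.approx(a * d / (b * c), rel=1e-8)

    def test_ml_matches_statsmodels(self, frame600):
        statsmodels = pytest.importorskip("statsmodels.api")
        df, _ = frame600
        X, names = build_design(df, ["low_tmt", "age", "sex", "admission_nihss"])
        y = df["end"].to_numpy(dtype=float)
        fit = fit_logistic(X, y, method="ml", term_names=names)
        ref = statsmodels.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)

    def test_separation_raises_advising_firth(self):
        x = np.r_[np.zeros(4), np.ones(4)]
        X = np.column_stack([np.ones(8), x])
        with pytest.raises(SeparationError, match="firth"):
            fit_logistic(X, x.copy(), method="ml")

    def test_separation_flag_when_allowed(self):
        x = np.r_[np.zeros(4), np.ones(4)]
        X = np.column_stack([np.ones(8), x])
        fit = fit_logistic(X, x.copy(), method="ml", allow_separation=True)
        assert fit.separation_detected

    def test_firth_finite_matches_penalized_likelihood_oracle(self):
        """On a completely separated design, the Firth fit agrees with a
        direct numerical maximization of the explicit Jeffreys-penalized
        likelihood."""
        x = np.r_[np.zeros(4), np.ones(4)]
        X = np.column_stack([np.ones(8), x])
        y = x.copy()
        fit = fit_logistic(X, y, method="firth")
        assert fit.converged and np.all(np.isfinite(fit.beta))

        def neg_pll(beta):
            eta = X @ beta
            mu = expit(eta)
            info = (X.T * (mu * (1 - mu))) @ X
            sign, logdet = np.linalg.slogdet(info)
            ll = np.sum(y * eta - np.logaddexp(0, eta))
            return -(ll + 0.5 * logdet)

        res = minimize(neg_pll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(fit.beta, res.x, atol=1e-6)

    def test_firth_converges_to_ml_under_replication(self):
        """Replicating a dataset 64-fold makes the Jeffreys penalty
        negligible: Firth estimates approach the ML estimates."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        y = (rng.random(100) < expit(0.5 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(100), x])
        ml = fit_logistic(X, y, method="ml")
        k = 64
        Xk, yk = np.tile(X, (k, 1)), np.tile(y, k)
        firth = fit_logistic(Xk, yk, method="firth")
        assert np.max(np.abs(firth.beta - ml.beta)) < 1e-3

    def test_aliased_column_dropped_and_reported(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2 * x])
        y = (rng.random(100) < expit(x)).astype(float)
        fit = fit_logistic(X, y, term_names=["(intercept)", "x", "x2"])
        assert fit.dropped_terms == ["x2"]
        assert fit.terms == ["(intercept)", "x"]


class TestAdjustedEffect:
    def test_exposure_coding_flip_inverts_or(self, frame600):
        df, _ = frame600
        est, _ = sm.adjusted_effect(df, "low_tmt", "end")
        flipped = df.copy()
        flipped["high_tmt"] = 1.0 - flipped["low_tmt"].astype(float)
        est2, _ = sm.adjusted_effect(flipped, "high_tmt", "end")
        assert est2.or_point == pytest.approx(1.0 / est.or_point, rel=1e-6)

    def test_planted_effect_recovered(self):
        cfg = sm.SimulationConfig(n_subjects=5000, seed=202)
        df, _ = sm.analysis_frame(sm.simulate_cohort(cfg))
        est, fit = sm.adjusted_effect(df, "low_tmt", "end")
        assert fit.method == "ML" and fit.converged
        assert est.ci_low < 2.75 < est.ci_high

    def test_continuous_per_mm_decrease_is_reciprocal(self, frame600):
        df, _ = frame600
        est_inc, _ = sm.adjusted_effect(df, "tmt_mean", "dysphagia")
        est_dec, _ = sm.adjusted_effect(
            df, "tmt_mean", "dysphagia", per_unit_decrease=True
        )
        assert est_dec.or_point == pytest.approx(1.0 / est_inc.or_point, rel=1e-10)

    def test_too_few_events_rejected(self, frame600):
        df, _ = frame600
        rare = df.copy()
        rare["rare"] = 0.0
        rare.loc[rare.index[0], "rare"] = 1.0
        with pytest.raises(ValueError, match="Firth"):
            sm.adjusted_effect(rare, "low_tmt", "rare")


class TestInteractionScan:
    COVS = ["age", "sex", "admission_nihss"]

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(11)
        n = 4000
        expo = (rng.random(n) < 0.25).astype(float)
        mod = (rng.random(n) < 0.5).astype(float)
        import pandas as pd

        df = pd.DataFrame(
            {
                "low_tmt": expo,
                "mod": mod,
                "age": rng.normal(75, 6, n),
                "sex": rng.choice(["male", "female"], n),
                "admission_nihss": rng.integers(0, 20, n).astype(float),
            }
        )
        lp = -1.0 + 0.3 * expo + 0.2 * mod + 1.2 * expo * mod
        df["y"] = (rng.random(n) < expit(lp)).astype(float)
        res = sm.interaction_scan(df, "low_tmt", "y", ["mod"], covariates=self.COVS)
        assert len(res) == 1
        assert res[0].p_interaction < 0.01
        assert res[0].or_modifier_present > res[0].or_modifier_absent

    def test_constant_modifier_skipped(self, frame600):
        df, _ = frame600
        df = df.copy()
        df["always"] = 1.0
        res = sm.interaction_scan(
            df, "low_tmt", "mrs3_ge3", ["always"], covariates=self.COVS
        )
        assert res == []

    def test_sparse_stratum_takes_firth_path(self):
        rng = np.random.default_rng(3)
        n = 300
        import pandas as pd

        expo = (rng.random(n) < 0.5).astype(float)
        mod = (rng.random(n) < 0.05).astype(float)
        df = pd.DataFrame(
            {
                "low_tmt": expo,
                "mod": mod,
                "age": rng.normal(75, 6, n),
                "sex": rng.choice(["male", "female"], n),
                "admission_nihss": rng.integers(0, 20, n).astype(float),
                "y": (rng.random(n) < 0.1).astype(float),
            }
        )
        res = sm.interaction_scan(df, "low_tmt", "y", ["mod"], covariates=self.COVS)
        assert len(res) == 1
        assert res[0].method == "Firth"
        assert np.isfinite(res[0].or_modifier_present)


class TestAlternativeIntervals:
    def test_profile_ci_matches_wald_on_well_behaved_fit(self, frame600):
        """With ample events the profile interval is close to Wald and
        brackets the point estimate."""
        from strokemap.effects import profile_ci

        df, _ = frame600
        X, names = build_design(df, ["low_tmt", "age", "sex", "admission_nihss"])
        y = df["mrs3_ge3"].to_numpy(dtype=float)
        fit = fit_logistic(X, y, method="ml", term_names=names)
        lo, hi = profile_ci(X, y, fit, "low_tmt")
        i = fit.terms.index("low_tmt")
        assert lo < fit.beta[i] < hi
        assert lo == pytest.approx(fit.beta[i] - 1.96 * fit.se[i], abs=0.05)
        assert hi == pytest.approx(fit.beta[i] + 1.96 * fit.se[i], abs=0.05)

    def test_bootstrap_ci_brackets_estimate(self, frame600):
        df, _ = frame600
        est, fit = sm.adjusted_effect(
            df, "low_tmt", "mrs3_ge3",
            covariates=["age", "sex", "admission_nihss"], ci_method="bootstrap",
        )
        assert est.ci_low < est.or_point < est.ci_high
        # same order of magnitude as the Wald interval
        wald = fit.term_effect("low_tmt")
        assert est.ci_high / est.ci_low == pytest.approx(
            wald.ci_high / wald.ci_low, rel=0.5
        )
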