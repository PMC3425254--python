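import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import cnvlrr as c
from cnvlrr.assoc import (
    _joint_em,
    covariate_design,
    fit_gmm1d,
    mixture_bic,
)
from tests.conftest import called_copies


def grid_loglik_2param(y, x, b0s, b1s):
    """Brute-force profile of the 2-parameter logistic log-likelihood."""
    best = -np.inf
    arg = None
    for b0, b1 in itertools.product(b0s, b1s):
        eta = b0 + b1 * x
        mu = 1 / (1 + np.exp(-eta))
        ll = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if ll > best:
            best, arg = ll, (b0, b1)
    return best, arg


class TestFitLogistic:
    def test_balanced_intercept_only(self):
        y = np.array([0, 1] * 20)
        fit = c.fit_logistic(y, np.ones((40, 1)))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_two_by_two_table_or_six(self):
        # cases: 30 exposed / 20 unexposed; controls: 10 / 40
        y = np.concatenate([np.ones(50), np.zeros(50)])
        x = np.concatenate([np.ones(30), np.zeros(20),
                            np.ones(10), np.zeros(40)])
        fit = c.fit_logistic(y, np.column_stack([np.ones(100), x]))
        assert math.exp(fit.coef[1]) == pytest.approx(6.0, abs=1e-6)
        assert fit.coef[1] == pytest.approx(math.log(6.0), abs=1e-6)
        assert fit.converged

    def test_loglik_matches_grid_search(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 120)
        y = (rng.random(120) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(
            float
        )
        fit = c.fit_logistic(y, np.column_stack([np.ones(120), x]))
        grid, _ = grid_loglik_2param(
            y, x, np.linspace(-1, 1.5, 121), np.linspace(-0.5, 2, 121)
        )
        assert fit.loglik >= grid - 1e-3
        assert abs(fit.loglik - grid) < 0.05

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(200), rng.normal(0, 1, (200, 2))])
        y = (rng.random(200) < 0.4).astype(float)
        fit = c.fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-5)

    def test_separation_flagged_unstable(self):
        y = np.concatenate([np.zeros(20), np.ones(20)])
        x = np.concatenate([np.zeros(20), np.ones(20)])
        fit = c.fit_logistic(y, np.column_stack([np.ones(40), x]))
        assert fit.unstable

    def test_fractional_weights_supported(self):
        # weighting a duplicated design must equal the unduplicated fit
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.5).astype(float)
        X = np.column_stack([np.ones(60), x])
        plain = c.fit_logistic(y, X)
        dup = c.fit_logistic(
            np.concatenate([y, y]), np.vstack([X, X]),
            weights=np.full(120, 0.5),
        )
        assert np.allclose(plain.coef, dup.coef, atol=1e-8)

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            c.fit_logistic(np.array([0.0, 0.5]), np.ones((2, 1)))


class TestCovariateDesign:
    def _cov(self, n=40):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "gender": rng.choice(["male", "female"], n),
                "age": rng.normal(66, 10, n),
                "region": rng.choice(["R1", "R2", "R3", "R4", "R5"], n),
                "smoking": rng.choice(["never", "former", "current"], n),
            }
        )

    def test_continuous_age_columns(self):
        d = covariate_design(self._cov(), age="continuous")
        assert "age" in d.columns
        assert sum(col.startswith("region_") for col in d.columns) == 4
        assert sum(col.startswith("smoking_") for col in d.columns) == 2

    def test_quartile_age_columns(self):
        d = covariate_design(self._cov(120), age="quartiles")
        assert sum(col.startswith("age_q") for col in d.columns) == 3
        assert "age" not in d.columns

    def test_unknown_age_coding(self):
        with pytest.raises(ValueError, match="age"):
            covariate_design(self._cov(), age="splines")


class TestProbeAndTrendTests:
    def test_null_effect_or_near_one(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 4000)
        y = rng.integers(0, 2, 4000)
        res = c.trend_test(g, y)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_trend_recovery_on_called_copies(self, trend_cohort):
        cohort, probes, locus, sig_ref, _ = trend_cohort
        called = called_copies(sig_ref, probes, locus)
        res_called = c.trend_test(called, cohort.phenotype,
                                  cohort.covariates)
        res_true = c.trend_test(cohort.true_copy_number, cohort.phenotype,
                                cohort.covariates)
        assert res_called.odds_ratio == pytest.approx(0.74, abs=0.08)
        assert abs(res_called.odds_ratio - res_true.odds_ratio) < 0.03
        assert res_called.p_value < 0.01

    def test_probe_lrr_tests_protective_direction(self, trend_cohort):
        cohort, probes, locus, _, sig_cohort = trend_cohort
        results = c.probe_lrr_tests(
            sig_cohort.lrr[:, locus], cohort.phenotype, cohort.covariates,
            [probes[j].probe_id for j in locus],
        )
        assert len(results) == 5
        assert all(r.odds_ratio < 1.0 for r in results)
        assert all(r.ci_low <= r.odds_ratio <= r.ci_high for r in results)
        assert {r.predictor for r in results} == {
            probes[j].probe_id for j in locus
        }

    def test_constant_probe_rejected(self):
        lrr = np.zeros((30, 2))
        lrr[:, 1] = np.linspace(-1, 1, 30)
        y = np.tile([0, 1], 15)
        with pytest.raises(ValueError, match="degenerate"):
            c.probe_lrr_tests(lrr, y, probe_ids=["flat", "ok"])

    def test_invalid_copy_numbers_rejected(self):
        with pytest.raises(ValueError, match="copy numbers"):
            c.trend_test(np.array([0, 1, 3]), np.array([0, 1, 0]))


class TestSummarizeSignal:
    def test_single_probe_is_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 0.2, (50, 1))
        s = c.summarize_signal(x)
        assert np.allclose(s, (x[:, 0] - x[:, 0].mean()) / x[:, 0].std())

    def test_direction_matches_grid_oracle_on_two_probes(self):
        rng = np.random.default_rng(1)
        n = 300
        cls = rng.random(n) < 0.5
        Z = rng.normal(0, 0.3, (n, 2)) + np.where(cls[:, None], 1.0, -1.0)
        from cnvlrr.assoc import _lda_direction

        w = _lda_direction(Z, cls.astype(int))
        # grid over direction angle maximizing between/within ratio
        best, best_ang = -np.inf, None
        for ang in np.linspace(0, np.pi, 20001):
            d = np.array([np.cos(ang), np.sin(ang)])
            proj = Z @ d
            m0, m1 = proj[~cls].mean(), proj[cls].mean()
            within = proj[~cls].var() * (~cls).sum() + proj[cls].var() * \
                cls.sum()
            ratio = (m1 - m0) ** 2 / within
            if ratio > best:
                best, best_ang = ratio, ang
        dbest = np.array([np.cos(best_ang), np.sin(best_ang)])
        cosang = abs(float(w @ dbest))
        assert cosang > 1 - 1e-3  # within ~0.045 rad of the oracle direction

    def test_summary_separates_truth_on_compressed_fixture(self):
        cfg = c.concordance_fixture(seed=21, n_background_probes=40)
        cohort, raw, probes = c.simulate_cohort(cfg)
        locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
        theta, R = c.compute_polar(raw.X, raw.Y)
        model = c.fit_cluster_model(theta, R, "cohort")
        sig = c.compute_lrr_baf(theta, R, model)
        s = c.summarize_signal(sig.lrr[:, locus], 2)
        carrier = cohort.true_copy_number > 0
        # AUC via rank statistic
        order = np.argsort(np.argsort(s))
        auc = (order[carrier].sum() - carrier.sum() *
               (carrier.sum() - 1) / 2) / (carrier.sum() *
                                           (~carrier).sum())
        assert auc > 0.95


class TestGaussianMixture:
    def test_em_reaches_grid_search_loglik(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-1, 0.3, 10), rng.normal(1, 0.3, 10)])
        fit = fit_gmm1d(x, 2)
        best = -np.inf
        for m1 in np.linspace(-1.6, -0.4, 13):
            for m2 in np.linspace(0.4, 1.6, 13):
                for sd in np.linspace(0.15, 0.6, 10):
                    for pi in np.linspace(0.2, 0.8, 7):
                        dens = pi * norm.pdf(x, m1, sd) + (1 - pi) * \
                            norm.pdf(x, m2, sd)
                        best = max(best, float(np.log(dens).sum()))
        assert fit.loglik >= best - 1e-3

    def test_components_sorted_and_posteriors_normalized(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(2, 0.5, 60), rng.normal(-2, 0.5, 40)])
        fit = fit_gmm1d(x, 2)
        assert fit.means[0] < fit.means[1]
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert fit.weights[0] == pytest.approx(0.4, abs=0.1)

    def test_bic_prefers_true_component_count(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-3, 0.4, 150),
                            rng.normal(3, 0.4, 150)])
        assert mixture_bic(x, 2) < mixture_bic(x, 3) + 1e-6


class TestJointMixture:
    def _data(self, n=600, beta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cls = (rng.random(n) < 0.5).astype(int)
        x = rng.normal(0, 0.25, n) + cls * 1.5
        eta = 0.0 + beta * cls
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return x, y, cls

    def test_null_effect_gives_or_near_one_and_small_lrt(self):
        x, y, _ = self._data(seed=5)
        fit = c.fit_joint_mixture(x, y, K=2, restarts=6)
        assert fit.odds_ratio == pytest.approx(1.0, abs=0.35)
        assert fit.lrt < 6.0
        assert fit.p_value > 0.01

    def test_effect_recovered(self):
        x, y, _ = self._data(n=3000, beta=math.log(0.6), seed=6)
        fit = c.fit_joint_mixture(x, y, K=2, restarts=6)
        assert fit.odds_ratio == pytest.approx(0.6, abs=0.08)
        assert fit.p_value < 1e-4

    def test_lrt_nonnegative_and_posteriors_normalized(self):
        x, y, _ = self._data(seed=7)
        fit = c.fit_joint_mixture(x, y, K=2, restarts=4)
        assert fit.lrt >= 0.0
        assert fit.loglik_alt >= fit.loglik_null - 1e-6
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert fit.means[0] < fit.means[1]

    def test_em_loglik_monotone(self):
        x, y, _ = self._data(n=400, beta=math.log(0.7), seed=8)
        Xc = np.ones((len(y), 1))
        out = _joint_em(
            x, y.astype(float), Xc,
            np.array([-0.2, 1.2]), np.array([0.5, 0.5]),
            np.array([0.5, 0.5]), np.zeros(1), 0.0,
            tol=1e-10, max_iter=60, sd_floor=1e-3,
        )
        lls = np.array(out[-1])
        assert (np.diff(lls) >= -1e-8).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="K"):
            c.fit_joint_mixture(np.zeros(10), np.zeros(10), K=1)


class TestConcordance:
    def test_perfect_agreement(self):
        cls = np.array([0, 0, 1, 1])
        assert c.class_concordance(cls, np.array([1, 1, 0, 0],
                                                 dtype=bool)) == 1.0

    def test_random_labels_hit_majority_rate(self):
        rng = np.random.default_rng(9)
        truth = rng.random(20000) < 0.53
        cls = (rng.random(20000) < 0.5).astype(int)
        expected = 0.5  # independent coin against any truth split
        assert c.class_concordance(cls, truth) == pytest.approx(expected,
                                                                abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            c.class_concordance(np.zeros(3), np.zeros(4, dtype=bool))
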