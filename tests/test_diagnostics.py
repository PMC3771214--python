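"""Pooling metrics, DIC, choice-curve refits, and predictive simulation."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom as binom_dist

from socialvalue import (
    ChainConfig,
    ChoiceBlock,
    Dataset,
    ModelSpec,
    compare_models,
    dic,
    fit_choice_curve,
    pooling_fraction,
    pooling_metrics,
    posterior_predictive_sessions,
    refit_choice_curves,
    variance_explained,
)


class TestPoolingOracles:
    def test_zero_residuals_give_r2_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert variance_explained(x, np.zeros(4)) == 1.0

    def test_two_unit_toy_complete_pooling(self):
        # units {(1, -1), (1, -1)}: within-unit means are (0, 0) -> lambda = 1
        eps = np.array([1.0, -1.0, 1.0, -1.0])
        units = np.array([0, 0, 1, 1])
        assert pooling_fraction(eps, units) == pytest.approx(1.0, abs=1e-15)

    def test_two_unit_toy_no_pooling(self):
        # units {(1, 1), (-1, -1)}: all residual variance is between units
        eps = np.array([1.0, 1.0, -1.0, -1.0])
        units = np.array([0, 0, 1, 1])
        assert pooling_fraction(eps, units) == pytest.approx(0.0, abs=1e-15)

    def test_arithmetic_oracle_unbalanced(self):
        # hand-computed: eps = (3,1 | 2), units of size 2 and 1
        eps = np.array([3.0, 1.0, 2.0])
        units = np.array([0, 0, 1])
        means = np.array([2.0, 2.0, 2.0])
        expected = 1.0 - np.var(means) / np.var(eps)  # = 1 - 0 = 1
        assert pooling_fraction(eps, units) == pytest.approx(expected)

    def test_lambda_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 40)
            eps = rng.normal(size=n) * rng.uniform(0.1, 5)
            units = rng.integers(0, rng.integers(1, n) + 1, size=n)
            lam = pooling_fraction(eps, units)
            if np.isfinite(lam):
                assert -1e-12 <= lam <= 1.0 + 1e-12

    def test_degenerate_variances_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(variance_explained(np.ones(4), np.zeros(4)))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(pooling_fraction(np.zeros(4), np.array([0, 0, 1, 1])))


class TestPoolingMetrics:
    def test_levels_and_ranges_on_fixture(self, canonical, fitted):
        report = pooling_metrics(fitted, fitted.spec, canonical.dataset)
        assert set(report.levels) == {"session", "utility", "counts"}
        for name, d in report.levels.items():
            assert d["R2"] <= 1.0
            assert 0.0 <= d["lambda"] <= 1.0
        frame = report.to_frame()
        assert list(frame.columns) == ["level", "R2", "lambda"]

    def test_requires_partial_pooling(self, canonical, fitted):
        with pytest.raises(ValueError, match="partial"):
            pooling_metrics(fitted, ModelSpec.from_model_number(2),
                            canonical.dataset)


class TestDic:
    def test_identity_and_degenerate_pd(self, canonical, fitted):
        spec = fitted.spec
        report = dic(fitted, spec, canonical.dataset)
        assert report.DIC == report.Dbar + report.pD  # exact by construction
        assert report.pD > 0

        # collapse the posterior to a single repeated draw: pD = 0
        import copy
        frozen = copy.deepcopy(fitted)
        for k, v in frozen.draws.items():
            frozen.draws[k] = np.broadcast_to(v[:1, :1], v.shape).copy()
        degen = dic(frozen, spec, canonical.dataset)
        assert degen.pD == pytest.approx(0.0, abs=1e-8)
        assert degen.DIC == pytest.approx(degen.Dbar, abs=1e-8)

    def test_deviance_draw_matches_pmf_oracle(self, canonical, fitted):
        from socialvalue.diagnostics import _deviance_draws
        from socialvalue.hier_model import ModelIndex

        index = ModelIndex(canonical.dataset, fitted.spec)
        dev = _deviance_draws(fitted, index)
        x = fitted.draws["logit_p"][0, 0]
        oracle = -2.0 * binom_dist.logpmf(index.n, index.N, expit(x)).sum()
        assert dev[0, 0] == pytest.approx(oracle, rel=1e-10)

    def test_gaussian_pd_matches_shrinkage_formula(self):
        # Normal(theta, 1) likelihood on n points, Normal(0, 100) prior:
        # pD = E[D] - D(theta_bar) = n * Var(theta | y)
        rng = np.random.default_rng(1)
        y = rng.normal(1.0, 1.0, size=25)
        prec = len(y) + 0.01
        post_mean, post_var = y.sum() / prec, 1.0 / prec
        theta = rng.normal(post_mean, np.sqrt(post_var), size=40_000)

        def D(t):
            return np.sum((y[None, :] - np.atleast_1d(t)[:, None]) ** 2, axis=1)

        pd_est = D(theta).mean() - D(np.array([theta.mean()]))[0]
        assert pd_est == pytest.approx(len(y) * post_var, rel=0.05)


class TestCompareModels:
    def test_schema_sorted_and_duplicates_agree(self, tiny_dataset):
        cfg = ChainConfig(n_chains=2, n_adapt=150, n_burn=300, n_iter=600,
                          thin=3, seed=21)
        spec = ModelSpec.from_model_number(6)
        table = compare_models(tiny_dataset.dataset, [spec, spec], cfg)
        assert list(table["DIC"]) == sorted(table["DIC"])
        assert {"model", "description", "session", "category", "subject",
                "Dbar", "pD", "DIC", "Dbar_se", "max_rhat",
                "converged"} <= set(table.columns)
        # same model twice: DIC difference within Monte-Carlo error
        d = abs(table["DIC"].iloc[0] - table["DIC"].iloc[1])
        se = np.hypot(table["Dbar_se"].iloc[0], table["Dbar_se"].iloc[1])
        assert d < 6 * se + 2.0


class TestChoiceCurve:
    def test_symmetric_counts_give_zero_pse(self):
        blocks = [ChoiceBlock("E", "s", "female", dv, n, 20)
                  for dv, n in [(-0.04, 4), (0.0, 10), (0.04, 16)]]
        fit = fit_choice_curve(blocks)
        assert fit.converged
        assert fit.beta0 == pytest.approx(0.0, abs=1e-8)
        assert fit.pse == pytest.approx(0.0, abs=1e-8)

    def test_three_point_toy_matches_grid_search(self):
        blocks = [ChoiceBlock("E", "s", "female", dv, n, 20)
                  for dv, n in [(-0.04, 2), (0.0, 10), (0.04, 18)]]
        fit = fit_choice_curve(blocks)

        # brute-force ML oracle on a two-stage grid
        dv = np.array([-0.04, 0.0, 0.04])
        n = np.array([2.0, 10.0, 18.0])
        N = np.full(3, 20.0)

        def loglik(b0, b1):
            eta = b0 + b1 * dv
            return float(n @ eta - N @ np.logaddexp(0.0, eta))

        b0g, b1g = 0.0, 50.0
        span0, span1 = 5.0, 80.0
        for _ in range(12):
            c0 = np.linspace(b0g - span0, b0g + span0, 41)
            c1 = np.linspace(b1g - span1, b1g + span1, 41)
            vals = np.array([[loglik(a, b) for b in c1] for a in c0])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            b0g, b1g = c0[i], c1[j]
            span0 *= 0.15
            span1 *= 0.15
        assert fit.beta0 == pytest.approx(b0g, abs=1e-4)
        assert fit.beta1 == pytest.approx(b1g, abs=1e-3)

    def test_generative_recovery_large_n(self):
        # omega = 0, v = 0.02 s, tau = 0.04 s: pse -> -0.02, width -> 0.04
        v, tau, N = 0.02, 0.04, 400_000
        dvs = np.array([-0.08, -0.04, 0.0, 0.04, 0.08])
        blocks = [ChoiceBlock("E", "s", "female", float(dv),
                              int(round(N * expit((dv + v) / tau))), N)
                  for dv in dvs]
        fit = fit_choice_curve(blocks)
        assert fit.pse == pytest.approx(-0.02, abs=2e-4)
        assert fit.width == pytest.approx(0.04, rel=0.01)
        assert fit.value == pytest.approx(0.02, abs=2e-4)

    def test_complete_separation_flagged(self):
        blocks = [ChoiceBlock("E", "s", "female", dv, n, 20)
                  for dv, n in [(-0.04, 0), (0.0, 0), (0.04, 20)]]
        fit = fit_choice_curve(blocks)
        assert not fit.converged

    def test_needs_two_distinct_dv(self):
        blocks = [ChoiceBlock("E", "s", "female", 0.0, 10, 20)]
        with pytest.raises(ValueError, match="distinct dv"):
            fit_choice_curve(blocks)

    def test_refit_frame_covers_all_trial_sets(self, canonical):
        frame = refit_choice_curves(canonical.dataset)
        assert len(frame) == 160  # 40 sessions x 4 categories
        assert {"subject", "session", "category", "width", "value",
                "converged"} <= set(frame.columns)


class TestPosteriorPredictive:
    def test_output_is_valid_dataset_with_requested_sessions(self, canonical,
                                                             fitted):
        rng = np.random.default_rng(2)
        ppc = posterior_predictive_sessions(fitted, canonical.dataset, 12, rng)
        assert len(ppc.sessions) == 12
        # Dataset construction already validates invariants; spot-check counts
        assert all(0 <= b.n <= b.N for b in ppc.blocks)
        assert set(b.N for b in ppc.blocks) == {30}

    def test_collapsed_posterior_reduces_to_point_simulation(self, canonical,
                                                             fitted):
        # with the posterior collapsed to one draw, every fictitious
        # session uses exactly that draw's hyperparameters
        import copy
        frozen = copy.deepcopy(fitted)
        for k, v in frozen.draws.items():
            frozen.draws[k] = np.repeat(v[:1, :1], 1, axis=1)[:1]
        rng = np.random.default_rng(3)
        ppc = posterior_predictive_sessions(frozen, canonical.dataset, 40, rng)
        refits = refit_choice_curves(ppc)
        ok = refits[refits["converged"]]
        # widths concentrate near the single draw's tau prior scale
        V = frozen.draws["V"][0, 0]
        vals = ok["value"].to_numpy()
        assert abs(np.median(vals) - np.median(V)) < 0.05
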