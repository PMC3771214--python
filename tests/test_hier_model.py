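"""Density correctness: priors, likelihood, deviance, and pooling variants."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from socialvalue import (
    Dataset,
    ModelIndex,
    ModelSpec,
    ParameterSet,
    PriorConfig,
    deviance,
    indifference_point,
    log_likelihood,
    log_prior,
)
from socialvalue.hier_model import binom_logpmf, trunc_t_logpdf


def _make_params(index, rng=None, **overrides):
    """A valid interior parameter point for any variant."""
    rng = rng or np.random.default_rng(0)
    M, C, S = index.n_subj_groups, index.n_cat_groups, index.n_sessions
    params = ParameterSet(
        V=np.zeros((M, C)) if index.has_V else None,
        sigma=np.full(M, 0.02) if index.has_sigma else None,
        omega=np.full(M, 0.5),
        tau=np.full(S, 0.05),
        tau_loc=0.05, tau_scale=0.02, tau_df=5.0,
        alpha=np.zeros((M, C)) if index.has_alpha else None,
        v=np.zeros((S, C)) if index.has_v else None,
        logit_p=np.zeros(index.n_blocks),
    )
    for k, v in overrides.items():
        setattr(params, k, v)
    return params


@pytest.fixture(scope="module")
def tiny(tiny_dataset):
    return tiny_dataset.dataset


class TestModelSpec:
    def test_all_eight_variants_constructible(self):
        numbers = [ModelSpec.from_model_number(k).model_number for k in range(8)]
        assert numbers == list(range(8))

    def test_trend_requires_partial_session_pooling(self):
        with pytest.raises(ValueError, match="partial"):
            ModelSpec(session_pooling="complete", time_trend=True)

    def test_mapping_round_trip(self):
        for k in range(8):
            spec = ModelSpec.from_model_number(k)
            assert ModelSpec.from_mapping(spec.to_mapping()) == spec


class TestLogPrior:
    def test_sigma_outside_support(self, tiny):
        spec = ModelSpec.from_model_number(6)
        index = ModelIndex(tiny, spec)
        params = _make_params(index, sigma=np.full(index.n_subj_groups, 2.0))
        assert log_prior(params, spec, tiny, index) == -np.inf

    def test_V_term_is_normal_density(self, tiny):
        # moving one V entry from 0 to x changes the prior by the
        # N(0, 0.01) log-density difference (model 1: no session level,
        # so the V term is isolated)
        spec = ModelSpec.from_model_number(1)
        index = ModelIndex(tiny, spec)
        p0 = _make_params(index)
        lp0 = log_prior(p0, spec, tiny, index)
        V = np.zeros((index.n_subj_groups, index.n_cat_groups))
        V[0, 0] = 0.15
        lp1 = log_prior(_make_params(index, V=V), spec, tiny, index)
        expected = stats.norm.logpdf(0.15, 0, 0.1) - stats.norm.logpdf(0.0, 0, 0.1)
        assert lp1 - lp0 == pytest.approx(expected, abs=1e-10)

    def test_truncated_t_normalizes_and_matches_scipy(self):
        df, loc, scale = 4.0, 0.25, 0.05
        # density value at tau = 0.2 against the scipy oracle
        expected = stats.t.logpdf(0.2, df, loc, scale) \
            - np.log(stats.t.sf(0.0, df, loc, scale))
        assert trunc_t_logpdf(0.2, df, loc, scale) == pytest.approx(expected, abs=1e-12)
        # quadrature: the truncated density integrates to 1 on (0, inf)
        mass, _ = integrate.quad(
            lambda x: np.exp(trunc_t_logpdf(x, df, loc, scale)), 0, np.inf)
        assert mass == pytest.approx(1.0, abs=1e-8)
        assert trunc_t_logpdf(-0.1, df, loc, scale) == -np.inf

    def test_out_of_support_omega(self, tiny):
        spec = ModelSpec.from_model_number(6)
        index = ModelIndex(tiny, spec)
        params = _make_params(index, omega=np.full(index.n_subj_groups, 10.0))
        assert log_prior(params, spec, tiny, index) == -np.inf  # log 10 > 2

    def test_finite_on_interior(self, tiny):
        for k in range(8):
            spec = ModelSpec.from_model_number(k)
            index = ModelIndex(tiny, spec)
            params = _make_params(index)
            total = log_prior(params, spec, tiny, index) \
                + log_likelihood(params, spec, tiny, index)
            assert np.isfinite(total)


class TestLogLikelihood:
    def test_binomial_closed_form(self):
        # single block, logit_p = 0, n = N/2: the count term is
        # log C(N, N/2) + N log(1/2)
        from math import comb, log
        N = 20
        expected = log(comb(N, 10)) + N * log(0.5)
        assert binom_logpmf(10, 20, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_marginal_by_two_independent_quadratures(self):
        # latent-augmented density integrated over logit_p: Gauss-Hermite
        # vs adaptive quadrature of the logit-normal-binomial marginal
        eta, omega, n, N = 0.7, 0.6, 13, 20

        def integrand(x):
            return np.exp(stats.norm.logpdf(x, eta, omega)
                          + binom_logpmf(n, N, x))

        nodes, weights = np.polynomial.hermite.hermgauss(80)
        gh = np.sum(weights / np.sqrt(np.pi)
                    * np.exp(binom_logpmf(n, N, eta + np.sqrt(2) * omega * nodes)))
        aq, _ = integrate.quad(integrand, -30, 30, limit=200)
        assert gh == pytest.approx(aq, abs=1e-8)

    def test_session_permutation_invariance_model2(self, tiny_dataset):
        # under complete session pooling (and equal tau) the likelihood
        # cannot depend on which session a block is assigned to
        spec = ModelSpec.from_model_number(2)
        data = tiny_dataset.dataset
        index = ModelIndex(data, spec)
        params = _make_params(index, logit_p=np.linspace(-1, 1, index.n_blocks))
        base = log_likelihood(params, spec, data, index)

        blocks = list(data.blocks)
        # swap all blocks between subject A's sessions 0 and 1
        remap = {"A_s000": "A_s001", "A_s001": "A_s000"}
        swapped = [type(b)(b.subject_id, remap.get(b.session_id, b.session_id),
                           b.category, b.dv, b.n, b.N) for b in blocks]
        data2 = Dataset(blocks=swapped, session_dates=data.session_dates,
                        subject_of=data.subject_of)
        index2 = ModelIndex(data2, spec)
        params2 = _make_params(index2, logit_p=np.linspace(-1, 1, index2.n_blocks))
        assert log_likelihood(params2, spec, data2, index2) == pytest.approx(
            base, abs=1e-10)

    def test_subject_relabel_invariance_complete_pooling(self, tiny_dataset):
        spec = ModelSpec.from_model_number(3)  # complete subject pooling
        data = tiny_dataset.dataset
        index = ModelIndex(data, spec)
        params = _make_params(index, logit_p=np.linspace(-1, 1, index.n_blocks))
        base = (log_prior(params, spec, data, index)
                + log_likelihood(params, spec, data, index))
        swap = {"A": "B", "B": "A"}
        blocks = [type(b)(swap[b.subject_id], b.session_id, b.category,
                          b.dv, b.n, b.N) for b in data.blocks]
        data2 = Dataset(blocks=blocks, session_dates=data.session_dates,
                        subject_of={s: swap[m] for s, m in data.subject_of.items()})
        index2 = ModelIndex(data2, spec)
        params2 = _make_params(index2, logit_p=np.linspace(-1, 1, index2.n_blocks))
        total2 = (log_prior(params2, spec, data2, index2)
                  + log_likelihood(params2, spec, data2, index2))
        assert total2 == pytest.approx(base, abs=1e-10)

    def test_nesting_collapses_to_complete_pooling(self, tiny_dataset):
        # model 6 with v pinned at V (the sigma -> 0 limit) gives the same
        # block-level likelihood as model 1 at the same mean values
        data = tiny_dataset.dataset
        spec6 = ModelSpec.from_model_number(6)
        spec1 = ModelSpec.from_model_number(1)
        ix6, ix1 = ModelIndex(data, spec6), ModelIndex(data, spec1)
        rng = np.random.default_rng(3)
        V = rng.normal(0, 0.02, (ix6.n_subj_groups, ix6.n_cat_groups))
        v = V[ix6.session_subj, :]
        x = rng.normal(0, 1, ix6.n_blocks)
        p6 = _make_params(ix6, V=V, v=v, logit_p=x)
        p1 = _make_params(ix1, V=V, logit_p=x)
        assert log_likelihood(p6, spec6, data, ix6) == pytest.approx(
            log_likelihood(p1, spec1, data, ix1), abs=1e-10)


class TestDeviance:
    def test_matches_pmf_oracle(self, tiny):
        spec = ModelSpec.from_model_number(6)
        index = ModelIndex(tiny, spec)
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, index.n_blocks)
        params = _make_params(index, logit_p=x)
        oracle = -2.0 * sum(
            stats.binom.logpmf(index.n[i], index.N[i], expit(x[i]))
            for i in range(index.n_blocks))
        assert deviance(params, spec, tiny, index) == pytest.approx(oracle, rel=1e-10)

    def test_single_block_point(self):
        # n=12, N=20, p=0.6
        assert -2.0 * binom_logpmf(12, 20, np.log(0.6 / 0.4)) == pytest.approx(
            -2.0 * stats.binom.logpmf(12, 20, 0.6), abs=1e-10)

    def test_saturated_extreme_counts_approach_zero(self):
        # blocks with n in {0, N} and p -> n/N: deviance -> 0
        dev = -2.0 * (binom_logpmf(0, 20, -60.0) + binom_logpmf(20, 20, 60.0))
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_prior_hyperparameters(self, tiny):
        loose = ModelSpec.from_model_number(6)
        tight = ModelSpec(priors=PriorConfig(V_variance=1e-4))
        index = ModelIndex(tiny, loose)
        params = _make_params(index, logit_p=np.linspace(-2, 2, index.n_blocks))
        assert deviance(params, loose, tiny) == deviance(params, tight, tiny)


class TestIndifference:
    def test_sign_and_units(self):
        assert indifference_point(0.0) == 0.0
        assert indifference_point(0.025) == pytest.approx(-0.025)
        assert indifference_point(0.025) * 1000 == pytest.approx(-25.0)

    def test_choice_probability_half_at_pse(self):
        # composition of utility and inverse logit at dv = -v, any tau
        for tau in (0.01, 0.05, 0.3):
            v = 0.05
            dv = indifference_point(v)
            assert expit((dv + v) / tau) == pytest.approx(0.5, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            indifference_point(np.nan)


def test_shape_validation_catches_mismatch(tiny_dataset):
    data = tiny_dataset.dataset
    spec = ModelSpec.from_model_number(6)
    index = ModelIndex(data, spec)
    params = _make_params(index, tau=np.full(index.n_sessions + 1, 0.05))
    with pytest.raises(ValueError, match="tau"):
        log_likelihood(params, spec, data, index)
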