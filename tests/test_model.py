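"""Design construction, beta density, priors, joint posterior."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from phylobeta.model import (DesignMatrix, ModelSpec, ParameterVector,
                             beta_logpdf, build_design, log_likelihood,
                             log_posterior, log_prior)
from phylobeta.phylo import PhyloCovariance, phylo_vcv
from phylobeta.synthetic_data import simulate_yule_tree
from phylobeta.traits import TraitTable, prepare_predictors
from tests.conftest import make_trait_frame


@pytest.fixture
def prepared(toy_table):
    return prepare_predictors(toy_table)


class TestBuildDesign:
    def test_main_effects_has_seven_named_columns(self, prepared):
        design = build_design(prepared, ModelSpec(form="main_effects"))
        assert design.p == 7
        assert design.names[:2] == ["Intercept", "NS"]
        assert np.all(design.X[:, 0] == 1)

    def test_interactions_has_twelve_columns(self, prepared):
        design = build_design(prepared, ModelSpec(form="interactions"))
        assert design.p == 12
        assert design.names[7] == "NS:log Range"

    def test_interaction_columns_are_products(self, prepared):
        spec = ModelSpec(form="interactions")
        design = build_design(prepared, spec)
        ns = design.X[:, 1]
        for j, name in enumerate(design.names):
            if name.startswith("NS:"):
                main = design.names.index(name[3:])
                np.testing.assert_allclose(design.X[:, j],
                                           ns * design.X[:, main])

    def test_interactions_nest_main_effects(self, prepared):
        main = build_design(prepared, ModelSpec(form="main_effects"))
        inter = build_design(prepared, ModelSpec(form="interactions"))
        np.testing.assert_allclose(inter.X[:, :7], main.X)
        assert inter.names[:7] == main.names

    def test_all_south_interactions_rejected(self):
        df = make_trait_frame([
            (f"t{i}", f"t{i}", "G", "south", 0.1 * (i + 1)) for i in range(4)
        ])
        prepared = prepare_predictors(TraitTable(data=df))
        with pytest.raises(ValueError, match="zero"):
            build_design(prepared, ModelSpec(form="interactions"))

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(form="quadratic")


class TestBetaLogpdf:
    def test_uniform_case_is_zero(self):
        # mu=0.5, gamma=2 -> Beta(1, 1), the uniform density
        assert beta_logpdf(0.3, 0.5, 2.0) == pytest.approx(0.0, abs=1e-14)

    def test_beta22_closed_form(self):
        # Beta(2, 2) density 6 y (1 - y); at y = 0.5 that is 1.5
        assert beta_logpdf(0.5, 0.5, 4.0) == pytest.approx(math.log(1.5),
                                                           abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        y = rng.uniform(0.01, 0.99, 100)
        mu = rng.uniform(0.05, 0.95, 100)
        gamma = rng.uniform(0.1, 50, 100)
        ours = beta_logpdf(y, mu, gamma)
        ref = stats.beta.logpdf(y, mu * gamma, (1 - mu) * gamma)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_normalises_by_quadrature(self):
        mu, gamma = 0.3, 7.2
        total, _ = quad(lambda y: math.exp(beta_logpdf(y, mu, gamma)), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.2, 1.3])
    def test_out_of_support_response_is_minus_inf(self, y):
        assert beta_logpdf(y, 0.4, 2.0) == -math.inf

    @pytest.mark.parametrize("mu,gamma", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0)])
    def test_invalid_parameters_raise(self, mu, gamma):
        with pytest.raises(ValueError):
            beta_logpdf(0.5, mu, gamma)


def _scipy_log_prior(params, spec, cov):
    """Independent recomputation of the joint prior via scipy.stats."""
    lp = stats.norm.logpdf(params.theta, 0, spec.prior_coef_sd).sum()
    lp += stats.uniform.logpdf(params.lam, spec.lambda_lower,
                               spec.lambda_upper - spec.lambda_lower)
    lp += stats.gamma.logpdf(params.gamma, spec.gamma_shape,
                             scale=1.0 / spec.gamma_rate_effective)
    C = spec_lambda_cov(cov, params.lam)
    lp += stats.multivariate_normal.logpdf(params.u, mean=np.zeros(len(cov.taxa)),
                                           cov=C)
    return lp


def spec_lambda_cov(cov, lam):
    C = lam * cov.C
    np.fill_diagonal(C, np.diag(cov.C))
    return C


class TestLogPrior:
    @pytest.fixture
    def cov(self):
        return phylo_vcv(simulate_yule_tree(5, seed=8))

    def test_lambda_outside_support_is_minus_inf(self, cov):
        params = ParameterVector(np.zeros(2), np.zeros(5), 1.0, 1.3)
        assert log_prior(params, ModelSpec(), cov) == -math.inf

    def test_nonpositive_gamma_is_minus_inf(self, cov):
        params = ParameterVector(np.zeros(2), np.zeros(5), -1.0, 0.5)
        assert log_prior(params, ModelSpec(), cov) == -math.inf

    def test_single_zero_coefficient_contribution(self, cov):
        # Normal(0, 1000) at 0 contributes -ln(1000) - 0.5 ln(2 pi)
        spec = ModelSpec()
        base = ParameterVector(np.zeros(0), np.zeros(5), 1.0, 0.5)
        one = ParameterVector(np.zeros(1), np.zeros(5), 1.0, 0.5)
        delta = log_prior(one, spec, cov) - log_prior(base, spec, cov)
        assert delta == pytest.approx(-math.log(1000) - 0.5 * math.log(2 * math.pi),
                                      abs=1e-9)

    def test_mvn_term_at_zero_is_half_logdet(self, cov):
        spec = ModelSpec()
        lam = 0.7
        params = ParameterVector(np.zeros(0), np.zeros(5), 1.0, lam)
        C = spec_lambda_cov(cov, lam)
        expected_mvn = -0.5 * np.linalg.slogdet(2 * np.pi * C)[1]
        other = (stats.uniform.logpdf(lam, 0, 1.2)
                 + stats.gamma.logpdf(1.0, 0.001, scale=1000.0))
        assert log_prior(params, spec, cov) == pytest.approx(
            expected_mvn + other, abs=1e-9)

    def test_matches_scipy_recomputation(self, cov, rng):
        spec = ModelSpec()
        for _ in range(5):
            params = ParameterVector(
                theta=rng.normal(0, 2, 3), u=rng.normal(0, 1, 5),
                gamma=float(rng.uniform(0.2, 5)), lam=float(rng.uniform(0, 1)))
            assert log_prior(params, spec, cov) == pytest.approx(
                _scipy_log_prior(params, spec, cov), abs=1e-8)

    def test_scale_parameterization_switch(self, cov):
        params = ParameterVector(np.zeros(1), np.zeros(5), 2.0, 0.5)
        rate_spec = ModelSpec(gamma_prior_parameterization="rate")
        scale_spec = ModelSpec(gamma_prior_parameterization="scale")
        d = log_prior(params, rate_spec, cov) - log_prior(params, scale_spec, cov)
        expected = (stats.gamma.logpdf(2.0, 0.001, scale=1000.0)
                    - stats.gamma.logpdf(2.0, 0.001, scale=0.001))
        assert d == pytest.approx(expected, abs=1e-9)

    def test_diagonal_cov_factorises_to_univariate_normals(self, rng):
        # star phylogeny at lambda = 0: the species-effect prior is a product
        # of independent normals
        diag = rng.uniform(0.5, 3.0, 6)
        cov = PhyloCovariance(taxa=[f"t{i}" for i in range(6)], C=np.diag(diag))
        u = rng.normal(0, 1, 6)
        spec = ModelSpec()
        with_u = ParameterVector(np.zeros(0), u, 1.0, 0.0)
        no_u = ParameterVector(np.zeros(0), np.zeros(6), 1.0, 0.0)
        delta = (log_prior(with_u, spec, cov) - log_prior(no_u, spec, cov))
        expected = (stats.norm.logpdf(u, 0, np.sqrt(diag)).sum()
                    - stats.norm.logpdf(np.zeros(6), 0, np.sqrt(diag)).sum())
        assert delta == pytest.approx(expected, abs=1e-10)


class TestLogPosterior:
    @pytest.fixture
    def toy(self, prepared):
        spec = ModelSpec()
        design = build_design(prepared, spec)
        cov = PhyloCovariance(taxa=prepared.taxa,
                              C=np.eye(4) + 0.3 * (np.ones((4, 4)) - np.eye(4)))
        params = ParameterVector(theta=np.full(design.p, 0.1),
                                 u=np.array([0.2, -0.1, 0.0, 0.3]),
                                 gamma=2.5, lam=0.6)
        return spec, design, cov, params, prepared.response

    def test_component_sum_oracle(self, toy):
        spec, design, cov, params, y = toy
        eta = design.X @ params.theta + params.u
        mu = 1 / (1 + np.exp(-eta))
        expected = (_scipy_log_prior(params, spec, cov)
                    + stats.beta.logpdf(y, mu * params.gamma,
                                        (1 - mu) * params.gamma).sum())
        assert log_posterior(params, design, y, cov, spec) == pytest.approx(
            expected, abs=1e-8)

    def test_negative_gamma_is_minus_inf(self, toy):
        spec, design, cov, params, y = toy
        bad = ParameterVector(params.theta, params.u, -1.0, params.lam)
        assert log_posterior(bad, design, y, cov, spec) == -math.inf

    def test_prior_likelihood_decomposition(self, toy):
        spec, design, cov, params, y = toy
        doubled = ParameterVector(2 * params.theta, 2 * params.u,
                                  params.gamma, params.lam)
        lhs = (log_posterior(doubled, design, y, cov, spec)
               - log_posterior(params, design, y, cov, spec))
        rhs = (log_prior(doubled, spec, cov) - log_prior(params, spec, cov)
               + log_likelihood(doubled, design, y)
               - log_likelihood(params, design, y))
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_taxon_permutation_invariance(self, toy):
        spec, design, cov, params, y = toy
        perm = np.array([2, 0, 3, 1])
        design_p = DesignMatrix(X=design.X[perm], names=design.names,
                                form=design.form)
        cov_p = PhyloCovariance(taxa=[cov.taxa[i] for i in perm],
                                C=cov.C[np.ix_(perm, perm)])
        params_p = ParameterVector(params.theta, params.u[perm],
                                   params.gamma, params.lam)
        assert log_posterior(params_p, design_p, y[perm], cov_p, spec) == \
            pytest.approx(log_posterior(params, design, y, cov, spec),
                          abs=1e-10)

    def test_dimension_mismatch_rejected(self, toy):
        spec, design, cov, params, y = toy
        bad = ParameterVector(params.theta[:-1], params.u, 1.0, 0.5)
        with pytest.raises(ValueError):
            log_posterior(bad, design, y, cov, spec)


def test_parameter_vector_pack_roundtrip(rng):
    params = ParameterVector(theta=rng.normal(size=3), u=rng.normal(size=5),
                             gamma=1.5, lam=0.4)
    again = ParameterVector.unpack(params.pack(), 3, 5)
    np.testing.assert_allclose(again.theta, params.theta)
    np.testing.assert_allclose(again.u, params.u)
    assert again.gamma == params.gamma and again.lam == params.lam


def test_model_spec_dict_roundtrip():
    spec = ModelSpec(form="interactions", prior_coef_sd=10.0)
    assert ModelSpec.from_dict(spec.to_dict()) == spec
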