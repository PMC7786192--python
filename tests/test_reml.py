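"""REML engine: likelihood correctness, fitting, BLUPs, multi-trait GREML."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from reactnorm import (
    ModelSpec,
    RNMParams,
    assemble_covariance,
    fit,
    loglik,
    multi_trait_greml,
    scenario,
)
from reactnorm.models import MODEL_NAMES
from reactnorm.simulate import SimulationConfig, simulate_genotypes
from reactnorm.genotypes import compute_grm, standardize

ALL_MODELS = list(MODEL_NAMES)


def _masked_params(params: RNMParams, spec: ModelSpec) -> RNMParams:
    G, E = params.joint_genetic(), params.joint_residual()
    mg = np.zeros((3, 3))
    mg[np.ix_(spec.active_genetic, spec.active_genetic)] = 1.0
    me = np.zeros((3, 3))
    me[np.ix_(spec.active_residual, spec.active_residual)] = 1.0
    return RNMParams.from_joint(G * mg, E * me)


def _error_contrast_loglik(params, y, A, c, spec, c_star=None):
    """Independent oracle: the restricted likelihood is the density of an
    orthonormal error-contrast basis K'y ~ N(0, K'VK)."""
    V = assemble_covariance(params, A, c, spec)
    n = len(y)
    if spec.second_trait:
        yj = np.concatenate([y, c_star])
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
    else:
        yj = np.asarray(y)
        X = np.ones((n, 1))
    Q, _ = np.linalg.qr(X, mode="complete")
    K = Q[:, X.shape[1]:]
    return multivariate_normal(
        mean=np.zeros(K.shape[1]), cov=K.T @ V @ K).logpdf(K.T @ yj)


class TestLoglik:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_matches_dense_error_contrast_oracle(self, tiny_dataset, name):
        ds = tiny_dataset
        spec = ModelSpec.from_name(name)
        params = _masked_params(ds.config.params(), spec)
        ll = loglik(params, ds.y, ds.grm.A, ds.c, spec, c_star=ds.c_star)
        oracle = _error_contrast_loglik(params, ds.y, ds.grm.A, ds.c, spec,
                                        c_star=ds.c_star)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_masked_slopes_equal_plain_greml(self, tiny_dataset):
        ds = tiny_dataset
        p = RNMParams(K_g=np.diag([0.4, 0.0]), K_e=np.diag([0.6, 0.0]))
        ll_rnm = loglik(p, ds.y, ds.grm.A, ds.c, ModelSpec.from_name("urnm-full"))
        ll_greml = loglik(p, ds.y, ds.grm.A, ds.c, ModelSpec.from_name("greml"))
        assert ll_rnm == pytest.approx(ll_greml, abs=1e-8)

    def test_masked_mrnm_equals_bivariate_greml(self, tiny_dataset):
        ds = tiny_dataset
        p = RNMParams(K_g=np.diag([0.4, 0.0]), K_e=np.diag([0.6, 0.0]),
                      K_g_beta=np.array([0.1, 0.0]),
                      K_e_eps=np.array([-0.05, 0.0]),
                      sigma_beta2=0.5, sigma_eps2=0.5)
        ll_full = loglik(p, ds.y, ds.grm.A, ds.c,
                         ModelSpec.from_name("mrnm-full"), c_star=ds.c_star)
        ll_bi = loglik(p, ds.y, ds.grm.A, ds.c,
                       ModelSpec.from_name("bigreml"), c_star=ds.c_star)
        assert ll_full == pytest.approx(ll_bi, abs=1e-8)

    def test_reml_translation_invariance(self, tiny_dataset):
        ds = tiny_dataset
        spec = ModelSpec.from_name("urnm-full")
        p = _masked_params(ds.config.params(), spec)
        ll0 = loglik(p, ds.y, ds.grm.A, ds.c, spec)
        ll1 = loglik(p, ds.y + 17.3, ds.grm.A, ds.c, spec)
        assert ll1 == pytest.approx(ll0, abs=1e-8)

    def test_ml_differs_from_reml(self, tiny_dataset):
        ds = tiny_dataset
        p = _masked_params(ds.config.params(), ModelSpec.from_name("greml"))
        ll_reml = loglik(p, ds.y, ds.grm.A, ds.c, ModelSpec.from_name("greml"))
        ll_ml = loglik(p, ds.y, ds.grm.A, ds.c,
                       ModelSpec.from_name("greml", criterion="ML"))
        assert ll_reml != pytest.approx(ll_ml, abs=1e-3)


class TestFit:
    def test_zero_genetic_variance_shrinks_to_boundary(self):
        cfg = SimulationConfig(
            n_individuals=1000, n_snps=800, seed=42,
            K_g=np.zeros((2, 2)), K_e=np.diag([1.0, 0.0]),
        )
        gsim = simulate_genotypes(1000, 800, seed=42)
        A = compute_grm(standardize(gsim.genotypes)).A
        rng = np.random.default_rng(42)
        y = rng.normal(0.0, 1.0, 1000)
        c = rng.normal(0.0, 1.0, 1000)
        res = fit(ModelSpec.from_name("greml"), y, A, c)
        assert res.converged
        assert res.params.K_g[0, 0] <= 0.02

    def test_optimum_dominates_generating_parameters(self, mid_dataset):
        ds = mid_dataset
        spec = ModelSpec.from_name("mrnm-full")
        res = fit(spec, ds.y, ds.grm.A, ds.c, c_star=ds.c_star,
                  init=ds.config.params())
        ll_truth = loglik(ds.config.params(), ds.y, ds.grm.A, ds.c, spec,
                          c_star=ds.c_star)
        assert res.loglik >= ll_truth - 1e-6

    def test_estimates_are_psd_and_masked(self, mid_dataset):
        ds = mid_dataset
        res = fit(ModelSpec.from_name("urnm-gxe"), ds.y, ds.grm.A, ds.c)
        res.params.validate_psd()
        assert res.params.K_e[1, 1] == 0.0  # masked residual slope
        assert res.params.sigma_beta2 == 0.0
        assert res.n_free_params == 4

    def test_standard_errors_finite_and_positive(self, mid_dataset):
        ds = mid_dataset
        res = fit(ModelSpec.from_name("urnm-full"), ds.y, ds.grm.A, ds.c,
                  compute_se=True)
        assert res.vcov.shape == (6, 6)
        assert res.se["var(alpha0)"] > 0
        assert np.isfinite(res.param_vector()).all()

    def test_blup_shrinkage(self):
        """BLUPs are shrunken: var(g_hat) <= var(g_true) across replicates."""
        shrunk = 0
        reps = 6
        for s in range(reps):
            ds = scenario("gxe", n=150, m=300, seed=100 + s)
            res = fit(ModelSpec.from_name("urnm-full"), ds.y, ds.grm.A, ds.c,
                      init=ds.config.params())
            g_true = ds.truth.genetic_value(ds.c)
            shrunk += res.blups["g"].var() <= g_true.var()
        assert shrunk >= reps - 1

    def test_blups_track_true_breeding_values(self):
        ds = scenario("combined", n=300, m=600, seed=17)
        res = fit(ModelSpec.from_name("mrnm-full"), ds.y, ds.grm.A, ds.c,
                  c_star=ds.c_star, init=ds.config.params())
        g_true = ds.truth.genetic_value(ds.c)
        r = np.corrcoef(res.blups["g"], g_true)[0, 1]
        assert r > 0.4

    def test_too_many_parameters_rejected(self):
        ds = scenario("null", n=10, m=20, seed=0)
        with pytest.raises(ValueError, match="free parameters"):
            fit(ModelSpec.from_name("mrnm-full"), ds.y, ds.grm.A, ds.c,
                c_star=ds.c_star)

    def test_second_trait_requires_c_star(self, mid_dataset):
        ds = mid_dataset
        with pytest.raises(ValueError, match="c_star"):
            fit(ModelSpec.from_name("bigreml"), ds.y, ds.grm.A, ds.c)


class TestMultiTrait:
    def test_single_trait_equals_univariate_greml(self, mid_dataset):
        ds = mid_dataset
        uni = fit(ModelSpec.from_name("greml"), ds.y, ds.grm.A, ds.c)
        multi = multi_trait_greml(ds.y[:, None], ds.grm.A)
        assert multi.loglik == pytest.approx(uni.loglik, abs=1e-4)
        assert multi.Sigma_g[0, 0] == pytest.approx(
            uni.params.K_g[0, 0], abs=5e-3)

    def test_independent_traits_have_small_genetic_correlation(self):
        gsim = simulate_genotypes(800, 600, seed=31)
        A = compute_grm(standardize(gsim.genotypes)).A
        La = np.linalg.cholesky(A + 1e-8 * np.eye(800))
        rng = np.random.default_rng(31)
        Y = np.column_stack([
            La @ rng.normal(0, np.sqrt(0.4), 800) + rng.normal(0, np.sqrt(0.6), 800)
            for _ in range(2)
        ])
        res = multi_trait_greml(Y, A)
        assert abs(res.genetic_correlations[0, 1]) <= 0.15

    def test_recovers_genetic_correlation(self):
        """20 replicates at n = 500, r_g = 0.5, h2 = 0.4 per trait."""
        Sg = 0.4 * np.array([[1.0, 0.5], [0.5, 1.0]])
        Lg = np.linalg.cholesky(Sg)
        ests = []
        for s in range(20):
            gsim = simulate_genotypes(500, 400, seed=700 + s)
            A = compute_grm(standardize(gsim.genotypes)).A
            La = np.linalg.cholesky(A + 1e-8 * np.eye(500))
            rng = np.random.default_rng(700 + s)
            G = La @ rng.normal(size=(500, 2)) @ Lg.T
            Y = G + rng.normal(0, np.sqrt(0.6), size=(500, 2))
            res = multi_trait_greml(Y, A)
            ests.append(res.genetic_correlations[0, 1])
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 3 * se + 0.02

    def test_heritabilities_in_unit_interval(self, mid_dataset):
        ds = mid_dataset
        res = multi_trait_greml(np.column_stack([ds.y, ds.c_star]), ds.grm.A)
        assert ((res.heritabilities >= 0) & (res.heritabilities <= 1)).all()

    def test_listwise_missing_handling(self, mid_dataset):
        ds = mid_dataset
        Y = np.column_stack([ds.y, ds.c_star])
        Y[:10, 0] = np.nan
        res = multi_trait_greml(Y, ds.grm.A)
        assert np.isfinite(res.loglik)

    def test_too_many_traits(self, mid_dataset):
        ds = mid_dataset
        with pytest.raises(ValueError):
            multi_trait_greml(np.tile(ds.y[:, None], (1, 5)), ds.grm.A)
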