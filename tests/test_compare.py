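"""Likelihood-ratio ladder, collinearity, heritability and EBV summaries."""

import copy

import numpy as np
import pytest
from scipy import stats

from reactnorm import (
    ModelSpec,
    collinearity_magnitude,
    ebv_rank_correlation,
    heritability_summary,
    lrt,
    residual_variance_contrast,
    run_ladder,
)
from reactnorm.compare import LADDER_ROWS
from reactnorm.reml import FitResult
from reactnorm.models import RNMParams


def _stub_fit(name, ll, n=100, blups_g=None, **kw):
    spec = ModelSpec.from_name(name)
    res = FitResult(
        spec=spec, params=RNMParams(), mu=np.zeros(spec.n_traits),
        loglik=ll, n_free_params=spec.n_free_params, converged=True,
        n_iter=1, grad_norm=0.0, n=n,
    )
    if blups_g is not None:
        res.blups = {"g": np.asarray(blups_g, dtype=float)}
    for k, v in kw.items():
        setattr(res, k, v)
    return res


class TestLRT:
    def test_identical_loglik_gives_p_one(self):
        r = lrt(_stub_fit("greml", -500.0), _stub_fit("urnm-full", -500.0))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_chi2_reference_value(self):
        """Statistic 5.99 on 2 df sits at the 5% tail."""
        r = lrt(_stub_fit("urnm-rxe", -500.0), _stub_fit("urnm-full", -497.005))
        assert r.df == 2
        assert r.p_value == pytest.approx(stats.chi2.sf(5.99, 2), abs=1e-6)
        assert r.p_value == pytest.approx(0.0500, abs=5e-4)

    def test_df_ladder(self):
        dfs = {}
        for idx, (null, alt, _) in LADDER_ROWS.items():
            r = lrt(_stub_fit(null, -100.0), _stub_fit(alt, -99.0), index=idx)
            dfs[idx] = r.df
        assert [dfs[f"M{i}"] for i in range(1, 7)] == [4, 2, 2, 6, 3, 3]

    def test_small_negative_statistic_clipped(self):
        r = lrt(_stub_fit("greml", -500.0), _stub_fit("urnm-full", -500.0 - 2e-7))
        assert r.statistic == 0.0

    def test_large_negative_statistic_raises(self):
        with pytest.raises(ArithmeticError):
            lrt(_stub_fit("greml", -500.0), _stub_fit("urnm-full", -501.0))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(_stub_fit("urnm-gxe", -500.0), _stub_fit("urnm-rxe", -499.0))
        with pytest.raises(ValueError):
            lrt(_stub_fit("greml", -500.0), _stub_fit("mrnm-full", -499.0))


class TestLadder:
    def test_full_ladder_structure(self, mid_dataset):
        ds = mid_dataset
        lad = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star)
        assert [r.index for r in lad.rows] == ["M1", "M2", "M3", "M4", "M5", "M6"]
        assert [r.df for r in lad.rows] == [4, 2, 2, 6, 3, 3]
        assert all(r.statistic >= 0.0 for r in lad.rows)
        assert all(0.0 <= r.p_value <= 1.0 for r in lad.rows)
        frame = lad.to_frame()
        assert list(frame["index"]) == ["M1", "M2", "M3", "M4", "M5", "M6"]

    def test_subset_rows(self, mid_dataset):
        ds = mid_dataset
        lad = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=("M2",))
        assert len(lad.rows) == 1
        assert set(lad.fits) == {"urnm-rxe", "urnm-full"}

    def test_missing_c_star_rejected(self, mid_dataset):
        ds = mid_dataset
        with pytest.raises(ValueError, match="c_star"):
            run_ladder(ds.y, ds.grm.A, ds.c, None, rows=("M4",))

    def test_unknown_row(self, mid_dataset):
        ds = mid_dataset
        with pytest.raises(ValueError, match="unknown ladder row"):
            run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=("M7",))


class TestCollinearity:
    def test_equal_logliks_give_zero(self):
        fits = [_stub_fit(n, -300.0) for n in
                ("bigreml", "mrnm-gxe", "mrnm-rxe", "mrnm-full")]
        r = collinearity_magnitude(*fits)
        assert r.collinearity == 0.0

    def test_algebraic_identity(self, rng):
        """M(comb) - M(GxE|RxE) - M(RxE|GxE) == 2(ll_gxe + ll_rxe - ll_0 - ll_f)."""
        for _ in range(20):
            l0, lg, lr, lf = sorted(rng.normal(-500, 10, 4))
            r = collinearity_magnitude(
                _stub_fit("bigreml", l0), _stub_fit("mrnm-gxe", lg),
                _stub_fit("mrnm-rxe", lr), _stub_fit("mrnm-full", lf))
            assert r.collinearity == pytest.approx(
                2 * (lg + lr - l0 - lf), abs=1e-9)

    def test_recomputation_from_fitted_ladder(self, mid_dataset):
        ds = mid_dataset
        lad = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star)
        f = lad.fits
        r = collinearity_magnitude(f["bigreml"], f["mrnm-gxe"],
                                   f["mrnm-rxe"], f["mrnm-full"])
        assert r.magnitude_combined == pytest.approx(
            2 * (f["mrnm-full"].loglik - f["bigreml"].loglik), abs=1e-9)
        assert r.magnitude_gxe_given_rxe >= -1e-6
        assert r.magnitude_rxe_given_gxe >= -1e-6

    def test_mismatched_fits_rejected(self):
        fits = [_stub_fit(n, -1.0) for n in
                ("bigreml", "mrnm-gxe", "mrnm-rxe", "mrnm-full")]
        fits[3].n = 999
        with pytest.raises(ValueError):
            collinearity_magnitude(*fits)


class TestHeritability:
    def test_no_slope_ratio(self):
        f = _stub_fit("greml", -1.0,
                      params=RNMParams(K_g=np.diag([0.35, 0.0]),
                                       K_e=np.diag([0.65, 0.0])))
        s = heritability_summary(f, np.zeros(10))
        assert s.h2 == pytest.approx(0.35)

    def test_standardized_covariate_sums_diagonal(self, rng):
        c = rng.normal(size=2000)
        c = (c - c.mean()) / c.std()
        f = _stub_fit("urnm-full", -1.0,
                      params=RNMParams(K_g=np.diag([0.3, 0.2]),
                                       K_e=np.diag([0.5, 0.0])))
        s = heritability_summary(f, c)
        assert s.mean_genetic_variance == pytest.approx(0.5, abs=1e-9)

    def test_delta_method_se_attached(self, mid_dataset):
        from reactnorm import fit

        ds = mid_dataset
        res = fit(ModelSpec.from_name("urnm-full"), ds.y, ds.grm.A, ds.c,
                  compute_se=True)
        s = heritability_summary(res, ds.c)
        assert 0.0 <= s.h2 <= 1.0
        assert s.se_h2 is not None and s.se_h2 > 0
        assert s.se_mean_residual_variance > 0

    def test_zero_total_variance_errors(self):
        f = _stub_fit("greml", -1.0)
        with pytest.raises(ZeroDivisionError):
            heritability_summary(f, np.zeros(5))


class TestEBV:
    def test_self_correlation_is_one(self):
        f = _stub_fit("greml", -1.0, blups_g=[3.0, 1.0, 2.0, 5.0])
        assert ebv_rank_correlation(f, f) == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        a = _stub_fit("greml", -1.0, blups_g=[1.0, 2.0, 3.0, 4.0])
        b = _stub_fit("urnm-full", -1.0, blups_g=[4.0, 3.0, 2.0, 1.0])
        assert ebv_rank_correlation(a, b) == pytest.approx(-1.0)

    def test_length_mismatch(self):
        a = _stub_fit("greml", -1.0, blups_g=[1.0, 2.0])
        b = _stub_fit("greml", -1.0, blups_g=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ebv_rank_correlation(a, b)

    def test_interaction_shifts_ranks_with_effect_size(self):
        """Rank agreement with the null model decreases as the genetic
        slope variance grows."""
        from reactnorm import scenario

        rhos = []
        for slope in (0.04, 0.16, 0.48):
            K_g = np.array([[0.4, 0.0], [0.0, slope]])
            ds = scenario("gxe", n=300, m=600, seed=5, K_g=K_g)
            lad = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=("M1",))
            rhos.append(ebv_rank_correlation(lad.fits["greml"],
                                             lad.fits["urnm-full"]))
        assert all(r < 1.0 for r in rhos)
        assert rhos[0] > rhos[-1]


class TestResidualContrast:
    def _fit_with_se(self, name, ve, se):
        f = _stub_fit(name, -1.0,
                      params=RNMParams(K_g=np.diag([0.3, 0.0]),
                                       K_e=np.diag([ve, 0.0])))
        f.param_names = ["var(alpha0)", "var(tau0)"]
        f.vcov = np.diag([1e-4, se**2])
        return f

    def test_identical_estimates_give_p_one(self):
        a = self._fit_with_se("bigreml", 0.6, 0.05)
        b = self._fit_with_se("mrnm-full", 0.6, 0.05)
        r = residual_variance_contrast(a, b, np.zeros(10))
        assert r.z == 0.0
        assert r.p_value == 1.0

    def test_1p96_pooled_se_is_five_percent(self):
        pooled = np.hypot(0.05, 0.05)
        a = self._fit_with_se("bigreml", 0.6 + 1.96 * pooled, 0.05)
        b = self._fit_with_se("mrnm-full", 0.6, 0.05)
        r = residual_variance_contrast(a, b, np.zeros(10))
        assert r.p_value == pytest.approx(0.05, abs=1e-4)
        assert "approximat" in r.note.lower()

    def test_real_fits_give_finite_contrast(self, mid_dataset):
        """End-to-end: Wald contrast between the additive and interaction
        models on real fits is finite with a valid p-value."""
        from reactnorm import fit

        ds = mid_dataset
        a = fit(ModelSpec.from_name("bigreml"), ds.y, ds.grm.A, ds.c,
                c_star=ds.c_star, compute_se=True)
        b = fit(ModelSpec.from_name("mrnm-full"), ds.y, ds.grm.A, ds.c,
                c_star=ds.c_star, compute_se=True)
        r = residual_variance_contrast(a, b, ds.c)
        assert np.isfinite(r.z)
        assert 0.0 <= r.p_value <= 1.0
        assert r.estimate_a > 0 and r.estimate_b > 0

    def test_missing_se_rejected(self):
        a = self._fit_with_se("bigreml", 0.6, 0.05)
        b = _stub_fit("mrnm-full", -1.0,
                      params=RNMParams(K_g=np.diag([0.3, 0.0]),
                                       K_e=np.diag([0.6, 0.0])))
        with pytest.raises(ValueError, match="SE|standard error"):
            residual_variance_contrast(a, b, np.zeros(10))
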