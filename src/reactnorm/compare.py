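"""Likelihood-ratio ladder, collinearity magnitude and fit summaries.

Six nested comparisons probe the interaction structure.  Within the
univariate family (covariate as fixed regressor only):

    M1  plain GREML        vs  both interactions      df 4  (combined)
    M2  RxE-only           vs  both interactions      df 2  (orthogonal GxE)
    M3  GxE-only           vs  both interactions      df 2  (orthogonal RxE)

and within the bivariate family (covariate jointly modeled as a second
trait, absorbing G-E and R-E correlations):

    M4  bivariate GREML    vs  full MRNM              df 6  (combined)
    M5  MRNM RxE           vs  full MRNM              df 3  (orthogonal GxE)
    M6  MRNM GxE           vs  full MRNM              df 3  (orthogonal RxE)

The collinearity magnitude quantifies how much of the combined interaction
evidence the two orthogonal contributions fail to account for:
M(combined) - M(GxE|RxE) - M(RxE|GxE) on the 2*logL scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ModelSpec, RNMParams
from .reml import FitResult, fit

__all__ = [
    "ComparisonResult",
    "LadderResult",
    "lrt",
    "run_ladder",
    "collinearity_magnitude",
    "CollinearityResult",
    "HeritabilitySummary",
    "heritability_summary",
    "ebv_rank_correlation",
    "residual_variance_contrast",
    "LADDER_ROWS",
]

#: row -> (null model, alternative model, interaction label)
LADDER_ROWS = {
    "M1": ("greml", "urnm-full", "combined"),
    "M2": ("urnm-rxe", "urnm-full", "orthogonal GxE"),
    "M3": ("urnm-gxe", "urnm-full", "orthogonal RxE"),
    "M4": ("bigreml", "mrnm-full", "combined"),
    "M5": ("mrnm-rxe", "mrnm-full", "orthogonal GxE"),
    "M6": ("mrnm-gxe", "mrnm-full", "orthogonal RxE"),
}


@dataclass
class ComparisonResult:
    index: str
    null_model: str
    alt_model: str
    loglik_null: float
    loglik_alt: float
    statistic: float
    df: int
    p_value: float
    interaction_type: str


@dataclass
class LadderResult:
    rows: list
    fits: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            dict(index=r.index, comparison=f"{r.null_model} vs {r.alt_model}",
                 interaction=r.interaction_type, statistic=r.statistic,
                 df=r.df, p_value=r.p_value)
            for r in self.rows
        ])


def lrt(fit_null: FitResult, fit_alt: FitResult, index: str = "",
        interaction_type: str = "", tol: float = 1e-6,
        boundary_correction: bool = False) -> ComparisonResult:
    """Likelihood-ratio test of two nested fits on the same data/criterion.

    statistic = 2 (logL_alt - logL_null); df = difference in free-parameter
    counts; p from the chi-square upper tail.  Small negative statistics
    (above ``-tol``) are clipped to zero; anything more negative signals an
    unconverged alternative and raises.

    ``boundary_correction`` replaces the plain chi-square reference with the
    equal-weight mixture of chi-square(df-1) and chi-square(df), the usual
    adjustment when the null pins a variance to the boundary of its space.
    The plain reference is the default (common practice) and is conservative
    for these tests.
    """
    if not fit_null.spec.is_nested_in(fit_alt.spec):
        raise ValueError(
            f"{fit_null.spec.name} is not nested in {fit_alt.spec.name} "
            "(or criteria differ)")
    if fit_null.n != fit_alt.n:
        raise ValueError("fits are not on the same data")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < -tol:
        raise ArithmeticError(
            f"alternative logL below null by {-stat / 2:.3g}; "
            "refit the alternative with restarts")
    stat = max(stat, 0.0)
    df = fit_alt.n_free_params - fit_null.n_free_params
    if stat <= 0:
        p = 1.0
    elif boundary_correction:
        p = float(0.5 * stats.chi2.sf(stat, df=max(df - 1, 1))
                  + 0.5 * stats.chi2.sf(stat, df=df))
    else:
        p = float(stats.chi2.sf(stat, df=df))
    return ComparisonResult(
        index=index,
        null_model=fit_null.spec.name,
        alt_model=fit_alt.spec.name,
        loglik_null=fit_null.loglik,
        loglik_alt=fit_alt.loglik,
        statistic=stat,
        df=df,
        p_value=p,
        interaction_type=interaction_type,
    )


def _warm_init(parents, spec: ModelSpec, y, c_star,
               slope_scale: float = 0.05) -> RNMParams | None:
    """Embed nested models' estimates, seeding new diagonals off zero.

    ``parents`` is a list of fitted (params, spec) pairs whose active blocks
    are copied in order (so a GxE-only and an RxE-only fit merge into a
    near-optimal start for the full model).  Starting a slope variance at
    exactly zero stalls the log-Cholesky optimizer (the gradient of a
    log-scale diagonal vanishes with the parameter), so absent diagonals
    start at ``slope_scale`` times the phenotypic variance.
    """
    if not parents:
        return None
    G = np.zeros((3, 3))
    E = np.zeros((3, 3))
    for params, pspec in parents:
        ag, ae = pspec.active_genetic, pspec.active_residual
        G[np.ix_(ag, ag)] = params.joint_genetic()[np.ix_(ag, ag)]
        E[np.ix_(ae, ae)] = params.joint_residual()[np.ix_(ae, ae)]
    vy = float(np.var(y))
    if 1 in spec.active_genetic and G[1, 1] < 1e-8:
        G[1, 1] = slope_scale * vy
    if 1 in spec.active_residual and E[1, 1] < 1e-8:
        E[1, 1] = slope_scale * vy
    if spec.second_trait:
        vc = float(np.var(c_star)) if c_star is not None else 1.0
        if G[2, 2] < 1e-8:
            G[2, 2] = 0.5 * vc
        if E[2, 2] < 1e-8:
            E[2, 2] = 0.5 * vc
    return RNMParams.from_joint(G, E)


# fitting order: every model is warm-started from already-fitted nested
# models; the full models merge the two single-interaction fits
_FIT_ORDER = [
    ("greml", ()),
    ("urnm-gxe", ("greml",)),
    ("urnm-rxe", ("greml",)),
    ("urnm-full", ("urnm-gxe", "urnm-rxe")),
    ("bigreml", ("greml",)),
    ("mrnm-gxe", ("bigreml", "urnm-gxe")),
    ("mrnm-rxe", ("bigreml", "urnm-rxe")),
    ("mrnm-full", ("mrnm-gxe", "mrnm-rxe")),
]


def run_ladder(
    y,
    A,
    c,
    c_star=None,
    rows=("M1", "M2", "M3", "M4", "M5", "M6"),
    criterion: str = "REML",
    compute_se: bool = False,
    seed: int = 0,
    boundary_correction: bool = False,
    **fit_kw,
) -> LadderResult:
    """Fit the component models and assemble the requested ladder rows.

    Models are fitted from small to large with warm starts; whenever an
    alternative's likelihood lands below its null, it is refitted from the
    null's estimates embedded (with near-zero new components) so the
    nesting inequality holds up to optimizer tolerance.
    """
    rows = list(rows)
    needed = set()
    for r in rows:
        if r not in LADDER_ROWS:
            raise ValueError(f"unknown ladder row {r!r}")
        needed.update(LADDER_ROWS[r][:2])
    if any(LADDER_ROWS[r][0].startswith(("bigreml", "mrnm")) or
           LADDER_ROWS[r][1].startswith("mrnm") for r in rows):
        if c_star is None:
            raise ValueError("second-trait rows need the adjusted covariate c_star")

    fits: dict[str, FitResult] = {}
    for name, parent_names in _FIT_ORDER:
        if name not in needed:
            continue
        spec = ModelSpec.from_name(name, criterion=criterion)
        parents = [(fits[p].params, fits[p].spec) for p in parent_names
                   if p in fits]
        init = _warm_init(parents, spec, y, c_star)
        fits[name] = fit(spec, y, A, c, c_star=c_star, init=init,
                         compute_se=compute_se, seed=seed, **fit_kw)

    results = []
    for r in rows:
        null_name, alt_name, label = LADDER_ROWS[r]
        f0, f1 = fits[null_name], fits[alt_name]
        if f1.loglik < f0.loglik - 1e-6:
            spec1 = f1.spec
            # embed the null optimum exactly: the alternative evaluates to
            # the same likelihood there, so the refit can only improve on it
            init = _warm_init([(f0.params, f0.spec)], spec1, y, c_star,
                              slope_scale=0.0)
            refit_kw = dict(fit_kw)
            refit_kw.setdefault("n_restarts", 3)
            refit = fit(spec1, y, A, c, c_star=c_star, init=init,
                        compute_se=compute_se, seed=seed + 1, **refit_kw)
            if refit.loglik > f1.loglik:
                fits[alt_name] = f1 = refit
        try:
            results.append(lrt(f0, f1, index=r, interaction_type=label,
                               boundary_correction=boundary_correction))
        except ArithmeticError as err:
            raise ArithmeticError(f"ladder row {r}: {err}") from None
    return LadderResult(rows=results, fits=fits)


@dataclass
class CollinearityResult:
    magnitude_combined: float
    magnitude_gxe_given_rxe: float
    magnitude_rxe_given_gxe: float
    collinearity: float


def collinearity_magnitude(fit_null: FitResult, fit_gxe: FitResult,
                           fit_rxe: FitResult, fit_full: FitResult) -> CollinearityResult:
    """Overlap between GxE and RxE evidence on the likelihood-ratio scale.

    With M(X) = twice the log-likelihood gain of the richer model:
    collinearity = M(combined) - M(GxE|RxE) - M(RxE|GxE)
                 = 2 (logL_gxe + logL_rxe - logL_null - logL_full).
    The sign is unconstrained; the two orthogonal magnitudes are each >= 0
    up to convergence tolerance.
    """
    for f in (fit_null, fit_gxe, fit_rxe, fit_full):
        if f is None:
            raise ValueError("all four fits are required")
    crits = {f.spec.criterion for f in (fit_null, fit_gxe, fit_rxe, fit_full)}
    ns = {f.n for f in (fit_null, fit_gxe, fit_rxe, fit_full)}
    if len(crits) != 1 or len(ns) != 1:
        raise ValueError("fits must share data and criterion")
    m_comb = 2.0 * (fit_full.loglik - fit_null.loglik)
    m_gxe = 2.0 * (fit_full.loglik - fit_rxe.loglik)
    m_rxe = 2.0 * (fit_full.loglik - fit_gxe.loglik)
    return CollinearityResult(
        magnitude_combined=m_comb,
        magnitude_gxe_given_rxe=m_gxe,
        magnitude_rxe_given_gxe=m_rxe,
        collinearity=m_comb - m_gxe - m_rxe,
    )


@dataclass
class HeritabilitySummary:
    mean_genetic_variance: float
    mean_residual_variance: float
    h2: float
    se_h2: float | None = None
    se_mean_genetic_variance: float | None = None
    se_mean_residual_variance: float | None = None


def _variance_gradients(fit: FitResult, m1: float, m2: float):
    """d(mean genetic var)/dtheta and d(mean residual var)/dtheta."""
    weights = {"var(alpha0)": 1.0, "cov(alpha0,alpha1)": 2.0 * m1,
               "var(alpha1)": m2}
    wres = {"var(tau0)": 1.0, "cov(tau0,tau1)": 2.0 * m1, "var(tau1)": m2}
    gg = np.array([weights.get(nm, 0.0) for nm in fit.param_names])
    ge = np.array([wres.get(nm, 0.0) for nm in fit.param_names])
    return gg, ge


def heritability_summary(fit: FitResult, c) -> HeritabilitySummary:
    """Average-over-individuals variance ratio under the fitted model.

    mean genetic variance = sum_i phi_i K_g phi_i' / n (and analogously for
    the residual side); h2 is their ratio.  With a stored parameter
    covariance, delta-method standard errors are attached.
    """
    c = np.asarray(c, dtype=float)
    m1, m2 = float(c.mean()), float((c ** 2).mean())
    Kg, Ke = fit.params.K_g, fit.params.K_e
    vg = Kg[0, 0] + 2.0 * Kg[0, 1] * m1 + Kg[1, 1] * m2
    ve = Ke[0, 0] + 2.0 * Ke[0, 1] * m1 + Ke[1, 1] * m2
    total = vg + ve
    if total <= 0:
        raise ZeroDivisionError("total variance is not positive")
    out = HeritabilitySummary(
        mean_genetic_variance=vg, mean_residual_variance=ve, h2=vg / total)
    if fit.vcov is not None:
        gg, ge = _variance_gradients(fit, m1, m2)
        out.se_mean_genetic_variance = float(np.sqrt(max(gg @ fit.vcov @ gg, 0)))
        out.se_mean_residual_variance = float(np.sqrt(max(ge @ fit.vcov @ ge, 0)))
        gh = (ve * gg - vg * ge) / total**2
        out.se_h2 = float(np.sqrt(max(gh @ fit.vcov @ gh, 0)))
    return out


def ebv_rank_correlation(fit_a: FitResult, fit_b: FitResult) -> float:
    """Spearman correlation of estimated breeding values g = a0 + a1 c."""
    ga, gb = fit_a.blups.get("g"), fit_b.blups.get("g")
    if ga is None or gb is None:
        raise ValueError("fits must carry BLUPs (compute_blups=True)")
    if len(ga) != len(gb):
        raise ValueError("fits cover different animals")
    rho, _ = stats.spearmanr(ga, gb)
    return float(rho)


@dataclass
class ResidualContrast:
    estimate_a: float
    estimate_b: float
    z: float
    p_value: float
    note: str = ("Wald contrast assuming independent fits; approximate, "
                 "since both models are fitted to the same data")


def residual_variance_contrast(fit_a: FitResult, fit_b: FitResult,
                               c) -> ResidualContrast:
    """Approximate two-sided test of equal mean residual variance.

    z = (e_a - e_b) / sqrt(SE_a^2 + SE_b^2) with the mean residual
    variances and their delta-method SEs from each fit.  Explicitly an
    approximation: the two fits share the data, so their estimates are not
    independent.
    """
    sa = heritability_summary(fit_a, c)
    sb = heritability_summary(fit_b, c)
    if sa.se_mean_residual_variance is None or sb.se_mean_residual_variance is None:
        raise ValueError("both fits need standard errors (compute_se=True)")
    denom = np.hypot(sa.se_mean_residual_variance, sb.se_mean_residual_variance)
    z = (sa.mean_residual_variance - sb.mean_residual_variance) / denom
    return ResidualContrast(
        estimate_a=sa.mean_residual_variance,
        estimate_b=sb.mean_residual_variance,
        z=float(z),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
    )
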