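"""REML/ML estimation for reaction-norm and multi-trait GREML models.

The engine maximizes the (restricted) Gaussian likelihood of the stacked
observations over the free variance components of a :class:`~reactnorm.models.ModelSpec`.
Free components are the unstructured covariance blocks over the active
genetic and residual component sets; each block is parameterized by its
Cholesky factor with log-transformed diagonal, which keeps every iterate
positive semi-definite and makes the problem unconstrained.  Gradients are
analytic: for a variance parameter th with V_th = dV/dth,

    dl/dth = -1/2 [ tr(P V_th) - y' P V_th P y ]        (REML)

with P the projected inverse covariance, and all trace terms reduce to
quadratic forms in the component loading vectors, so one gradient costs one
Cholesky factorization plus O(n^2) work.

The restricted likelihood includes its full constant, so the value equals
the log-density of any orthonormal basis of error contrasts -- convenient
for testing against an independent dense construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import optimize

from .models import (
    GENETIC_COMPONENTS,
    RESIDUAL_COMPONENTS,
    ModelSpec,
    RNMParams,
    component_loadings,
    tile_structures,
)

__all__ = ["FitResult", "loglik", "fit", "multi_trait_greml",
           "multi_trait_loglik", "MultiTraitResult"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FitResult:
    spec: ModelSpec
    params: RNMParams
    mu: np.ndarray  # GLS grand mean per modeled trait
    loglik: float
    n_free_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    blups: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    vcov: np.ndarray | None = None
    param_names: list = field(default_factory=list)
    n: int = 0

    def param_vector(self) -> np.ndarray:
        """Free parameters in vech order (matches ``param_names``)."""
        return _params_to_vech(self.params, self.spec)

    def summary(self) -> str:
        lines = [
            f"model: {self.spec.name}   criterion: {self.spec.criterion}",
            f"logL = {self.loglik:.4f}   free params = {self.n_free_params}"
            f"   converged = {self.converged} ({self.n_iter} iterations)",
        ]
        vec = self.param_vector()
        for name, val in zip(self.param_names, vec):
            se = self.se.get(name)
            lines.append(f"  {name:<24s} {val: .4f}"
                         + (f"  (SE {se:.4f})" if se is not None else ""))
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        vec = self.param_vector()
        return pd.DataFrame({
            "parameter": self.param_names,
            "estimate": vec,
            "se": [self.se.get(nm, np.nan) for nm in self.param_names],
        })


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _vech_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i + 1)]


def _block_param_names(active, labels):
    names = []
    for i, j in _vech_indices(len(active)):
        a, b = labels[active[i]], labels[active[j]]
        names.append(f"var({a})" if i == j else f"cov({a},{b})")
    return names


def param_names_for(spec: ModelSpec) -> list[str]:
    return (_block_param_names(spec.active_genetic, GENETIC_COMPONENTS)
            + _block_param_names(spec.active_residual, RESIDUAL_COMPONENTS))


def _params_to_vech(params: RNMParams, spec: ModelSpec) -> np.ndarray:
    G, E = params.joint_genetic(), params.joint_residual()
    out = []
    for M, active in ((G, spec.active_genetic), (E, spec.active_residual)):
        sub = M[np.ix_(active, active)]
        out.extend(sub[i, j] for i, j in _vech_indices(len(active)))
    return np.array(out)


def _vech_to_params(theta: np.ndarray, spec: ModelSpec) -> RNMParams:
    G = np.zeros((3, 3))
    E = np.zeros((3, 3))
    pos = 0
    for M, active in ((G, spec.active_genetic), (E, spec.active_residual)):
        k = len(active)
        for i, j in _vech_indices(k):
            M[active[i], active[j]] = M[active[j], active[i]] = theta[pos]
            pos += 1
    return RNMParams.from_joint(G, E)


def _chol_pack(M: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a PSD matrix as a vector with log diagonal."""
    k = M.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(M + jitter * np.eye(k))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-8)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("could not factorize initial covariance")
    out = []
    for i, j in _vech_indices(k):
        out.append(np.log(max(L[i, i], 1e-8)) if i == j else L[i, j])
    return np.array(out)


def _chol_unpack(x: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    for pos, (i, j) in enumerate(_vech_indices(k)):
        L[i, j] = np.exp(np.clip(x[pos], -40.0, 40.0)) if i == j else x[pos]
    return L


# ---------------------------------------------------------------------------
# likelihood workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed structures shared across likelihood evaluations."""

    def __init__(self, spec: ModelSpec, y, A, c, c_star=None):
        y = np.asarray(y, dtype=float)
        A = np.asarray(A, dtype=float)
        c = np.asarray(c, dtype=float)
        n = len(y)
        if A.shape != (n, n):
            raise ValueError("GRM dimension does not match phenotype length")
        if len(c) != n:
            raise ValueError("covariate length does not match phenotype length")
        self.spec = spec
        self.n = n
        if spec.second_trait:
            if c_star is None:
                raise ValueError(f"model {spec.name!r} requires the adjusted "
                                 "covariate c_star as second trait")
            c_star = np.asarray(c_star, dtype=float)
            self.y = np.concatenate([y, c_star])
            X = np.zeros((2 * n, 2))
            X[:n, 0] = 1.0
            X[n:, 1] = 1.0
        else:
            self.y = y
            X = np.ones((n, 1))
        self.X = X
        self.n_obs, self.p = X.shape
        self.logdet_XtX = self.p * np.log(n)
        self.F = component_loadings(c, spec.second_trait)
        self.Tg, self.Te = tile_structures(A, spec.second_trait)
        self.Fg = self.F[:, list(spec.active_genetic)]
        self.Fe = self.F[:, list(spec.active_residual)]
        if spec.n_free_params > n:
            raise ValueError(
                f"{spec.n_free_params} free parameters exceed n = {n}")

    # -- assembly -----------------------------------------------------------

    def build_V(self, Gact: np.ndarray, Eact: np.ndarray) -> np.ndarray:
        V = (self.Fg @ Gact @ self.Fg.T) * self.Tg
        V += (self.Fe @ Eact @ self.Fe.T) * self.Te
        return V

    def _common(self, V):
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        ViX = sla.cho_solve(cf, self.X, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        b = np.linalg.solve(XtViX, ViX.T @ self.y)
        r = self.y - self.X @ b
        Vir = sla.cho_solve(cf, r, check_finite=False)
        quad = float(r @ Vir)
        return cf, logdetV, ViX, XtViX, logdet_XtViX, b, r, Vir, quad

    def loglik_only(self, Gact, Eact) -> tuple[float, np.ndarray]:
        V = self.build_V(Gact, Eact)
        cf, logdetV, ViX, XtViX, logdet_XtViX, b, r, Vir, quad = self._common(V)
        if self.spec.criterion == "REML":
            ll = -0.5 * ((self.n_obs - self.p) * _LOG2PI + logdetV
                         + logdet_XtViX - self.logdet_XtX + quad)
        else:
            ll = -0.5 * (self.n_obs * _LOG2PI + logdetV + quad)
        return float(ll), b

    def loglik_grad(self, Gact, Eact, want_ai: bool = False):
        """Log-likelihood, S matrices (dl/dG, dl/dE entrywise) and optionally
        the average-information matrix over the vech parameters."""
        V = self.build_V(Gact, Eact)
        cf, logdetV, ViX, XtViX, logdet_XtViX, b, r, Vir, quad = self._common(V)
        Vi, info = sla.lapack.dpotri(cf[0], lower=1)
        if info != 0:  # pragma: no cover
            raise np.linalg.LinAlgError("dpotri failed")
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        if self.spec.criterion == "REML":
            ll = -0.5 * ((self.n_obs - self.p) * _LOG2PI + logdetV
                         + logdet_XtViX - self.logdet_XtX + quad)
            Q = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        else:
            ll = -0.5 * (self.n_obs * _LOG2PI + logdetV + quad)
            Q = Vi
        w = Vir  # equals P y under REML
        Sg = self._block_S(self.Fg, Q, w, self.Tg)
        Se = self._block_S(self.Fe, Q, w, self.Te)
        if not want_ai:
            return float(ll), Sg, Se, b
        # AI_kl = 1/2 (dV_k Py)' P (dV_l Py); dV_k Py reduces to loading products
        cols = []
        for Fa, T in ((self.Fg, self.Tg), (self.Fe, self.Te)):
            k = Fa.shape[1]
            tw = [T @ (Fa[:, j] * w) for j in range(k)]
            for i, j in _vech_indices(k):
                u = Fa[:, i] * tw[j]
                if i != j:
                    u = u + Fa[:, j] * tw[i]
                cols.append(u)
        U = np.column_stack(cols)
        QU = Q @ U
        AI = 0.5 * (U.T @ QU)
        return float(ll), Sg, Se, b, AI

    @staticmethod
    def _block_S(Fa, Q, w, T):
        trace_mat = Fa.T @ (Q * T) @ Fa
        Vw = Fa * w[:, None]
        quad_mat = Vw.T @ T @ Vw
        return -0.5 * (trace_mat - quad_mat)


def loglik(params: RNMParams, y, A, c, spec: ModelSpec, c_star=None) -> float:
    """(Restricted) log-likelihood of the data at the given parameters.

    Includes the full Gaussian constant: under REML the value equals the
    log-density of an orthonormal basis of error contrasts K'y ~ N(0, K'VK).
    """
    ws = _Workspace(spec, y, A, c, c_star)
    Gact = params.joint_genetic()[np.ix_(spec.active_genetic, spec.active_genetic)]
    Eact = params.joint_residual()[np.ix_(spec.active_residual, spec.active_residual)]
    ll, _ = ws.loglik_only(Gact, Eact)
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _default_init(spec: ModelSpec, y, c_star) -> RNMParams:
    vy = float(np.var(y))
    G = np.zeros((3, 3))
    E = np.zeros((3, 3))
    G[0, 0] = 0.45 * vy
    E[0, 0] = 0.45 * vy
    if spec.genetic_slope:
        G[1, 1] = 0.05 * vy
    if spec.residual_slope:
        E[1, 1] = 0.05 * vy
    if spec.second_trait:
        vc = float(np.var(c_star))
        G[2, 2] = 0.5 * vc
        E[2, 2] = 0.5 * vc
    return RNMParams.from_joint(G, E)


def _grad_from_S(Sg, Se, Lg, Le):
    grads = []
    for S, L in ((Sg, Lg), (Se, Le)):
        dL = 2.0 * (S @ L)
        g = []
        for i, j in _vech_indices(L.shape[0]):
            g.append(dL[i, i] * L[i, i] if i == j else dL[i, j])
        grads.extend(g)
    return np.array(grads)


def _vech_grad_from_S(Sg, Se):
    """Gradient over vech parameters (off-diagonals counted once)."""
    out = []
    for S in (Sg, Se):
        for i, j in _vech_indices(S.shape[0]):
            out.append(S[i, i] if i == j else 2.0 * S[i, j])
    return np.array(out)


def _split_vech(theta, kg, ke):
    ng = kg * (kg + 1) // 2
    Gact = np.zeros((kg, kg))
    Eact = np.zeros((ke, ke))
    for pos, (i, j) in enumerate(_vech_indices(kg)):
        Gact[i, j] = Gact[j, i] = theta[pos]
    for pos, (i, j) in enumerate(_vech_indices(ke)):
        Eact[i, j] = Eact[j, i] = theta[ng + pos]
    return Gact, Eact


def _join_vech(Gact, Eact):
    kg, ke = Gact.shape[0], Eact.shape[0]
    return np.concatenate([
        np.array([Gact[i, j] for i, j in _vech_indices(kg)]),
        np.array([Eact[i, j] for i, j in _vech_indices(ke)]),
    ])


def _project_psd(M: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh((M + M.T) / 2.0)
    if lam[0] >= 0:
        return M
    return (vec * np.clip(lam, 0.0, None)) @ vec.T


def _ai_reml(ws: _Workspace, theta0: np.ndarray, kg: int, ke: int,
             tol: float, max_iter: int):
    """Average-information REML on the variance-component (vech) scale.

    Newton-like updates with the AI matrix, step halving, and projection of
    each covariance block back onto the PSD cone -- the standard fast
    algorithm for GREML-type models.  Variance components that reach zero
    with a non-positive gradient are frozen (their rows in the update drop
    out, an active-set treatment of the boundary), so null-adjacent fits
    converge as quickly as interior ones.  Returns the best point found and
    whether the Newton-decrement criterion was met.
    """
    coords = [(0, i, j) for i, j in _vech_indices(kg)]
    coords += [(1, i, j) for i, j in _vech_indices(ke)]
    npar = len(coords)
    comp_coords = {}  # (block, component) -> coord positions touching it
    diag_coord = {}   # (block, component) -> its variance position
    for pos, (b, i, j) in enumerate(coords):
        for comp in {i, j}:
            comp_coords.setdefault((b, comp), []).append(pos)
        if i == j:
            diag_coord[(b, i)] = pos

    # absolute scale for "a variance is zero": fraction of the data variance
    vscale = max(float(np.var(ws.y)), 1e-8)
    tiny = 1e-7 * vscale

    theta = theta0.copy()
    frozen: set[tuple[int, int]] = set()

    def apply_freeze(th):
        out = th.copy()
        for key in frozen:
            out[comp_coords[key]] = 0.0
        return out

    def is_feasible(th):
        Gc, Ec = _split_vech(th, kg, ke)
        for M in (Gc, Ec):
            try:
                np.linalg.cholesky(M + 1e-12 * np.eye(M.shape[0]))
            except np.linalg.LinAlgError:
                return False
        return True

    def feasible_cap(th, direction):
        """Largest t in (0, 1] keeping th + t*direction PSD (bisection)."""
        if is_feasible(th + direction):
            return 1.0
        lo, hi = 0.0, 1.0
        for _ in range(20):
            mid = (lo + hi) / 2.0
            if is_feasible(th + mid * direction):
                lo = mid
            else:
                hi = mid
        return 0.98 * lo

    def evaluate(th):
        Gact, Eact = _split_vech(th, kg, ke)
        ll, Sg, Se, b, AI = ws.loglik_grad(Gact, Eact, want_ai=True)
        return ll, _vech_grad_from_S(Sg, Se), AI

    if not is_feasible(theta):
        Gc, Ec = _split_vech(theta, kg, ke)
        theta = _join_vech(_project_psd(Gc) + tiny * np.eye(kg),
                           _project_psd(Ec) + tiny * np.eye(ke))
    try:
        ll, grad, AI = evaluate(theta)
    except np.linalg.LinAlgError:
        return theta, -np.inf, 0, False
    converged = False
    it = 0

    def release_candidates():
        return [key for key, dpos in diag_coord.items()
                if key in frozen and grad[dpos] > 1e-8]

    for it in range(1, max_iter + 1):
        # active-set update: freeze zero variances being pushed negative,
        # release any frozen component whose gradient turned positive
        for key, dpos in diag_coord.items():
            if key in frozen:
                if grad[dpos] > 1e-8:
                    frozen.discard(key)
            elif theta[dpos] < tiny and grad[dpos] < -1e-10:
                frozen.add(key)
        theta = apply_freeze(theta)
        mask = np.ones(npar, dtype=bool)
        for key in frozen:
            mask[comp_coords[key]] = False
        nfree = int(mask.sum())
        if nfree == 0:  # pragma: no cover - everything pinned at zero
            converged = True
            break
        g = grad[mask]
        H = AI[np.ix_(mask, mask)]
        ridge = 1e-8 * max(np.trace(H) / nfree, 1.0)
        step_m = None
        for _ in range(8):
            try:
                step_m = np.linalg.solve(H + ridge * np.eye(nfree), g)
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        if step_m is None:  # pragma: no cover
            break
        if 0.5 * float(g @ step_m) < tol * max(1.0, abs(ll)):
            rel = release_candidates()
            if rel:  # a pinned component wants back in; keep iterating
                frozen.difference_update(rel)
                continue
            converged = True
            break
        step = np.zeros(npar)
        step[mask] = step_m
        grad_dir = np.zeros(npar)
        grad_dir[mask] = g / max(np.trace(H) / nfree, 1.0)
        improved = False
        for direction in (step, grad_dir):
            factor = feasible_cap(theta, direction)
            for _ in range(10):
                if factor <= 1e-10:
                    break
                cand = apply_freeze(theta + factor * direction)
                try:
                    ll_c, grad_c, AI_c = evaluate(cand)
                except np.linalg.LinAlgError:
                    factor /= 2.0
                    continue
                if ll_c > ll + 1e-12:
                    theta, ll, grad, AI = cand, ll_c, grad_c, AI_c
                    improved = True
                    break
                factor /= 2.0
            if improved:
                break
        if not improved:
            rel = release_candidates()
            if rel:
                frozen.difference_update(rel)
                continue
            # no ascent direction improves: at a (possibly boundary) optimum
            converged = True
            break
    return theta, ll, it, converged


def fit(
    spec: ModelSpec,
    y,
    A,
    c,
    c_star=None,
    init: RNMParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 2,
    compute_se: bool = False,
    compute_blups: bool = True,
    seed: int = 0,
) -> FitResult:
    """Maximize the REML (or ML) likelihood of a reaction-norm model.

    Parameters
    ----------
    spec : ModelSpec
        Which variance components are free.
    y, A, c, c_star
        Trait phenotype, genomic relationship matrix, standardized
        environmental covariate, and (for second-trait models) the adjusted
        covariate serving as the second phenotype.
    init : RNMParams, optional
        Warm start; defaults to an equal-split heuristic.
    n_restarts : int
        Additional randomized starts attempted when the first optimization
        fails to converge or a later start is needed to escape a poor local
        optimum.
    compute_se : bool
        Standard errors from the inverse observed information (numerical
        Hessian of the profile-free likelihood over the vech parameters).
    """
    ws = _Workspace(spec, y, A, c, c_star)
    kg, ke = len(spec.active_genetic), len(spec.active_residual)
    ng = kg * (kg + 1) // 2

    def unpack(x):
        Lg = _chol_unpack(x[:ng], kg)
        Le = _chol_unpack(x[ng:], ke)
        return Lg, Le

    def nll(x):
        Lg, Le = unpack(x)
        try:
            ll, Sg, Se, b = ws.loglik_grad(Lg @ Lg.T, Le @ Le.T)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e10, np.zeros_like(x)
        return -ll, -_grad_from_S(Sg, Se, Lg, Le)

    def lbfgs(x_start, iters=max_iter):
        diag_pos = [p for p, (i, j) in enumerate(_vech_indices(kg)) if i == j]
        diag_pos += [ng + p for p, (i, j) in enumerate(_vech_indices(ke)) if i == j]
        bounds = [(-9.0, 12.0) if p in diag_pos else (-1e3, 1e3)
                  for p in range(len(x_start))]
        return optimize.minimize(
            nll, x_start, jac=True, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=iters, ftol=tol * 1e-2, gtol=1e-4),
        )

    if init is None:
        init = _default_init(spec, ws.y[: ws.n], c_star)
    Gact0 = init.joint_genetic()[np.ix_(spec.active_genetic, spec.active_genetic)]
    Eact0 = init.joint_residual()[np.ix_(spec.active_residual, spec.active_residual)]
    theta0 = _join_vech(_project_psd(Gact0), _project_psd(Eact0))

    # primary: average-information updates on the variance scale
    theta, ll_ai, it_ai, conv_ai = _ai_reml(ws, theta0, kg, ke, tol, max_iter=60)
    best_theta, best_ll, total_iter = theta, ll_ai, it_ai
    converged = conv_ai

    # log-Cholesky polish: a short verification pass when the AI stage
    # converged (escapes boundary-adjacent local dips the projected Newton
    # step can fall into), a full pass when it stalled
    if np.isfinite(best_ll):
        Gb, Eb = _split_vech(best_theta, kg, ke)
        x_polish = np.concatenate([_chol_pack(Gb), _chol_pack(Eb)])
    else:
        x_polish = np.concatenate([_chol_pack(Gact0), _chol_pack(Eact0)])
    res = lbfgs(x_polish, iters=20 if conv_ai else 100)
    total_iter += int(res.nit)
    if conv_ai and res.fun < 1e9 and -res.fun > best_ll + 1e-4:
        # the quick pass found something better; finish the job
        res = lbfgs(res.x, iters=150)
        total_iter += int(res.nit)
    if res.fun < 1e9 and -res.fun > best_ll:
        Lg, Le = unpack(res.x)
        best_theta = _join_vech(Lg @ Lg.T, Le @ Le.T)
        best_ll = -res.fun
        converged = converged or res.success or np.linalg.norm(res.jac) < 1e-3

    # fallback / escape: randomized restarts when nothing converged
    if not converged or not np.isfinite(best_ll):
        rng = np.random.default_rng(seed)
        x0 = np.concatenate([_chol_pack(Gact0), _chol_pack(Eact0)])
        for attempt in range(n_restarts):
            res = lbfgs(x0 + rng.normal(0.0, 0.4, len(x0)))
            total_iter += int(res.nit)
            if res.fun < 1e9 and -res.fun > best_ll + 1e-9:
                Lg, Le = unpack(res.x)
                best_theta = _join_vech(Lg @ Lg.T, Le @ Le.T)
                best_ll = -res.fun
                converged = bool(res.success or np.linalg.norm(res.jac) < 1e-3)
            else:
                converged = converged or bool(res.fun < 1e9 and res.success)
            if converged:
                break

    Gact, Eact = _split_vech(best_theta, kg, ke)
    params = _vech_to_params(_join_vech(Gact, Eact), spec)
    ll, b = ws.loglik_only(Gact, Eact)
    _, Sg, Se, _ = ws.loglik_grad(Gact, Eact)
    grad_norm = float(np.linalg.norm(_vech_grad_from_S(Sg, Se)))
    result = FitResult(
        spec=spec,
        params=params,
        mu=np.asarray(b, dtype=float).ravel(),
        loglik=ll,
        n_free_params=spec.n_free_params,
        converged=bool(converged and np.isfinite(ll)),
        n_iter=int(total_iter),
        grad_norm=grad_norm,
        n=ws.n,
    )
    result.param_names = param_names_for(spec)
    if compute_blups:
        result.blups = _blups(ws, params, np.asarray(c, dtype=float))
    if compute_se:
        vcov = _observed_information_vcov(ws, params, spec)
        result.vcov = vcov
        result.se = {
            nm: float(np.sqrt(v)) if v > 0 else np.nan
            for nm, v in zip(result.param_names, np.diag(vcov))
        }
    return result


def _blups(ws: _Workspace, params: RNMParams, c: np.ndarray) -> dict:
    """Conditional means of the random regression coefficients."""
    G = params.joint_genetic()
    E = params.joint_residual()
    Gact = G[np.ix_(ws.spec.active_genetic, ws.spec.active_genetic)]
    Eact = E[np.ix_(ws.spec.active_residual, ws.spec.active_residual)]
    V = ws.build_V(Gact, Eact)
    cf = sla.cho_factor(V, lower=True, check_finite=False)
    ViX = sla.cho_solve(cf, ws.X, check_finite=False)
    b = np.linalg.solve(ws.X.T @ ViX, ViX.T @ ws.y)
    w = sla.cho_solve(cf, ws.y - ws.X @ b, check_finite=False)

    n = ws.n
    A_tile = ws.Tg[:n, :n]  # the GRM itself

    def fold(v):
        return v[:n] + (v[n:] if ws.spec.second_trait else 0.0)

    s = [fold(ws.F[:, l] * w) for l in range(3)]
    out = {}
    for k, lab in enumerate(GENETIC_COMPONENTS):
        load = sum(G[k, l] * s[l] for l in range(3))
        out[lab] = A_tile @ load
    for k, lab in enumerate(RESIDUAL_COMPONENTS):
        out[lab] = sum(E[k, l] * s[l] for l in range(3))
    out["g"] = out["alpha0"] + out["alpha1"] * c
    return out


def _observed_information_vcov(ws, params, spec, step: float = 1e-4):
    """Covariance of the free parameters from a numerical observed information.

    Central differences of the analytic gradient on the vech scale; the step
    is shrunk when a perturbed parameter leaves the feasible (positive
    definite) region.
    """
    theta = _params_to_vech(params, spec)
    k = len(theta)

    def grad_at(t):
        p = _vech_to_params(t, spec)
        Gact = p.joint_genetic()[np.ix_(spec.active_genetic, spec.active_genetic)]
        Eact = p.joint_residual()[np.ix_(spec.active_residual, spec.active_residual)]
        _, Sg, Se, _ = ws.loglik_grad(Gact, Eact)
        out = []
        for S, active in ((Sg, spec.active_genetic), (Se, spec.active_residual)):
            for i, j in _vech_indices(len(active)):
                out.append(S[i, i] if i == j else 2.0 * S[i, j])
        return np.array(out)

    H = np.zeros((k, k))
    for i in range(k):
        h = step * max(abs(theta[i]), 0.05)
        for _ in range(6):
            try:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h
                tm[i] -= h
                H[:, i] = (grad_at(tp) - grad_at(tm)) / (2.0 * h)
                break
            except np.linalg.LinAlgError:
                h /= 10.0
        else:  # pragma: no cover
            H[:, i] = np.nan
    H = (H + H.T) / 2.0
    try:
        return np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(-H)


# ---------------------------------------------------------------------------
# multi-trait GREML
# ---------------------------------------------------------------------------

def multi_trait_loglik(Y, A, Sigma_g, Sigma_e, criterion: str = "REML") -> float:
    """(Restricted) log-likelihood of the multi-trait GREML model at fixed
    covariances, same constant convention as :func:`loglik`."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    A = np.asarray(A, dtype=float)
    n, t = Y.shape
    lam, U = np.linalg.eigh(A)
    Yt = U.T @ Y
    a = U.T @ np.ones(n)
    W = lam[:, None, None] * np.asarray(Sigma_g) + np.asarray(Sigma_e)
    sign, logdets = np.linalg.slogdet(W)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("covariance not positive definite")
    Wi = np.linalg.inv(W)
    XtViX = np.einsum("i,ijk->jk", a * a, Wi)
    XtViy = np.einsum("i,ijk,ik->j", a, Wi, Yt)
    b = np.linalg.solve(XtViX, XtViy)
    R = Yt - np.outer(a, b)
    quad = float(np.einsum("ij,ijk,ik->", R, Wi, R))
    logdetV = float(logdets.sum())
    if criterion == "REML":
        s2, ld2 = np.linalg.slogdet(XtViX)
        if s2 <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return float(-0.5 * ((n * t - t) * _LOG2PI + logdetV + ld2
                             - t * np.log(n) + quad))
    return float(-0.5 * (n * t * _LOG2PI + logdetV + quad))


@dataclass
class MultiTraitResult:
    Sigma_g: np.ndarray
    Sigma_e: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    heritabilities: np.ndarray = None
    genetic_correlations: np.ndarray = None


def multi_trait_greml(
    Y,
    A,
    criterion: str = "REML",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MultiTraitResult:
    """Unstructured multi-trait GREML: V = Sigma_g (x) A + Sigma_e (x) I.

    Rows of ``Y`` are individuals, columns traits (t <= 4); rows with any
    missing trait are dropped (listwise).  The spectral decomposition of the
    GRM reduces every likelihood evaluation to n independent t x t problems.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    keep = ~np.isnan(Y).any(axis=1)
    Y = Y[keep]
    A = np.asarray(A, dtype=float)[np.ix_(keep, keep)]
    n, t = Y.shape
    if t > 4:
        raise ValueError("at most four traits are supported")

    lam, U = np.linalg.eigh(A)
    Yt = U.T @ Y            # n x t
    a = U.T @ np.ones(n)    # rotated intercept column
    nv = t * (t + 1) // 2

    def unpack(x):
        Lg = _chol_unpack(x[:nv], t)
        Le = _chol_unpack(x[nv:], t)
        return Lg @ Lg.T, Le @ Le.T

    def nll(x):
        Sg, Se = unpack(x)
        W = lam[:, None, None] * Sg + Se  # (n, t, t)
        sign, logdets = np.linalg.slogdet(W)
        if np.any(sign <= 0):
            return 1e10
        Wi = np.linalg.inv(W)
        XtViX = np.einsum("i,ijk->jk", a * a, Wi)
        XtViy = np.einsum("i,ijk,ik->j", a, Wi, Yt)
        b = np.linalg.solve(XtViX, XtViy)
        R = Yt - np.outer(a, b)
        quad = float(np.einsum("ij,ijk,ik->", R, Wi, R))
        logdetV = float(logdets.sum())
        if criterion == "REML":
            s2, ld2 = np.linalg.slogdet(XtViX)
            if s2 <= 0:
                return 1e10
            ll = -0.5 * ((n * t - t) * _LOG2PI + logdetV + ld2
                         - t * np.log(n) + quad)
        else:
            ll = -0.5 * (n * t * _LOG2PI + logdetV + quad)
        return -ll

    vy = np.var(Y, axis=0)
    Sg0 = np.diag(0.5 * vy)
    Se0 = np.diag(0.5 * vy)
    x0 = np.concatenate([_chol_pack(Sg0), _chol_pack(Se0)])
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options=dict(maxiter=max_iter, ftol=tol * 1e-2))
    Sg, Se = unpack(res.x)
    # recover mu at the optimum
    W = lam[:, None, None] * Sg + Se
    Wi = np.linalg.inv(W)
    XtViX = np.einsum("i,ijk->jk", a * a, Wi)
    XtViy = np.einsum("i,ijk,ik->j", a, Wi, Yt)
    mu = np.linalg.solve(XtViX, XtViy)
    dg, de = np.diag(Sg), np.diag(Se)
    h2 = dg / (dg + de)
    denom = np.sqrt(np.outer(dg, dg))
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = Sg / np.where(denom > 0, denom, np.nan)
    return MultiTraitResult(
        Sigma_g=Sg, Sigma_e=Se, mu=mu, loglik=float(-res.fun),
        converged=bool(res.success and res.fun < 1e9), n_iter=int(res.nit),
        heritabilities=h2, genetic_correlations=rg,
    )
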