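"""Covariance algebra for reaction-norm mixed models.

A phenotype y and (optionally) an adjusted environmental covariate c* are
modeled jointly.  Random genetic effects are a zero- and first-order random
regression on the standardized covariate c, with coefficient covariance K_g;
residual effects mirror that structure with K_e.  When the covariate is
modeled as a second trait, its own genetic and residual components (beta,
epsilon) and their covariances with the regression coefficients join the
parameter set, giving 3x3 joint genetic and residual covariance matrices
over (alpha0, alpha1, beta) and (tau0, tau1, epsilon).

The marginal covariance of the stacked observations is

    cov(y_i, y_j)  = A_ij (phi_i K_g phi_j') + 1[i=j] (phi_i K_e phi_i')
    cov(y_i, c*_j) = A_ij (phi_i K_gb)       + 1[i=j] (phi_i K_ee)
    cov(c*, c*)    = A sigma2_beta + I sigma2_eps

with phi_i = (1, c_i) and A the genomic relationship matrix.  Residual
contributions are diagonal because each animal has a single record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RNMParams", "ModelSpec", "build_phi", "assemble_covariance", "MODEL_NAMES"]

# component order in the joint 3x3 blocks
GENETIC_COMPONENTS = ("alpha0", "alpha1", "beta")
RESIDUAL_COMPONENTS = ("tau0", "tau1", "eps")


@dataclass
class RNMParams:
    """Variance components of the (multivariate) reaction-norm model.

    All cross terms default to zero so the same container serves every model
    in the nesting ladder; entries masked out by a :class:`ModelSpec` must be
    exactly zero.
    """

    K_g: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    K_e: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    K_g_beta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    K_e_eps: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sigma_beta2: float = 0.0
    sigma_eps2: float = 0.0

    def __post_init__(self):
        self.K_g = np.asarray(self.K_g, dtype=float)
        self.K_e = np.asarray(self.K_e, dtype=float)
        self.K_g_beta = np.asarray(self.K_g_beta, dtype=float)
        self.K_e_eps = np.asarray(self.K_e_eps, dtype=float)
        for M, lab in ((self.K_g, "K_g"), (self.K_e, "K_e")):
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"{lab} must be a symmetric 2x2 matrix")

    def joint_genetic(self) -> np.ndarray:
        """3x3 covariance of (alpha0, alpha1, beta)."""
        G = np.zeros((3, 3))
        G[:2, :2] = self.K_g
        G[:2, 2] = G[2, :2] = self.K_g_beta
        G[2, 2] = self.sigma_beta2
        return G

    def joint_residual(self) -> np.ndarray:
        """3x3 covariance of (tau0, tau1, epsilon)."""
        E = np.zeros((3, 3))
        E[:2, :2] = self.K_e
        E[:2, 2] = E[2, :2] = self.K_e_eps
        E[2, 2] = self.sigma_eps2
        return E

    @classmethod
    def from_joint(cls, G: np.ndarray, E: np.ndarray) -> "RNMParams":
        G = np.asarray(G, dtype=float)
        E = np.asarray(E, dtype=float)
        return cls(
            K_g=G[:2, :2], K_e=E[:2, :2],
            K_g_beta=G[:2, 2], K_e_eps=E[:2, 2],
            sigma_beta2=float(G[2, 2]), sigma_eps2=float(E[2, 2]),
        )

    def validate_psd(self, tol: float = 1e-8) -> None:
        for M, lab in ((self.joint_genetic(), "joint genetic"),
                       (self.joint_residual(), "joint residual")):
            lam = np.linalg.eigvalsh(M)
            if lam[0] < -tol:
                raise ValueError(
                    f"{lab} covariance is not positive semi-definite "
                    f"(smallest eigenvalue {lam[0]:.3g})"
                )


@dataclass(frozen=True)
class ModelSpec:
    """Which components of the full MRNM are switched on.

    ``genetic_slope``  -- alpha1 present (GxE interaction variance)
    ``residual_slope`` -- tau1 present (RxE interaction variance)
    ``second_trait``   -- c* jointly modeled (G-E / R-E correlations)

    Every model in the comparison ladder is a flag combination; the free
    parameters are the unstructured covariances over the active component
    sets, so the counts are 2 / 4 / 4 / 6 (univariate family) and
    6 / 9 / 9 / 12 (bivariate family).
    """

    genetic_slope: bool = False
    residual_slope: bool = False
    second_trait: bool = False
    criterion: str = "REML"  # or "ML"

    @property
    def name(self) -> str:
        for nm, spec in MODEL_NAMES.items():
            if (spec.genetic_slope, spec.residual_slope, spec.second_trait) == (
                self.genetic_slope, self.residual_slope, self.second_trait
            ):
                return nm
        raise AssertionError("unreachable")

    @classmethod
    def from_name(cls, name: str, criterion: str = "REML") -> "ModelSpec":
        try:
            base = MODEL_NAMES[name]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; expected one of {sorted(MODEL_NAMES)}"
            ) from None
        return cls(base.genetic_slope, base.residual_slope, base.second_trait,
                   criterion=criterion)

    @property
    def active_genetic(self) -> tuple[int, ...]:
        idx = [0]
        if self.genetic_slope:
            idx.append(1)
        if self.second_trait:
            idx.append(2)
        return tuple(idx)

    @property
    def active_residual(self) -> tuple[int, ...]:
        idx = [0]
        if self.residual_slope:
            idx.append(1)
        if self.second_trait:
            idx.append(2)
        return tuple(idx)

    @property
    def n_free_params(self) -> int:
        kg, ke = len(self.active_genetic), len(self.active_residual)
        return kg * (kg + 1) // 2 + ke * (ke + 1) // 2

    @property
    def n_traits(self) -> int:
        return 2 if self.second_trait else 1

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.second_trait == other.second_trait
            and set(self.active_genetic) <= set(other.active_genetic)
            and set(self.active_residual) <= set(other.active_residual)
            and self.criterion == other.criterion
        )


MODEL_NAMES: dict[str, ModelSpec] = {
    "greml": ModelSpec(False, False, False),
    "urnm-gxe": ModelSpec(True, False, False),
    "urnm-rxe": ModelSpec(False, True, False),
    "urnm-full": ModelSpec(True, True, False),
    "bigreml": ModelSpec(False, False, True),
    "mrnm-gxe": ModelSpec(True, False, True),
    "mrnm-rxe": ModelSpec(False, True, True),
    "mrnm-full": ModelSpec(True, True, True),
}


def build_phi(c) -> np.ndarray:
    """n x 2 polynomial matrix with rows (1, c_i)."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate contains non-finite values")
    return np.column_stack([np.ones_like(c), c])


def component_loadings(c: np.ndarray, second_trait: bool) -> np.ndarray:
    """Loading vectors f_k of the stacked observations on the six components.

    Returns an (n_obs x 3) matrix whose columns are the loadings on
    (alpha0|tau0, alpha1|tau1, beta|eps): the y block loads (1, c_i, 0), the
    c* block loads (0, 0, 1).
    """
    n = len(c)
    if second_trait:
        F = np.zeros((2 * n, 3))
        F[:n, 0] = 1.0
        F[:n, 1] = c
        F[n:, 2] = 1.0
    else:
        F = np.zeros((n, 3))
        F[:, 0] = 1.0
        F[:, 1] = c
    return F


def tile_structures(A: np.ndarray, second_trait: bool) -> tuple[np.ndarray, np.ndarray]:
    """Relationship tilings: genetic blocks all A, residual blocks all I."""
    n = A.shape[0]
    if second_trait:
        return np.tile(A, (2, 2)), np.tile(np.eye(n), (2, 2))
    return A, np.eye(n)


def assemble_covariance(
    params: RNMParams,
    A: np.ndarray,
    c,
    spec: ModelSpec,
) -> np.ndarray:
    """Marginal covariance matrix of the stacked observations (y[, c*]).

    Size n x n without the second trait, 2n x 2n with it (y first).
    """
    c = np.asarray(c, dtype=float)
    A = np.asarray(A, dtype=float)
    G = np.zeros((3, 3))
    E = np.zeros((3, 3))
    ag, ae = spec.active_genetic, spec.active_residual
    G[np.ix_(ag, ag)] = params.joint_genetic()[np.ix_(ag, ag)]
    E[np.ix_(ae, ae)] = params.joint_residual()[np.ix_(ae, ae)]
    if not (np.all(np.isfinite(G)) and np.all(np.isfinite(E))):
        raise FloatingPointError("non-finite variance parameter")
    F = component_loadings(c, spec.second_trait)
    Tg, Te = tile_structures(A, spec.second_trait)
    V = (F @ G @ F.T) * Tg + (F @ E @ F.T) * Te
    return (V + V.T) / 2.0
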