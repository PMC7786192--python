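"""Synthetic data under the reaction-norm generative model.

The generator emulates a heat-stress G-by-E study design: n genotyped
animals with GRM-structured genetic effects, a continuous environmental
covariate (THI-like) that may itself carry a genetic component confounded
with the trait, and a single phenotype per animal built from zero- and
first-order random regressions on the standardized covariate with
heterogeneous residuals:

    y_i  = mu + alpha0_i + alpha1_i c_i + tau0_i + tau1_i c_i
    c*_i = beta_i + eps_i                      (adjusted covariate)
    raw_i = location_effect[subpop_i] + beta_i + eps_i

(alpha0, alpha1, beta) are drawn jointly from N(0, G3 (x) A) and
(tau0, tau1, eps) from N(0, E3 (x) I), where G3 and E3 are the 3x3 joint
covariances the fitted models try to recover.  Random effects are sampled
directly from the multivariate normal through factorizations of A, G3 and
E3, so the realized small-sample covariances are exact draws from the
target distribution rather than sums over per-SNP effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM, GenotypeMatrix, compute_grm, standardize
from .models import RNMParams
from .thi import standardize_covariate

__all__ = [
    "SimulationConfig",
    "TruthComponents",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_random_effects",
    "simulate_thi",
    "simulate_phenotype",
    "scenario",
    "SCENARIOS",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """All knobs of the generative model.

    Covariance entries live in trait-variance units; ``sigma_beta2`` and
    ``sigma_eps2`` are on the scale of the (unstandardized) covariate.
    """

    n_individuals: int = 500
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    K_g: np.ndarray = field(default_factory=lambda: np.diag([0.4, 0.0]))
    K_e: np.ndarray = field(default_factory=lambda: np.diag([0.6, 0.0]))
    K_g_beta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    K_e_eps: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sigma_beta2: float = 0.5
    sigma_eps2: float = 0.5
    location_effects: np.ndarray = field(default_factory=lambda: np.zeros(1))
    grand_mean: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.K_g = np.asarray(self.K_g, dtype=float)
        self.K_e = np.asarray(self.K_e, dtype=float)
        self.K_g_beta = np.asarray(self.K_g_beta, dtype=float)
        self.K_e_eps = np.asarray(self.K_e_eps, dtype=float)
        self.location_effects = np.asarray(self.location_effects, dtype=float)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.fst < 0 or self.fst >= 1:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_subpops == 1 and self.fst != 0.0:
            raise ValueError("fst must be 0 with a single subpopulation")
        for M, lab in ((self.joint_genetic(), "joint genetic"),
                       (self.joint_residual(), "joint residual")):
            lam = np.linalg.eigvalsh(M)
            if lam[0] < -1e-10:
                raise ValueError(
                    f"{lab} 3x3 covariance not PSD (eigenvalue {lam[0]:.3g})")

    def joint_genetic(self) -> np.ndarray:
        return self.params().joint_genetic()

    def joint_residual(self) -> np.ndarray:
        return self.params().joint_residual()

    def params(self) -> RNMParams:
        return RNMParams(
            K_g=self.K_g, K_e=self.K_e,
            K_g_beta=self.K_g_beta, K_e_eps=self.K_e_eps,
            sigma_beta2=self.sigma_beta2, sigma_eps2=self.sigma_eps2,
        )


@dataclass
class TruthComponents:
    alpha0: np.ndarray
    alpha1: np.ndarray
    beta: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    eps: np.ndarray
    config: SimulationConfig | None = None

    def genetic_value(self, c) -> np.ndarray:
        return self.alpha0 + self.alpha1 * np.asarray(c)


@dataclass
class GenotypeSimResult:
    genotypes: GenotypeMatrix
    subpop_labels: np.ndarray
    ancestral_freq: np.ndarray
    subpop_freq: np.ndarray       # (n_subpops, m)
    sample_freq: np.ndarray       # realized per-SNP allele frequency


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    grm: GRM
    subpop_labels: np.ndarray
    raw_thi: np.ndarray
    c: np.ndarray
    c_star: np.ndarray
    y: np.ndarray
    truth: TruthComponents

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config


def simulate_genotypes(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    n_subpops: int = 1,
    fst: float = 0.0,
    seed: int = 0,
) -> GenotypeSimResult:
    """Biallelic genotypes under a Balding-Nichols island model.

    Ancestral allele frequencies are uniform on ``maf_range``; with more
    than one subpopulation the per-subpopulation frequencies are
    Beta-distributed around the ancestral value with divergence ``fst``.
    Individuals are split evenly across subpopulations.
    """
    if n < 1 or m < 1:
        raise ValueError("need at least one individual and one SNP")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if fst < 0 or fst >= 1:
        raise ValueError("fst must lie in [0, 1)")
    if n_subpops == 1 and fst != 0.0:
        raise ValueError("fst must be 0 with a single subpopulation")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(lo, hi, size=m)
    labels = np.arange(n) % n_subpops
    if fst > 0:
        shape = (1.0 - fst) / fst
        p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape,
                         size=(n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    else:
        p_sub = np.tile(p_anc, (n_subpops, 1))
    calls = rng.binomial(2, p_sub[labels, :]).astype(float)
    g = GenotypeMatrix(
        animal_ids=np.array([f"ind{i:05d}" for i in range(n)]),
        snp_ids=np.array([f"snp{j:05d}" for j in range(m)]),
        calls=calls,
    )
    return GenotypeSimResult(
        genotypes=g,
        subpop_labels=labels,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
        sample_freq=calls.mean(axis=0) / 2.0,
    )


def _psd_factor(M: np.ndarray, label: str) -> np.ndarray:
    lam, vec = np.linalg.eigh(np.asarray(M, dtype=float))
    if lam[0] < -1e-10:
        raise ValueError(f"{label} covariance not PSD (eigenvalue {lam[0]:.3g})")
    return vec * np.sqrt(np.clip(lam, 0.0, None))


def simulate_random_effects(
    A: np.ndarray,
    config: SimulationConfig,
    seed: int = 0,
    jitter: float = 1e-8,
) -> TruthComponents:
    """Draw the six random-effect vectors.

    (alpha0, alpha1, beta) jointly from N(0, G3 (x) A) via Cholesky factors
    of A (jittered when rank-deficient, as it is whenever m < n) and the
    eigen-factor of G3; (tau0, tau1, eps) from N(0, E3 (x) I).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    Bg = _psd_factor(config.joint_genetic(), "joint genetic")
    Be = _psd_factor(config.joint_residual(), "joint residual")
    try:
        La = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        La = np.linalg.cholesky(A + jitter * np.eye(n))
    gen = La @ rng.standard_normal((n, 3)) @ Bg.T
    res = rng.standard_normal((n, 3)) @ Be.T
    return TruthComponents(
        alpha0=gen[:, 0], alpha1=gen[:, 1], beta=gen[:, 2],
        tau0=res[:, 0], tau1=res[:, 1], eps=res[:, 2],
        config=config,
    )


def simulate_thi(subpop_labels, location_effects, beta, eps):
    """Raw covariate, its z-score and its fixed-effect-adjusted form.

    raw = location_effect[subpop] + beta + eps;  c is the population-sd
    z-score of raw;  c* = beta + eps (raw with location effects removed).
    """
    labels = np.asarray(subpop_labels)
    loc = np.asarray(location_effects, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if not (len(labels) == len(beta) == len(eps)):
        raise ValueError("subpop labels and effect vectors must share length")
    raw = loc[labels] + beta + eps
    return raw, standardize_covariate(raw), beta + eps


def simulate_phenotype(config: SimulationConfig, truth: TruthComponents, c):
    """y = mu + alpha0 + alpha1 c + tau0 + tau1 c, exactly."""
    c = np.asarray(c, dtype=float)
    return (config.grand_mean + truth.alpha0 + truth.alpha1 * c
            + truth.tau0 + truth.tau1 * c)


def _dataset_from_config(config: SimulationConfig) -> SyntheticDataset:
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_eff = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    gsim = simulate_genotypes(
        config.n_individuals, config.n_snps, config.maf_range,
        config.n_subpops, config.fst, seed=s_geno,
    )
    # the GRM uses polymorphic SNPs only (small samples can fix an allele)
    poly = gsim.genotypes.calls.std(axis=0) > 0.0
    gpoly = GenotypeMatrix(
        animal_ids=gsim.genotypes.animal_ids,
        snp_ids=gsim.genotypes.snp_ids[poly],
        calls=gsim.genotypes.calls[:, poly],
    )
    grm = compute_grm(standardize(gpoly), gsim.genotypes.animal_ids)
    truth = simulate_random_effects(grm.A, config, seed=s_eff)
    raw, c, c_star = simulate_thi(
        gsim.subpop_labels, config.location_effects, truth.beta, truth.eps)
    y = simulate_phenotype(config, truth, c)
    return SyntheticDataset(
        genotypes=gsim.genotypes, grm=grm, subpop_labels=gsim.subpop_labels,
        raw_thi=raw, c=c, c_star=c_star, y=y, truth=truth,
    )


def _base(**kw) -> SimulationConfig:
    return SimulationConfig(**kw)


#: Named presets mirroring the alternative hypotheses of the model ladder.
#: Trait-side variances total 1.0 in the additive case (h2 = 0.4); slope
#: variances, when on, are 30% of the corresponding intercept variance.
SCENARIOS = {
    # no interaction, no trait-covariate correlation
    "null": dict(
        K_g=np.diag([0.4, 0.0]), K_e=np.diag([0.6, 0.0]),
    ),
    # genetic slope variance only
    "gxe": dict(
        K_g=np.array([[0.4, 0.06], [0.06, 0.12]]), K_e=np.diag([0.6, 0.0]),
    ),
    # residual slope variance only
    "rxe": dict(
        K_g=np.diag([0.4, 0.0]), K_e=np.array([[0.6, -0.06], [-0.06, 0.18]]),
    ),
    # both interactions plus genetic and residual trait-covariate covariances
    "combined": dict(
        K_g=np.array([[0.4, 0.1], [0.1, 0.2]]),
        K_e=np.array([[0.5, -0.05], [-0.05, 0.15]]),
        K_g_beta=np.array([0.1, 0.05]),
        K_e_eps=np.array([-0.05, 0.03]),
    ),
    # G-E correlation (0.3) with no interaction variance: the confounding
    # case in which unmodeled correlation produces spurious interaction
    "corr_only": dict(
        K_g=np.diag([0.4, 0.0]), K_e=np.diag([0.6, 0.0]),
        K_g_beta=np.array([0.3 * np.sqrt(0.4 * 0.5), 0.0]),
    ),
}


def scenario(name: str, n: int = 500, m: int = 1000, seed: int = 0,
             **overrides) -> SyntheticDataset:
    """Generate a named study condition.

    All presets use sigma_beta2 = sigma_eps2 = 0.5 for the covariate and a
    single unstructured population; see :data:`SCENARIOS` for the component
    settings each name switches on.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kw = dict(SCENARIOS[name])
    kw.update(overrides)
    config = _base(n_individuals=n, n_snps=m, seed=seed, **kw)
    return _dataset_from_config(config)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write genotypes, phenotype/covariate table, and truth as text files."""
    from pathlib import Path

    from .genotypes import write_plink_additive

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink_additive(ds.genotypes, outdir / "genotypes.tsv")
    pd.DataFrame({
        "animal_id": ds.genotypes.animal_ids,
        "y": ds.y, "raw_thi": ds.raw_thi, "c": ds.c, "c_star": ds.c_star,
        "subpop": ds.subpop_labels,
    }).to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    pd.DataFrame({
        "animal_id": ds.genotypes.animal_ids,
        "alpha0": ds.truth.alpha0, "alpha1": ds.truth.alpha1,
        "beta": ds.truth.beta, "tau0": ds.truth.tau0,
        "tau1": ds.truth.tau1, "eps": ds.truth.eps,
    }).to_csv(outdir / "truth.tsv", sep="\t", index=False)
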