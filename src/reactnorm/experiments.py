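"""Replication studies over synthetic datasets.

Thin drivers that repeat simulate-fit-compare cycles and collect the
quantities the package's calibration claims rest on: type-I error and power
of the ladder tests, parameter recovery of the variance components,
direction of the heritability bias under unmodeled interaction, and
invariance of the genetic variance.  Both the test suite and the
reproduction script call these, so the measured conditions are identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import heritability_summary, run_ladder
from .models import ModelSpec
from .reml import fit
from .simulate import scenario

__all__ = [
    "ladder_pvalues",
    "rejection_rate",
    "parameter_recovery",
    "heritability_bias",
    "genetic_variance_invariance",
]


def _spawn_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(k)]


def ladder_pvalues(
    scenario_name: str,
    n: int = 500,
    m: int = 1000,
    n_replicates: int = 200,
    rows=("M2", "M5"),
    seed: int = 0,
    criterion: str = "REML",
    boundary_correction: bool = False,
) -> pd.DataFrame:
    """P-values of the requested ladder rows over independent replicates."""
    records = []
    for rep, s in enumerate(_spawn_seeds(seed, n_replicates)):
        ds = scenario(scenario_name, n=n, m=m, seed=s)
        ladder = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=rows,
                            criterion=criterion, seed=s,
                            boundary_correction=boundary_correction)
        for row in ladder.rows:
            records.append(dict(replicate=rep, index=row.index,
                                statistic=row.statistic, p=row.p_value))
    return pd.DataFrame(records)


def rejection_rate(pvals: pd.DataFrame, row: str, alpha: float = 0.05) -> float:
    sub = pvals[pvals["index"] == row]
    return float((sub["p"] < alpha).mean())


def parameter_recovery(
    scenario_name: str = "combined",
    n: int = 500,
    m: int = 2000,
    n_replicates: int = 10,
    seed: int = 0,
    model: str = "mrnm-full",
) -> tuple[pd.DataFrame, dict]:
    """Fit the generating model to fresh replicates; collect estimates.

    Returns the per-replicate estimates (one column per free parameter) and
    the true values under the scenario's configuration.
    """
    spec = ModelSpec.from_name(model)
    rows = []
    truth = None
    for s in _spawn_seeds(seed, n_replicates):
        ds = scenario(scenario_name, n=n, m=m, seed=s)
        res = fit(spec, ds.y, ds.grm.A, ds.c, c_star=ds.c_star,
                  init=ds.config.params(), seed=s)
        rows.append(dict(zip(res.param_names, res.param_vector())))
        if truth is None:
            tparams = ds.config.params()
            from .reml import _params_to_vech  # vech order matches param_names

            truth = dict(zip(res.param_names, _params_to_vech(tparams, spec)))
    return pd.DataFrame(rows), truth


def heritability_bias(
    scenario_name: str,
    n: int = 500,
    m: int = 1000,
    n_replicates: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired heritabilities: additive null model vs interaction model.

    For each replicate fits the bivariate GREML (no interaction) and the
    full MRNM to the same data and records both average-variance h2 values.
    """
    rows = []
    for s in _spawn_seeds(seed, n_replicates):
        ds = scenario(scenario_name, n=n, m=m, seed=s)
        ladder = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=("M4",), seed=s)
        h_null = heritability_summary(ladder.fits["bigreml"], ds.c)
        h_full = heritability_summary(ladder.fits["mrnm-full"], ds.c)
        rows.append(dict(h2_null=h_null.h2, h2_interaction=h_full.h2,
                         ve_null=h_null.mean_residual_variance,
                         ve_interaction=h_full.mean_residual_variance))
    return pd.DataFrame(rows)


def genetic_variance_invariance(
    n: int = 500,
    m: int = 1000,
    n_replicates: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Average genetic variance, null vs interaction model, on null data."""
    rows = []
    for s in _spawn_seeds(seed, n_replicates):
        ds = scenario("null", n=n, m=m, seed=s)
        ladder = run_ladder(ds.y, ds.grm.A, ds.c, ds.c_star, rows=("M1",), seed=s)
        vg_null = heritability_summary(ladder.fits["greml"], ds.c)
        vg_int = heritability_summary(ladder.fits["urnm-full"], ds.c)
        rows.append(dict(vg_null=vg_null.mean_genetic_variance,
                         vg_interaction=vg_int.mean_genetic_variance))
    return pd.DataFrame(rows)
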