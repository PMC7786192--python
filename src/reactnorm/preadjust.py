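"""Phenotype filtering, fixed-effect model selection and pre-adjustment.

Variance-component models downstream expect phenotypes already cleared of
fixed effects.  This module implements that two-stage strategy: outlier and
small-group filtering on the raw records, AIC selection among a grid of
candidate fixed-effect models (with/without genomic PCs crossed with the
polynomial order of the environmental covariate), least-squares
residualization, and a rank-based inverse-normal transform (RINT).  The
environmental covariate itself is residualized on the non-THI fixed effects
to form the second-trait phenotype used by the multivariate reaction-norm
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FixedEffectsDesign",
    "filter_phenotypes",
    "candidate_models",
    "select_by_aic",
    "adjust",
    "rint",
    "adjust_covariate",
]


@dataclass
class FixedEffectsDesign:
    """A named least-squares design matrix.

    ``X`` always contains an intercept; categorical factors enter with the
    first level dropped so the matrix has full column rank.
    """

    name: str
    X: np.ndarray
    columns: list[str] = field(default_factory=list)
    has_pcs: bool = False
    thi_order: int = 0  # 0 none, 1 linear, 2 quadratic only, 3 linear+quadratic

    @property
    def k(self) -> int:
        """Number of mean parameters."""
        return self.X.shape[1]


def filter_phenotypes(
    records: pd.DataFrame,
    trait_cols,
    sd_bound: float = 3.0,
    min_group: int = 5,
    group_cols=("contemporary_group", "farm_location"),
    strict_greater: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Drop phenotypic outliers, then animals in undersized groups.

    Per trait, values outside mean +/- ``sd_bound`` sample standard
    deviations are removed (the whole record is dropped).  Afterwards,
    animals belonging to any grouping level with fewer than ``min_group``
    records are removed; with ``strict_greater`` a level must have strictly
    more than ``min_group`` records to survive.
    """
    report = {"n_in": len(records)}
    df = records.copy()
    for col in trait_cols:
        mu, sd = df[col].mean(), df[col].std()
        keep = (df[col] - mu).abs() <= sd_bound * sd
        report[f"outliers_removed_{col}"] = int((~keep).sum())
        df = df[keep]
    for gcol in group_cols:
        sizes = df[gcol].value_counts()
        ok = sizes.index[sizes > min_group] if strict_greater else sizes.index[sizes >= min_group]
        keep = df[gcol].isin(ok)
        report[f"small_group_removed_{gcol}"] = int((~keep).sum())
        df = df[keep]
    report["n_out"] = len(df)
    if len(df) == 0:
        binding = max((k for k in report if k.startswith(("outliers", "small"))),
                      key=report.get)
        raise ValueError(f"all records filtered out; binding filter: {binding}")
    return df.reset_index(drop=True), report


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype("category"), prefix=prefix, drop_first=True)
    return d.astype(float)


def build_design(
    records: pd.DataFrame,
    thi_order: int = 0,
    pcs: np.ndarray | None = None,
    thi_col: str = "raw_thi",
    name: str | None = None,
) -> FixedEffectsDesign:
    """Assemble intercept + sex + contemporary group + location + age
    [+ THI polynomial] [+ PCs]."""
    parts = [pd.DataFrame({"intercept": np.ones(len(records))})]
    for col, prefix in [("sex", "sex"), ("contemporary_group", "cg"),
                        ("farm_location", "loc")]:
        if col in records.columns:
            parts.append(_dummies(records[col], prefix).reset_index(drop=True))
    if "age" in records.columns:
        parts.append(pd.DataFrame({"age": records["age"].to_numpy(dtype=float)}))
    if thi_order in (1, 3):
        parts.append(pd.DataFrame({"thi": records[thi_col].to_numpy(dtype=float)}))
    if thi_order in (2, 3):
        parts.append(pd.DataFrame({"thi2": records[thi_col].to_numpy(dtype=float) ** 2}))
    if pcs is not None:
        parts.append(pd.DataFrame(
            {f"pc{i + 1}": pcs[:, i] for i in range(pcs.shape[1])}))
    X = pd.concat(parts, axis=1)
    if name is None:
        thi_names = {0: "no-thi", 1: "thi-linear", 2: "thi-quadratic", 3: "thi-lin+quad"}
        name = thi_names[thi_order] + ("+pcs" if pcs is not None else "")
    design = FixedEffectsDesign(
        name=name,
        X=X.to_numpy(dtype=float),
        columns=list(X.columns),
        has_pcs=pcs is not None,
        thi_order=thi_order,
    )
    if np.linalg.matrix_rank(design.X) < design.k:
        raise ValueError(f"design {name!r} is rank deficient")
    return design


def candidate_models(records: pd.DataFrame, pcs: np.ndarray,
                     thi_col: str = "raw_thi") -> list[FixedEffectsDesign]:
    """The 2x4 grid {without, with PCs} x {no THI, linear, quadratic, both}."""
    designs = []
    for use_pcs in (False, True):
        for order in (0, 1, 2, 3):
            designs.append(build_design(
                records, thi_order=order, pcs=pcs if use_pcs else None,
                thi_col=thi_col))
    return designs


def _ols_loglik(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def select_by_aic(y, designs) -> tuple[FixedEffectsDesign, pd.DataFrame]:
    """Gaussian OLS fit per design; lowest AIC = 2k - 2 logL wins.

    ``k`` counts the mean coefficients plus the residual variance.  Ties
    (within 1e-9) break toward fewer parameters.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for d in designs:
        if np.linalg.matrix_rank(d.X) < d.k:
            raise ValueError(f"design {d.name!r} rejected: rank deficient")
        ll = _ols_loglik(y, d.X)
        k = d.k + 1
        rows.append((d.name, k, ll, 2 * k - 2 * ll))
    table = pd.DataFrame(rows, columns=["model", "k", "logL", "AIC"])
    order = np.lexsort((table["k"].to_numpy(), np.round(table["AIC"].to_numpy(), 9)))
    best = designs[order[0]]
    table["selected"] = table["model"] == best.name
    return best, table


def adjust(y, design: FixedEffectsDesign) -> np.ndarray:
    """Least-squares residuals of y on the design (orthogonal to every column)."""
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    return y - design.X @ beta


def rint(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform.

    A value of rank r (average ranks for ties) maps to the standard-normal
    quantile of ``(r - offset) / n``.  The default offset 0.5 gives exactly
    symmetric quantiles; Blom's constant (3/8 with denominator n + 1/4) is
    available via ``offset='blom'``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot transform an empty vector")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed in rint()")
    r = stats.rankdata(x, method="average")
    if offset == "blom":
        u = (r - 3.0 / 8.0) / (len(x) + 0.25)
    else:
        u = (r - offset) / len(x)
    return stats.norm.ppf(u)


def adjust_covariate(raw_thi, design: FixedEffectsDesign) -> np.ndarray:
    """Residualize the raw covariate on the non-THI fixed effects, centered.

    The result is the 'adjusted THI' that serves as the second-trait
    phenotype in the multivariate reaction-norm model; the design must not
    itself contain THI terms.
    """
    if design.thi_order != 0:
        raise ValueError("covariate adjustment design must exclude THI terms")
    resid = adjust(raw_thi, design)
    return resid - resid.mean()
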