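"""Regression layer: OLS fits, variance-inflation screening, ANCOVA with
edaphic dummies plus a spatial filter, and climate/edaphic variance
partitioning.

The partition splits the explained variation of a diversity index Y into a
pure-climate fraction [a], a fraction shared between climate and substrate
[b], a pure-substrate fraction [c], and an unexplained remainder [d],
using three fits: R2(Y~X+W) = a+b+c, R2(Y~X) = a+b, R2(Y~W) = b+c, so
b = (a+b) + (b+c) - (a+b+c).  With the (default) Ezekiel-adjusted R2 the
fractions may come out slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spatial import EDAPHIC_CLASSES, SiteTable

__all__ = [
    "ModelFit",
    "VariancePartition",
    "ols_fit",
    "vif_screen",
    "edaphic_dummies",
    "ancova",
    "variance_partition",
    "RankDeficiencyError",
]


class RankDeficiencyError(ValueError):
    """Design matrix is not full column rank."""


@dataclass(frozen=True)
class ModelFit:
    """Summary of one least-squares fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    r2: float
    adj_r2: float
    n: int
    df_model: int
    significant: pd.Series | None = None  # p < alpha flags when requested

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coefficient": self.params,
            "se": self.bse,
            "t": self.tvalues,
            "p": self.pvalues,
        })
        if self.significant is not None:
            out["significant"] = self.significant
        return out


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name the offending columns: those whose removal restores rank
        base_rank = np.linalg.matrix_rank(M)
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == base_rank:
                bad.append(name)
        raise RankDeficiencyError(f"collinear design columns: {bad}")


def ols_fit(y: Sequence[float], X: pd.DataFrame, intercept: bool = True,
            alpha: float | None = None) -> ModelFit:
    """Ordinary least squares with named terms.

    t statistics and two-sided p-values use the residual-df t reference;
    adjusted R2 is Ezekiel's 1 - (1-R2)(n-1)/(n-p-1).  Passing ``alpha``
    adds per-coefficient significance flags.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).copy()
    if intercept:
        X.insert(0, "Intercept", 1.0)
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need n > number of terms ({X.shape[1]}), got n = {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    adj = float(res.rsquared_adj)
    flags = None
    if alpha is not None:
        flags = pd.Series(res.pvalues < alpha, index=X.columns)
    return ModelFit(
        params=res.params, bse=res.bse, tvalues=res.tvalues,
        pvalues=res.pvalues, residuals=np.asarray(res.resid),
        r2=r2, adj_r2=adj, n=len(y), df_model=int(res.df_model),
        significant=flags,
    )


def vif_screen(X: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    VIF_k = 1/(1 - R2_k) from regressing predictor k on the remaining
    predictors (with intercept); exact collinearity gives infinite VIF and is
    dropped first.  Returns (retained predictor names, drop/VIF log with one
    row per iteration-predictor pair).
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 predictors")
    zero_var = [c for c in X.columns if X[c].var() == 0]
    if zero_var:
        raise ValueError(f"zero-variance predictors: {zero_var}")
    kept = list(X.columns)
    log_rows = []
    iteration = 0
    while len(kept) >= 2:
        vifs = {}
        for col in kept:
            others = [c for c in kept if c != col]
            design = sm.add_constant(X[others])
            r2 = sm.OLS(X[col], design).fit().rsquared
            vifs[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda c: vifs[c])
        drop = vifs[worst] > threshold
        for col in kept:
            log_rows.append({"iteration": iteration, "predictor": col,
                             "vif": vifs[col],
                             "dropped": drop and col == worst})
        if not drop:
            break
        kept.remove(worst)
        iteration += 1
    return kept, pd.DataFrame(log_rows)


def edaphic_dummies(sites: SiteTable, reference: str = "sedimentary"
                    ) -> pd.DataFrame:
    """Treatment-coded substrate dummies with the given reference class.

    Column names are capitalized class names (e.g. Crystalline, Inselberg);
    classes absent from the table are simply omitted.
    """
    if reference not in EDAPHIC_CLASSES:
        raise ValueError(f"unknown reference class {reference!r}")
    sub = sites.table["substrate"]
    cols = {}
    for cls in EDAPHIC_CLASSES:
        if cls == reference or cls not in set(sub):
            continue
        cols[cls.capitalize()] = (sub == cls).astype(float)
    return pd.DataFrame(cols, index=sites.table.index)


def ancova(y: Sequence[float], sites: SiteTable, climate_terms: Sequence[str],
           spatial_filter: Sequence[float] | None = None,
           reference_class: str = "sedimentary", alpha: float = 0.10
           ) -> ModelFit:
    """ANCOVA of a diversity index on climate covariates with substrate as a
    categorical covariate and one PCNM spatial filter.

    Design: intercept + climate terms + treatment-coded edaphic dummies
    (reference class omitted) + the spatial filter.  Coefficients with
    p < alpha are flagged.
    """
    X = sites.table[list(climate_terms)].astype(float).copy()
    dummies = edaphic_dummies(sites, reference=reference_class)
    if dummies.shape[1] == 0:
        raise ValueError("need at least 2 edaphic classes represented")
    X = pd.concat([X, dummies], axis=1)
    if spatial_filter is not None:
        X["Spatial Filter"] = np.asarray(spatial_filter, dtype=float)
    return ols_fit(y, X, intercept=True, alpha=alpha)


@dataclass(frozen=True)
class VariancePartition:
    """Fractions of variation: pure climate [a], shared [b], pure edaphic
    [c], unexplained [d]."""

    climate: float          # a
    shared: float           # b
    edaphic: float          # c
    unexplained: float      # d
    r2_full: float          # a + b + c, in the chosen R2 flavour
    r2_flavour: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"climate": self.climate, "edaphic": self.edaphic,
              "interaction": self.shared, "r2_full": self.r2_full,
              "unexplained": self.unexplained,
              "r2_flavour": self.r2_flavour}]
        )


def variance_partition(y: Sequence[float], X: pd.DataFrame, W: pd.DataFrame,
                       r2_flavour: Literal["raw", "adjusted"] = "adjusted"
                       ) -> VariancePartition:
    """Partition explained variation of y between predictor blocks X
    (climate) and W (edaphic dummies).

    Three fits give R2(Y~X+W) = a+b+c, R2(Y~X) = a+b and R2(Y~W) = b+c;
    the shared fraction is b = (a+b) + (b+c) - (a+b+c) and d = 1-(a+b+c).

    Redundancy *between* the blocks (e.g. W a linear image of X) is allowed
    and simply shows up as shared variation: the combined fit uses a
    minimum-norm least-squares solution with the effective design rank.
    """
    X = pd.DataFrame(X)
    W = pd.DataFrame(W)
    both = pd.concat([X, W], axis=1)
    y = np.asarray(y, dtype=float)

    def r2(design: pd.DataFrame) -> float:
        M = np.column_stack([np.ones(len(y)), design.to_numpy(dtype=float)])
        beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        tss = ((y - y.mean()) ** 2).sum()
        raw = 1.0 - (resid ** 2).sum() / tss
        if r2_flavour == "raw":
            return float(raw)
        p = rank - 1  # predictors actually spanning the fit
        return float(1.0 - (1.0 - raw) * (len(y) - 1) / (len(y) - p - 1))

    abc = r2(both)
    ab = r2(X)
    bc = r2(W)
    b = ab + bc - abc
    a = ab - b
    c = bc - b
    return VariancePartition(climate=a, shared=b, edaphic=c,
                             unexplained=1.0 - abc, r2_full=abc,
                             r2_flavour=r2_flavour)
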