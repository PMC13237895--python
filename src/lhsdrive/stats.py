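"""Results-style analytics over simulated project tables.

Covers the three reporting blocks used to characterize a simulated
cohort: the Pearson correlation structure among velocities, efficiency
indices and economics; Kruskal-Wallis comparisons of CTI/TEI/ROI
across LHS typology states (medians and IQRs per state); and the
global multivariate ROI model, an ordinary least-squares fit of ROI on
CTI, TEI and the mission-weighted mean velocity with adjusted R^2 and
variance inflation factors.

A caution that belongs with the regression: the marginal association
of CTI with ROI is strongly positive, but its fitted coefficient
conditional on TEI and Vmean can be negative because those mediators
carry most of the CTI signal.  That sign is a conditioning artifact,
not a causal claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import ValidationError


@dataclass
class RoiModelFit:
    """OLS fit of ROI on CTI, TEI and mean velocity."""

    params: dict[str, float]
    adj_r2: float
    r2: float
    vif: dict[str, float]
    n: int
    pvalues: dict[str, float]

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.params["const"])
        for name, b in self.params.items():
            if name != "const":
                out = out + b * df[name].to_numpy()
        return out


@dataclass
class GroupComparison:
    """Per-state medians/IQRs plus the Kruskal-Wallis rank test."""

    statistic: str
    table: pd.DataFrame  # index: state; columns: n, median, q25, q75
    h: float
    pvalue: float


def correlation_matrix(df: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix over the requested columns.

    Zero-variance variables yield NaN rows/columns (flagged undefined)
    rather than an arbitrary zero.
    """
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValidationError(f"unknown variables {missing}")
    if len(df) < 3:
        raise ValidationError("correlation matrix needs at least 3 records")
    sub = df[variables].astype(float)
    if not np.isfinite(sub.to_numpy()).all():
        raise ValidationError("non-finite values in correlation input")
    return sub.corr(method="pearson")


def compare_states(df: pd.DataFrame, statistic: str,
                   group_col: str = "state") -> GroupComparison:
    """Compare a statistic across LHS states with a Kruskal-Wallis test.

    Reports each state's n, median and (25th, 75th) percentiles; the H
    statistic uses the standard tie correction and the chi-square
    approximation for the p-value.
    """
    if statistic not in df.columns:
        raise ValidationError(f"unknown statistic column {statistic!r}")
    groups = [g[statistic].to_numpy(dtype=float)
              for _, g in df.groupby(group_col) if len(g)]
    if len(groups) < 2:
        raise ValidationError("state comparison needs at least 2 nonempty groups")
    h, p = sps.kruskal(*groups)
    table = df.groupby(group_col)[statistic].agg(
        n="count", median="median",
        q25=lambda x: float(np.percentile(x, 25)),
        q75=lambda x: float(np.percentile(x, 75)),
    )
    return GroupComparison(statistic=statistic, table=table,
                           h=float(h), pvalue=float(p))


def fit_roi_model(df: pd.DataFrame, response: str = "roi",
                  predictors: tuple[str, ...] = ("cti", "tei", "v_mean")
                  ) -> RoiModelFit:
    """Ordinary least-squares fit of ROI on CTI, TEI and mean velocity.

    Rejects perfectly collinear predictor sets, naming the offending
    columns.  VIFs are computed per predictor against the others (with
    intercept); an orthogonal predictor set has VIF 1.
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"unknown columns {missing}")
    if len(df) <= 10:
        raise ValidationError("ROI model needs more than 10 records")
    X = df[list(predictors)].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [(predictors[i], predictors[j])
                 for i in range(len(predictors)) for j in range(i + 1, len(predictors))
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValidationError(f"perfectly collinear predictors: {pairs or list(predictors)}")
    fit = sm.OLS(y, exog).fit()
    names = ["const", *predictors]
    vif = {predictors[j]: float(variance_inflation_factor(exog, j + 1))
           for j in range(len(predictors))}
    return RoiModelFit(
        params=dict(zip(names, map(float, fit.params))),
        adj_r2=float(fit.rsquared_adj), r2=float(fit.rsquared),
        vif=vif, n=int(fit.nobs),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
    )
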