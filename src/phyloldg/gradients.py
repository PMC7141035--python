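"""Latitudinal gradient fits and bivariate variance-explained tables.

Richness and MRD are regressed on latitude with linear or quadratic OLS; a
concave quadratic fit yields a peak latitude at the vertex -b/(2a). The
bivariate table reports, for every predictor x response pair, the percentage
of variance explained by a single-predictor OLS with a significance code
(ns / ' / * / ** / ***), flagging the top three predictors per response.

Richness responses are natural-log transformed (richness-area relations are
power functions); reserve area enters models as ln(AREA) for the same
reason. MRD responses are modeled untransformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: significance codes: p >= .1 'ns', < .1 "'", < .05 '*', < .01 '**', < .001 '***'
SIG_THRESHOLDS = [(0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "'")]


def significance_code(p: float) -> str:
    for threshold, code in SIG_THRESHOLDS:
        if p < threshold:
            return code
    return "ns"


@dataclass(frozen=True)
class GradientFit:
    """Result of an OLS fit of a response against latitude (or any predictor)."""

    response: str
    predictor: str
    shape: str                 # "linear" | "quadratic"
    intercept: float
    b: float                   # linear coefficient
    a: float                   # quadratic coefficient (0.0 for linear fits)
    r2: float
    p_value: float             # overall model F-test
    n: int
    x_range: tuple[float, float]
    coef_p_values: tuple[float, ...] = ()

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.shape == "quadratic":
            return (self.intercept, self.b, self.a)
        return (self.intercept, self.b)


def fit_latitudinal(y: Sequence[float], lat: Sequence[float], shape: str = "linear",
                    response: str = "y", predictor: str = "lat",
                    log_y: bool = False) -> GradientFit:
    """OLS fit of ``y`` on latitude, linear or quadratic.

    With ``log_y`` the response is ln-transformed first; nonpositive values
    are dropped with a logged count (presence-only richness lists can yield
    zero counts for a group). The model p-value is the F-test of the full
    model against the intercept-only model.
    """
    if shape not in ("linear", "quadratic"):
        raise ValueError("shape must be 'linear' or 'quadratic'")
    y = np.asarray(y, dtype=float)
    x = np.asarray(lat, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    if log_y:
        positive = y > 0
        n_dropped = int((keep & ~positive).sum())
        if n_dropped:
            logger.info("dropping %d nonpositive responses before log transform", n_dropped)
        keep &= positive
    y, x = y[keep], x[keep]
    if log_y:
        y = np.log(y)
    n_min = 3 if shape == "linear" else 4
    if len(y) < n_min:
        raise ValueError(f"need at least {n_min} observations for a {shape} fit")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    if np.ptp(y) == 0 and shape == "quadratic":
        # constant response: quadratic design is fine, fall through
        pass
    X = np.column_stack([x, x ** 2]) if shape == "quadratic" else x[:, None]
    model = sm.OLS(y, sm.add_constant(X)).fit()
    params = model.params
    a = float(params[2]) if shape == "quadratic" else 0.0
    p = float(model.f_pvalue)
    if math.isnan(p):  # zero-variance response: no relationship
        p = 1.0
    return GradientFit(
        response=response, predictor=predictor, shape=shape,
        intercept=float(params[0]), b=float(params[1]), a=a,
        r2=float(model.rsquared) if np.ptp(y) > 0 else 0.0,
        p_value=p, n=int(model.nobs),
        x_range=(float(x.min()), float(x.max())),
        coef_p_values=tuple(float(v) for v in model.pvalues),
    )


def peak_latitude(fit: GradientFit) -> tuple[float | None, str]:
    """Vertex of a concave quadratic fit, if it lies inside the data range.

    Returns ``(peak, reason)``; ``peak`` is None when the fitted parabola is
    degenerate (a = 0), opens upward (a > 0), or peaks outside the observed
    latitude span.
    """
    if fit.shape != "quadratic":
        raise ValueError("peak_latitude requires a quadratic fit")
    if fit.a == 0:
        return None, "degenerate quadratic"
    if fit.a > 0:
        return None, "upward parabola (minimum, not peak)"
    vertex = -fit.b / (2.0 * fit.a)
    lo, hi = fit.x_range
    if not (lo <= vertex <= hi):
        return None, f"vertex {vertex:.2f} outside data range [{lo:.2f}, {hi:.2f}]"
    return float(vertex), "ok"


@dataclass(frozen=True)
class BivariateCell:
    pct_variance: float | None   # 100 * R^2, None if unavailable
    p_value: float | None
    code: str                    # significance code or "na"
    top3: bool = False


@dataclass(frozen=True)
class BivariateTable:
    """Predictors x responses matrix of single-predictor variance explained."""

    predictors: tuple[str, ...]
    responses: tuple[str, ...]
    cells: Mapping[tuple[str, str], BivariateCell]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per predictor x response."""
        rows = []
        for pred in self.predictors:
            for resp in self.responses:
                c = self.cells[(pred, resp)]
                rows.append({
                    "predictor": pred, "response": resp,
                    "pct_variance": c.pct_variance, "p_value": c.p_value,
                    "code": c.code, "top3": c.top3,
                })
        return pd.DataFrame(rows)

    def to_matrix(self) -> pd.DataFrame:
        """Wide predictors-by-responses matrix of formatted cells."""
        data = {}
        for resp in self.responses:
            col = []
            for pred in self.predictors:
                c = self.cells[(pred, resp)]
                if c.pct_variance is None:
                    col.append("")
                else:
                    col.append(f"{c.pct_variance:.1f}{c.code if c.code != 'ns' else ''}")
            data[resp] = col
        return pd.DataFrame(data, index=list(self.predictors))


def bivariate_table(covariates: pd.DataFrame,
                    responses: Mapping[str, Sequence[float]],
                    predictors: Sequence[str] | None = None,
                    log_responses: Sequence[str] = ()) -> BivariateTable:
    """Single-predictor OLS table: 100*R^2 with significance codes.

    ``covariates`` must carry one row per reserve. Responses named in
    ``log_responses`` (richness counts) are ln-transformed, dropping zero
    counts. A column ``LN_AREA`` is derived from ``AREA`` on the fly when
    requested among predictors. Cells with fewer than 3 complete cases are
    marked unavailable. The three largest R^2 per response are flagged.
    """
    from .covariates import MODELED_PREDICTORS
    if predictors is None:
        predictors = [p for p in MODELED_PREDICTORS
                      if p in covariates.columns or
                      (p == "LN_AREA" and "AREA" in covariates.columns)]
    cov = covariates.copy()
    if "LN_AREA" in predictors and "LN_AREA" not in cov.columns:
        cov["LN_AREA"] = np.log(cov["AREA"].astype(float))
    cells: dict[tuple[str, str], BivariateCell] = {}
    log_set = set(log_responses)
    for resp_name, resp_values in responses.items():
        scored: list[tuple[str, float, float]] = []
        for pred in predictors:
            x = cov[pred].to_numpy(dtype=float) if pred in cov.columns else None
            if x is None or not np.isfinite(x).any():
                cells[(pred, resp_name)] = BivariateCell(None, None, "na")
                continue
            y = np.asarray(resp_values, dtype=float)
            try:
                fit = fit_latitudinal(y, x, "linear", response=resp_name,
                                      predictor=pred, log_y=resp_name in log_set)
            except ValueError:
                cells[(pred, resp_name)] = BivariateCell(None, None, "na")
                continue
            cells[(pred, resp_name)] = BivariateCell(
                100.0 * fit.r2, fit.p_value, significance_code(fit.p_value))
            scored.append((pred, 100.0 * fit.r2, fit.p_value))
        for pred, pct, p in sorted(scored, key=lambda t: -t[1])[:3]:
            c = cells[(pred, resp_name)]
            cells[(pred, resp_name)] = BivariateCell(c.pct_variance, c.p_value,
                                                     c.code, top3=True)
    return BivariateTable(predictors=tuple(predictors),
                          responses=tuple(responses.keys()), cells=cells)
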