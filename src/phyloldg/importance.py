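"""Multivariate variable-importance stage.

Pipeline: (1) backward elimination of candidate predictors on an OLS model
by AIC; (2) iterative removal of the largest variance inflation factor (VIF)
until all VIF <= 10; (3) a bootstrap regression forest (default 200 trees)
whose out-of-bag (OOB) permutation importances, floored at zero and divided
by the maximum, give normalized importances in (0, 1]; (4) Moran's I of the
forest's OOB residuals across equal-count great-circle distance classes,
with permutation p-values, to check that residuals carry no spatial
autocorrelation that would bias the importance ranking.

All randomness (bootstraps, tree construction, permutations) is governed by
the seed recorded in the report; ties are broken by predictor declaration
order throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics.pairwise import haversine_distances
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
VIF_THRESHOLD = 10.0


@dataclass
class ModelSpec:
    """Configuration of one importance-stage model."""

    response: str
    predictors: tuple[str, ...]
    log_response: bool = False
    seed: int = 0
    n_trees: int = 200
    vif_threshold: float = VIF_THRESHOLD
    prune_order: str = "aic-then-vif"   # or "vif-then-aic"
    moran_classes: int = 10
    moran_permutations: int = 999

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("candidate predictors must be nonempty")
        self.predictors = tuple(self.predictors)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1/(1 - R^2_j).

    R^2_j comes from regressing predictor j on all other predictors (with
    intercept). Perfect collinearity yields ``inf``. Constant columns are
    rejected by name.
    """
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("VIF needs more observations than predictors + 1")
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"constant column {col!r}")
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    mat = sm.add_constant(X.to_numpy(), has_constant="add")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect collinearity -> divide-by-zero
        for j, col in enumerate(X.columns):
            v = variance_inflation_factor(mat, j + 1)
            # numerically perfect collinearity can surface as a huge finite value
            out[col] = float("inf") if (not np.isfinite(v) or v > 1e12) else float(v)
    return pd.Series(out)


@dataclass(frozen=True)
class PruneLog:
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...]   # (name, "AIC" | "VIF")


def _ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    return float(sm.OLS(y, sm.add_constant(X, has_constant="add")).fit().aic)


def prune_predictors(data: pd.DataFrame, spec: ModelSpec) -> PruneLog:
    """Drop predictors by backward AIC elimination, then by VIF > threshold.

    Stage order is switchable via ``spec.prune_order``. Deterministic: at
    each AIC step the removal giving the lowest AIC wins, ties broken by
    declaration order; the VIF stage removes the largest VIF first.
    """
    y, X = _design(data, spec)
    if len(y) < len(spec.predictors) + 2:
        raise ValueError("fewer complete cases than predictors + 2")
    if len(y) < 10:
        raise ValueError("need at least 10 complete cases")
    stages = (("AIC", "VIF") if spec.prune_order == "aic-then-vif"
              else ("VIF", "AIC"))
    retained = list(spec.predictors)
    dropped: list[tuple[str, str]] = []

    def aic_stage():
        nonlocal retained
        current = _ols_aic(y, X[retained].to_numpy())
        while len(retained) > 1:
            best_aic, best_drop = current, None
            for name in retained:
                trial = [p for p in retained if p != name]
                a = _ols_aic(y, X[trial].to_numpy())
                if a < best_aic - 1e-12:
                    best_aic, best_drop = a, name
            if best_drop is None:
                break
            retained.remove(best_drop)
            dropped.append((best_drop, "AIC"))
            current = best_aic

    def vif_stage():
        nonlocal retained
        while len(retained) >= 2:
            v = vif(X[retained])
            worst = v.idxmax()  # first occurrence wins ties (declaration order)
            if v[worst] <= spec.vif_threshold:
                break
            retained.remove(worst)
            dropped.append((worst, "VIF"))

    for stage in stages:
        if stage == "AIC":
            aic_stage()
        else:
            vif_stage()
    return PruneLog(retained=tuple(retained), dropped=tuple(dropped))


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Complete-case response vector and predictor frame with transforms."""
    missing = [p for p in spec.predictors if p not in data.columns]
    if missing:
        raise KeyError(f"predictors absent from data: {missing}")
    if spec.response not in data.columns:
        raise KeyError(f"response {spec.response!r} absent from data")
    df = data[[spec.response, *spec.predictors]].astype(float)
    y = df[spec.response].to_numpy()
    if spec.log_response:
        df = df[y > 0]
        y = np.log(df[spec.response].to_numpy())
    keep = np.isfinite(y) & np.isfinite(df[list(spec.predictors)].to_numpy()).all(axis=1)
    df = df[keep]
    y = y[keep]
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    return y, df[list(spec.predictors)]


@dataclass(frozen=True)
class ForestResult:
    importance: pd.Series          # normalized, max = 1
    raw_importance: pd.Series      # mean OOB permutation MSE increase
    oob_residuals: np.ndarray
    oob_prediction: np.ndarray
    seed: int


def rf_importance(data: pd.DataFrame, retained: Sequence[str],
                  spec: ModelSpec) -> ForestResult:
    """Bootstrap regression forest with OOB permutation importance.

    Each of ``spec.n_trees`` trees is fit on a bootstrap resample; for every
    tree, each retained predictor is permuted over that tree's out-of-bag
    rows and the increase in OOB mean-squared error is recorded. Importances
    are averaged over trees, floored at 0, and normalized by the maximum so
    the top predictor scores exactly 1. OOB residuals (observed minus mean
    OOB prediction) are returned for spatial diagnostics.
    """
    if not retained:
        raise ValueError("retained predictor set is empty")
    sub = ModelSpec(response=spec.response, predictors=tuple(retained),
                    log_response=spec.log_response, seed=spec.seed,
                    n_trees=spec.n_trees)
    y, X = _design(data, sub)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    Xm = X.to_numpy()
    p = Xm.shape[1]
    # leakage canary: a predictor identical to the (transformed) response
    for j, name in enumerate(retained):
        if np.ptp(Xm[:, j] - y) == 0:
            warnings.warn(f"predictor {name!r} is identical to the response "
                          "(leakage); its importance will be ~1.0", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    raw = np.zeros(p)
    n_used = np.zeros(p)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    max_features = max(1, p // 3)  # regression-forest convention: p/3
    for t in range(spec.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(Xm[oob])
        oob_sum[oob] += pred
        oob_count[oob] += 1
        base_mse = np.mean((y[oob] - pred) ** 2)
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xperm = Xm[oob].copy()
            Xperm[:, j] = Xperm[perm, j]
            perm_mse = np.mean((y[oob] - tree.predict(Xperm)) ** 2)
            raw[j] += perm_mse - base_mse
            n_used[j] += 1
    raw = np.where(n_used > 0, raw / np.maximum(n_used, 1), 0.0)
    floored = np.clip(raw, 0.0, None)
    top = floored.max()
    if top <= 0:
        raise ValueError("all permutation importances nonpositive; "
                         "forest explains nothing")
    norm = floored / top
    never_oob = oob_count == 0
    if never_oob.any():
        logger.warning("%d rows never out-of-bag; OOB residual set to 0 there",
                       int(never_oob.sum()))
    oob_pred = np.where(oob_count > 0, oob_sum / np.maximum(oob_count, 1), y)
    return ForestResult(
        importance=pd.Series(norm, index=list(retained)),
        raw_importance=pd.Series(raw, index=list(retained)),
        oob_residuals=y - oob_pred,
        oob_prediction=oob_pred,
        seed=spec.seed,
    )


# -- Moran's I ----------------------------------------------------------------

@dataclass(frozen=True)
class MoranClass:
    k: int
    d_lo: float                 # km
    d_hi: float
    n_pairs: int
    I: float | None
    p_value: float | None
    empty: bool = False


def _great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from (lon, lat) degree pairs."""
    latlon_rad = np.radians(coords[:, [1, 0]])
    return haversine_distances(latlon_rad) * EARTH_RADIUS_KM


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    """Moran's I for centered values z and a binary symmetric weight matrix."""
    n = len(z)
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i(values: Sequence[float], coords: Sequence[tuple[float, float]],
             n_classes: int = 10, n_perm: int = 999,
             seed: int = 0) -> list[MoranClass]:
    """Moran's I per great-circle distance class, with permutation p-values.

    ``coords`` are (lon, lat) in decimal degrees. Pairs are binned into
    ``n_classes`` classes with approximately equal pair counts (quantiles of
    the pairwise distance distribution). Within class k, with binary weights
    w_ij = 1 iff the pair's distance falls in the class,

        I_k = (n / sum(w)) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),

    where z are mean-centered values. The two-sided p-value compares
    |I - E[I]| (E[I] = -1/(n-1)) against ``n_perm`` seeded random
    permutations of the values over the locations.
    """
    v = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(v)
    if n < 10:
        raise ValueError("need at least 10 locations")
    if np.ptp(v) == 0:
        raise ValueError("values are constant")
    dist = _great_circle_km(xy)
    iu, ju = np.triu_indices(n, k=1)
    dvals = dist[iu, ju]
    edges = np.quantile(dvals, np.linspace(0, 1, n_classes + 1))
    edges[-1] = np.inf
    z = v - v.mean()
    denom = float(z @ z)
    expectation = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    out: list[MoranClass] = []
    for k in range(n_classes):
        in_class = (dvals >= edges[k]) & (dvals < edges[k + 1])
        if k == 0:
            in_class |= dvals == edges[0]
        n_pairs = int(in_class.sum())
        hi = float(dvals.max()) if not np.isfinite(edges[k + 1]) else float(edges[k + 1])
        if n_pairs == 0:
            out.append(MoranClass(k, float(edges[k]), hi, 0, None, None, empty=True))
            continue
        w = np.zeros((n, n))
        w[iu[in_class], ju[in_class]] = 1.0
        w += w.T
        i_obs = _moran_stat(z, w)
        zp = z[perms]                                   # (n_perm, n)
        i_perm = (n / w.sum()) * np.einsum("pi,ij,pj->p", zp, w, zp) / denom
        extreme = np.abs(i_perm - expectation) >= abs(i_obs - expectation) - 1e-15
        p = (1 + int(extreme.sum())) / (n_perm + 1)
        out.append(MoranClass(k, float(edges[k]), hi, n_pairs, i_obs, float(p)))
    return out


@dataclass(frozen=True)
class ImportanceReport:
    """Full record of one pruning + forest + residual-diagnostics run."""

    response: str
    retained: tuple[str, ...]
    importance: Mapping[str, float]
    dropped: tuple[tuple[str, str], ...]
    moran: tuple[MoranClass, ...]
    residuals_spatially_independent: bool
    seed: int
    n: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "retained": list(self.retained),
            "importance": {k: float(v) for k, v in self.importance.items()},
            "dropped": [{"predictor": nm, "reason": why} for nm, why in self.dropped],
            "moran": [
                {"class": m.k, "d_lo_km": m.d_lo, "d_hi_km": m.d_hi,
                 "n_pairs": m.n_pairs, "I": m.I, "p": m.p_value, "empty": m.empty}
                for m in self.moran
            ],
            "residuals_spatially_independent": self.residuals_spatially_independent,
            "seed": self.seed,
            "n": self.n,
        }


def run_importance_stage(data: pd.DataFrame, spec: ModelSpec,
                         coords: Sequence[tuple[float, float]] | None = None
                         ) -> ImportanceReport:
    """Compose pruning, random-forest importance, and residual Moran's I.

    ``coords`` ((lon, lat) per row of ``data``) default to columns
    ``lon``/``lat`` when present. The independence flag is set when no
    distance class has a permutation p-value below 0.05.
    """
    prune = prune_predictors(data, spec)
    forest = rf_importance(data, prune.retained, spec)
    if coords is None and {"lon", "lat"}.issubset(data.columns):
        y, X = _design(data, ModelSpec(response=spec.response,
                                       predictors=prune.retained,
                                       log_response=spec.log_response,
                                       seed=spec.seed))
        idx = X.index
        coords = data.loc[idx, ["lon", "lat"]].to_numpy()
    moran_classes: tuple[MoranClass, ...] = ()
    independent = True
    if coords is not None:
        mres = morans_i(forest.oob_residuals, coords,
                        n_classes=spec.moran_classes,
                        n_perm=spec.moran_permutations, seed=spec.seed)
        moran_classes = tuple(mres)
        independent = all(m.empty or m.p_value >= 0.05 for m in mres)
    return ImportanceReport(
        response=spec.response,
        retained=prune.retained,
        importance=dict(forest.importance),
        dropped=prune.dropped,
        moran=moran_classes,
        residuals_spatially_independent=independent,
        seed=spec.seed,
        n=len(forest.oob_residuals),
    )
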