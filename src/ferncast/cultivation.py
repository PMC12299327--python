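"""Suitability-productivity cultivation model and zoning.

Site productivity combines habitat suitability S with an entropy-weighted
nutrition index N (P = S + N; by default rescaled to (S + N) / 2 so P stays
in [0, 1] and the fixed zoning thresholds remain meaningful). The P ~ S
relation is then fitted with seven canonical trendline forms, the winner is
chosen by AIC with a parsimony tie-break (candidates within dAIC < 2 of the
minimum: fewest parameters wins), and the fitted relation projects P — and
hence cultivation zones — across the suitability raster, where no nutrition
data exist.

Zoning: core where P > 0.58, general where 0.37 <= P <= 0.58, marginal where
P < 0.37, all within suitable habitat only; unsuitable cells carry no zone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import SuitabilityMap

ZONE_CODES = {"unsuitable": 0, "marginal": 1, "general": 2, "core": 3}
CORE_MIN = 0.58  # zone thresholds on predicted productivity
GENERAL_MIN = 0.37


# ---------------------------------------------------------------------------
# entropy-weighted nutrition index


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each indicator column to [0, 1] (order-preserving).

    Constant columns become all-zeros with a warning; the entropy weight of a
    constant indicator is zero anyway.
    """
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            warnings.warn(f"indicator '{col}' is constant; standardized to zeros")
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


def entropy_weights(X_norm: pd.DataFrame, eps: float = 1e-12) -> pd.Series:
    """Entropy-method indicator weights.

    p_ij = x_ij / sum_i x_ij (zeros shifted by eps), e_j = -(1/ln n) sum p ln p,
    d_j = 1 - e_j, w_j = d_j / sum d. Indicators with more dispersion (lower
    entropy) get larger weights; constant indicators get weight 0.
    """
    X = pd.DataFrame(X_norm).to_numpy(dtype=float)
    n, k = X.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 sites")
    if (X < 0).any():
        raise ValueError("entries must be non-negative")
    Xs = np.where(X > 0, X, eps)
    p = Xs / Xs.sum(axis=0, keepdims=True)
    e = -(p * np.log(p)).sum(axis=0) / np.log(n)
    d = np.clip(1.0 - e, 0.0, None)
    d[d < 1e-10] = 0.0  # constant columns: entropy = 1 up to log round-off
    if d.sum() <= 0:
        raise ValueError("all indicators are constant; weights are undefined")
    return pd.Series(d / d.sum(), index=pd.DataFrame(X_norm).columns)


def nutrition_index(X_norm: pd.DataFrame, weights: pd.Series) -> np.ndarray:
    """Weighted standardized sum N = sum_i w_i * x_i^norm per site."""
    X = pd.DataFrame(X_norm)
    w = pd.Series(weights).reindex(X.columns)
    if w.isna().any():
        raise ValueError("weights must cover every indicator column")
    return X.to_numpy(dtype=float) @ w.to_numpy(dtype=float)


def site_productivity(S: np.ndarray, N: np.ndarray, rescale: bool = True) -> np.ndarray:
    """P = S + N; with rescale=True returns (S + N) / 2 so P stays in [0, 1]."""
    S = np.asarray(S, dtype=float)
    N = np.asarray(N, dtype=float)
    if S.shape != N.shape:
        raise ValueError("S and N must be aligned site vectors")
    P = S + N
    return P / 2.0 if rescale else P


# ---------------------------------------------------------------------------
# candidate trendline forms


@dataclass
class Candidate:
    name: str
    n_params: int
    func: callable
    p0: list[float]
    needs_positive_x: bool = False


def _registry() -> list[Candidate]:
    return [
        Candidate("line2P", 2, lambda x, a, b: a * x + b, [1.0, 0.0]),
        Candidate("line3P", 3, lambda x, a, b, c: a * x**2 + b * x + c, [0.0, 1.0, 0.0]),
        Candidate("log2P", 2, lambda x, a, b: a * np.log(x) + b, [1.0, 0.0], needs_positive_x=True),
        Candidate("exp2P", 2, lambda x, a, b: a * np.exp(b * x), [1.0, 0.1]),
        Candidate("exp3P", 3, lambda x, a, b, c: a * np.exp(b * x) + c, [1.0, 0.1, 0.0]),
        Candidate("power2P", 2, lambda x, a, b: a * np.power(x, b), [1.0, 1.0], needs_positive_x=True),
        Candidate("power3P", 3, lambda x, a, b, c: a * np.power(x, b) + c, [1.0, 1.0, 0.0], needs_positive_x=True),
    ]


@dataclass
class CandidateFit:
    name: str
    n_params: int
    params: np.ndarray | None
    rss: float
    aic: float
    skipped: str = ""


class ProductivityRegressor(BaseEstimator, RegressorMixin):
    """AIC-selected trendline regression of productivity P on suitability S.

    Fits seven candidate forms (2- and 3-parameter linear, logarithmic,
    exponential and power families) by least squares and selects by
    AIC = n ln(RSS/n) + 2k. Candidates within ``delta_aic`` of the minimum are
    treated as equivalent and the fewest-parameter one wins (remaining ties:
    registry order). Log/power forms are skipped (with a record) when any
    S <= 0.

    Attributes
    ----------
    selected_ : name of the winning form
    params_ : fitted parameters of the winner
    aic_table_ : DataFrame ledger (form, k, params, RSS, AIC, dAIC, skipped)
    slope_ci_ : 95% CI of the linear-form slope (from OLS), for the
        positive-correlation check
    """

    def __init__(self, delta_aic: float = 2.0):
        self.delta_aic = delta_aic

    def fit(self, X, y) -> "ProductivityRegressor":
        S = np.asarray(X, dtype=float).ravel()
        P = np.asarray(y, dtype=float).ravel()
        if S.size != P.size:
            raise ValueError("S and P must have equal length")
        n = S.size
        if n < 8:
            raise ValueError("need at least 8 sites to rank 7 candidate forms")
        fits: list[CandidateFit] = []
        for cand in _registry():
            if cand.needs_positive_x and S.min() <= 0:
                fits.append(CandidateFit(cand.name, cand.n_params, None, np.inf, np.inf, "non-positive S"))
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    params, _ = curve_fit(cand.func, S, P, p0=cand.p0, maxfev=20000)
                resid = P - cand.func(S, *params)
                rss = float(resid @ resid)
                aic = n * np.log(max(rss, 1e-300) / n) + 2 * cand.n_params
                fits.append(CandidateFit(cand.name, cand.n_params, params, rss, aic))
            except (RuntimeError, ValueError) as exc:  # no convergence
                fits.append(CandidateFit(cand.name, cand.n_params, None, np.inf, np.inf, str(exc)))
        ok = [f for f in fits if np.isfinite(f.aic)]
        if not ok:
            raise RuntimeError("no candidate form could be fitted")
        best_aic = min(f.aic for f in ok)
        tied = [f for f in ok if f.aic - best_aic < self.delta_aic]
        winner = min(tied, key=lambda f: f.n_params)  # stable min keeps registry order

        self.candidates_ = fits
        self.selected_ = winner.name
        self.params_ = winner.params
        self._func = next(c.func for c in _registry() if c.name == winner.name)
        self.aic_table_ = pd.DataFrame(
            {
                "form": [f.name for f in fits],
                "k": [f.n_params for f in fits],
                "params": [None if f.params is None else list(np.round(f.params, 6)) for f in fits],
                "rss": [f.rss for f in fits],
                "aic": [f.aic for f in fits],
                "delta_aic": [f.aic - best_aic for f in fits],
                "skipped": [f.skipped for f in fits],
            }
        )
        # linear-slope inference for the suitability-productivity correlation check
        ols = sm.OLS(P, sm.add_constant(S)).fit()
        self.slope_ = float(ols.params[1])
        self.slope_ci_ = tuple(ols.conf_int(alpha=0.05)[1])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        S = np.asarray(X, dtype=float).ravel()
        return self._func(S, *self.params_)


def fit_productivity_model(S: np.ndarray, P: np.ndarray, delta_aic: float = 2.0) -> ProductivityRegressor:
    """Functional wrapper over ProductivityRegressor.fit."""
    return ProductivityRegressor(delta_aic=delta_aic).fit(S, P)


# ---------------------------------------------------------------------------
# zoning


@dataclass
class CultivationZoneMap:
    """Predicted productivity and cultivation zones on the suitability grid."""

    P: np.ndarray
    zones: np.ndarray  # byte codes per ZONE_CODES
    areas: dict[str, float] = field(default_factory=dict)  # 10^4 km^2 per zone

    @property
    def total(self) -> float:
        return self.areas["marginal"] + self.areas["general"] + self.areas["core"]


def classify_zones(P: np.ndarray, suitable: np.ndarray) -> np.ndarray:
    """Zone codes from predicted productivity within suitable habitat.

    core: P > 0.58; general: 0.37 <= P <= 0.58; marginal: P < 0.37
    (both thresholds belong to the general band).
    """
    zones = np.zeros(P.shape, dtype=np.uint8)
    zones[suitable & (P < GENERAL_MIN)] = ZONE_CODES["marginal"]
    zones[suitable & (P >= GENERAL_MIN) & (P <= CORE_MIN)] = ZONE_CODES["general"]
    zones[suitable & (P > CORE_MIN)] = ZONE_CODES["core"]
    return zones


def project_zones(
    model: ProductivityRegressor, smap: SuitabilityMap, areas: np.ndarray
) -> CultivationZoneMap:
    """Project productivity from S via the selected model and zone the raster."""
    check_is_fitted(model, "selected_")
    P = model.predict(smap.S.ravel()).reshape(smap.S.shape)
    zones = classify_zones(P, smap.suitable)
    zone_areas = {
        name: float(areas[zones == code].sum()) / 1e4
        for name, code in ZONE_CODES.items()
        if name != "unsuitable"
    }
    return CultivationZoneMap(P=P, zones=zones, areas=zone_areas)


def zone_table(zone_maps: dict[tuple[str, str], CultivationZoneMap]) -> pd.DataFrame:
    """Cultivation-zone area table, one row per (period, scenario)."""
    rows = []
    for (period, scenario), zm in zone_maps.items():
        rows.append(
            {
                "period": period,
                "scenario": scenario,
                "marginal": zm.areas["marginal"],
                "general": zm.areas["general"],
                "core": zm.areas["core"],
                "total": zm.total,
            }
        )
    return pd.DataFrame(rows)
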