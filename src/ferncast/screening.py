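"""Collinearity screening of environmental variables.

Candidate variables are pruned in two passes: greedy Spearman-correlation
elimination (while any pair has |rho| >= rho_max, drop the lower-priority
member of the worst pair), then iterative VIF elimination (drop the largest
VIF until all are below vif_max). "Priority" is an explicit user-supplied
ecological-relevance ranking: lower rank = more relevant = kept in ties.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class ScreeningReport:
    retained: list[str]
    dropped: list[tuple[str, str]]  # (variable, reason in {"correlation", "vif"})
    spearman: pd.DataFrame
    vif: dict[str, float]
    priority: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": self.retained,
            "dropped": [list(d) for d in self.dropped],
            "spearman": self.spearman.to_dict(),
            "vif": {k: (None if np.isinf(v) else v) for k, v in self.vif.items()},
            "priority": self.priority,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations; NaN for constant columns."""
    values = pd.DataFrame(values)
    if len(values) < 3:
        raise ValueError("need at least 3 sites for rank correlations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce NaN, not errors
        rho = stats.spearmanr(values.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.columns, columns=values.columns)


def vif(values: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Perfect collinearity is reported as +inf rather than raised.
    """
    values = pd.DataFrame(values)
    n, p = values.shape
    if n <= p:
        raise ValueError("need more sites than variables for VIF")
    X = values.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant columns have no defined VIF; drop them first")
    out: dict[str, float] = {}
    for j, name in enumerate(values.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else max(1.0, 1.0 / (1.0 - r2))
    return out


def screen(
    values: pd.DataFrame,
    priority: dict[str, int] | None = None,
    rho_max: float = 0.7,
    vif_max: float = 5.0,
) -> ScreeningReport:
    """Two-pass collinearity screening; see the module docstring for the rules."""
    values = pd.DataFrame(values)
    cols = list(values.columns)
    if priority is None:
        priority = {c: k for k, c in enumerate(cols)}
    missing = set(cols) - set(priority)
    if missing:
        raise ValueError(f"priority must cover all variables; missing {sorted(missing)}")

    full_rho = spearman_matrix(values)
    dropped: list[tuple[str, str]] = []
    keep = list(cols)

    # pass 1: greedy correlation pruning, worst offending pair first
    while len(keep) > 1:
        sub = full_rho.loc[keep, keep].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        sub = np.nan_to_num(sub)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] < rho_max:
            break
        a, b = keep[worst[0]], keep[worst[1]]
        loser = a if priority[a] > priority[b] else b
        keep.remove(loser)
        dropped.append((loser, "correlation"))

    # pass 2: iterative VIF pruning
    while len(keep) > 1:
        vifs = vif(values[keep])
        worst_var = max(keep, key=lambda c: (vifs[c], priority[c]))
        if vifs[worst_var] < vif_max:
            break
        keep.remove(worst_var)
        dropped.append((worst_var, "vif"))

    if not keep:
        raise ValueError("screening removed every variable; relax the thresholds")
    final_vif = vif(values[keep]) if len(values) > len(keep) and len(keep) > 1 else {c: 1.0 for c in keep}
    return ScreeningReport(
        retained=[c for c in cols if c in keep],
        dropped=dropped,
        spearman=full_rho,
        vif=final_vif,
        priority=dict(priority),
    )


class CollinearityScreener(TransformerMixin, BaseEstimator):
    """Transformer that keeps a collinearity-pruned subset of columns.

    Parameters
    ----------
    rho_max : float
        Pairwise |Spearman rho| above which the lower-priority variable of the
        pair is dropped.
    vif_max : float
        Variance inflation factor above which the worst variable is dropped.
    priority : dict or None
        Ecological-relevance ranking (lower = more relevant). Defaults to
        input column order.

    Attributes
    ----------
    retained_ : list of retained column names
    report_ : ScreeningReport with the full audit trail
    """

    def __init__(self, rho_max: float = 0.7, vif_max: float = 5.0, priority: dict | None = None):
        self.rho_max = rho_max
        self.vif_max = vif_max
        self.priority = priority

    def fit(self, X: pd.DataFrame, y=None) -> "CollinearityScreener":
        X = pd.DataFrame(X)
        self.report_ = screen(X, self.priority, self.rho_max, self.vif_max)
        self.retained_ = self.report_.retained
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)
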