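"""TSS-weighted ensemble species-distribution modelling.

Workflow: thin occurrences to one per km grid cell, draw pseudo-absences from
cells without presences, fit a registry of base learners over stratified
75/25 train/test repeats, score each fit with ROC AUC / TSS / Cohen's kappa,
keep fits with TSS >= 0.7, and average their suitability predictions with
weights proportional to TSS. The ensemble score is binarized at the threshold
maximizing TSS on the pooled held-out data, and the suprathreshold range is
split into three equal-width suitability tiers (low / moderate / high).

Base learners: regularized logistic regression, random forest and gradient
boosting (scikit-learn), an L1-regularized Maxent-style model over linear,
quadratic and product feature transforms, and a rectilinear environmental
envelope (surface-range-envelope) classifier.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_is_fitted

from .centroids import EARTH_RADIUS_KM
from .containers import EnvStack, GridGeometry, OccurrenceSet, SuitabilityMap

# ---------------------------------------------------------------------------
# occurrence preparation


def thin_occurrences(raw: OccurrenceSet, cell_km: float = 1.0) -> OccurrenceSet:
    """Keep at most one point per cell of a km grid (first in input order).

    The grid is anchored at the south-west corner of the point cloud; degrees
    are converted to km on a sphere using the mean latitude for the east-west
    scale (adequate for basin-scale domains).
    """
    if len(raw) == 0:
        return raw
    lat0 = float(np.mean(raw.lat))
    km_per_deg_lat = np.pi * EARTH_RADIUS_KM / 180.0
    km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(lat0))
    x = (raw.lon - raw.lon.min()) * km_per_deg_lon
    y = (raw.lat - raw.lat.min()) * km_per_deg_lat
    cells = np.floor(x / cell_km).astype(int) * 2**20 + np.floor(y / cell_km).astype(int)
    _, first = np.unique(cells, return_index=True)
    keep = np.sort(first)
    return OccurrenceSet(raw.lon[keep], raw.lat[keep], raw.label[keep], raw.weight[keep])


def sample_pseudo_absences(
    stack: EnvStack, presences: OccurrenceSet, n: int = 1200, seed: int = 0
) -> OccurrenceSet:
    """Sample n distinct pseudo-absence cells uniformly from non-presence cells."""
    geom = stack.geometry
    valid = np.isfinite(stack.layers).all(axis=0)
    pi, pj = geom.index_of(presences.lon, presences.lat)
    occupied = np.zeros(geom.shape, dtype=bool)
    occupied[pi, pj] = True
    candidates = np.flatnonzero(valid & ~occupied)
    if n > candidates.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {candidates.size} free cells available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    i, j = np.unravel_index(chosen, geom.shape)
    return OccurrenceSet(
        geom.lon[j], geom.lat[i], np.full(n, "pseudo_absence", dtype=object), np.ones(n)
    )


def split_repeats(
    y: np.ndarray, train_frac: float = 0.75, repeats: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test index splits, one pair per repeat."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to split")
    sss = StratifiedShuffleSplit(n_splits=repeats, train_size=train_frac, random_state=seed)
    return [(tr, te) for tr, te in sss.split(np.zeros_like(y), y)]


# ---------------------------------------------------------------------------
# base learners


class EnvelopeModel(BaseEstimator, ClassifierMixin):
    """Rectilinear environmental envelope (surface range envelope, SRE).

    Scores 1 inside the per-dimension [q, 1-q] presence quantile box, 0 outside.
    ``quantile=0`` uses the full presence range.
    """

    def __init__(self, quantile: float = 0.025):
        self.quantile = quantile

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pres = X[y == 1]
        if pres.size == 0:
            raise ValueError("envelope model needs presence rows")
        self.lo_ = np.quantile(pres, self.quantile, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.quantile, axis=0)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "lo_")
        X = np.asarray(X, dtype=float)
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1).astype(float)
        return np.column_stack([1.0 - inside, inside])

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5


def _maxent_like(seed: int) -> BaseEstimator:
    """Maxent-style member: L1-regularized logistic model on linear, quadratic
    and pairwise-product feature transforms (an exponential-family
    approximation of Maxent's feature machinery)."""
    return make_pipeline(
        StandardScaler(),
        PolynomialFeatures(degree=2, include_bias=False),
        LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=2000, random_state=seed),
    )


def model_registry(seed: int = 0) -> dict[str, BaseEstimator]:
    """Default base-learner registry keyed by algorithm name."""
    return {
        "glm": make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000)),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        "gbm": GradientBoostingClassifier(random_state=seed),
        "maxent": _maxent_like(seed),
        "sre": EnvelopeModel(quantile=0.0),
    }


def fit_base_model(algorithm: str, X: np.ndarray, y: np.ndarray, seed: int = 0) -> BaseEstimator:
    """Fit one registry algorithm on covariates X with presence labels y."""
    registry = model_registry(seed)
    if algorithm not in registry:
        raise ValueError(f"unknown algorithm '{algorithm}'; registry: {sorted(registry)}")
    return clone(registry[algorithm]).fit(X, y)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationScore:
    roc_auc: float
    tss: float
    kappa: float
    threshold_at_max_tss: float


def confusion_skill(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """TSS and Cohen's kappa from a confusion table at a fixed threshold."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    n = tp + fn + tn + fp
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1 else 0.0
    return tss, kappa


def max_tss_threshold(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Threshold over the observed-score grid maximizing TSS; returns (thr, tss)."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y_true[order]
    n_pos = y_true.sum()
    n_neg = y_true.size - n_pos
    # predicted positive means score >= threshold; sweep thresholds at each
    # distinct score (plus one above the max, the all-negative rule)
    thresholds = np.concatenate([np.unique(s_sorted), [s_sorted[-1] + 1.0]])
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])  # positives strictly below index
    cum_neg = np.concatenate([[0], np.cumsum(~y_sorted)])
    idx = np.searchsorted(s_sorted, thresholds, side="left")
    tp = n_pos - cum_pos[idx]
    fp = n_neg - cum_neg[idx]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))
    return float(thresholds[best]), float(tss[best])


def evaluate(scores: np.ndarray, y_true: np.ndarray) -> EvaluationScore:
    """ROC AUC plus TSS and kappa at the TSS-maximizing threshold."""
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation needs both classes in the test data")
    scores = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y_true, scores))
    thr, tss = max_tss_threshold(y_true, scores)
    kappa = float(cohen_kappa_score(y_true, (scores >= thr).astype(int)))
    return EvaluationScore(roc_auc=auc, tss=tss, kappa=kappa, threshold_at_max_tss=thr)


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleMember:
    algorithm: str
    repeat: int
    score: EvaluationScore
    model: BaseEstimator


def member_scores(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Suitability in [0, 1] from any fitted member."""
    return model.predict_proba(X)[:, 1]


def build_ensemble(
    members: list[EnsembleMember], tss_min: float = 0.7
) -> tuple[list[EnsembleMember], np.ndarray]:
    """Gate members at TSS >= tss_min; weights proportional to TSS, summing to 1."""
    passing = [m for m in members if m.score.tss >= tss_min]
    if not passing:
        best = max((m.score.tss for m in members), default=float("nan"))
        raise ValueError(
            f"no member reached TSS >= {tss_min} (best {best:.3f}); relax the gate"
        )
    tss = np.array([m.score.tss for m in passing])
    return passing, tss / tss.sum()


def binarize_and_tier(
    S: np.ndarray, geometry: GridGeometry, pooled_scores: np.ndarray, pooled_y: np.ndarray
) -> SuitabilityMap:
    """Cutoff = TSS-maximizing threshold on pooled held-out ensemble scores."""
    cutoff, _ = max_tss_threshold(pooled_y, pooled_scores)
    if cutoff >= 1.0:
        raise ValueError("degenerate cutoff = 1; ensemble scores are uninformative")
    return SuitabilityMap(geometry, S, cutoff=float(cutoff))


class EnsembleSDM(BaseEstimator, ClassifierMixin):
    """TSS-weighted ensemble species-distribution classifier.

    Fits each registry algorithm over ``repeats`` stratified train/test splits,
    evaluates every fit on its held-out fold, keeps fits with TSS >= ``tss_gate``
    and averages their probabilities with TSS-proportional weights.

    Parameters
    ----------
    algorithms : list of str or None
        Registry algorithm names; None = all five defaults.
    train_frac : float, default 0.75
        Training fraction per repeat.
    repeats : int, default 10
        Number of stratified splits per algorithm.
    tss_gate : float, default 0.7
        Minimum held-out TSS for a fit to join the ensemble.
    random_state : int, default 0

    Attributes
    ----------
    members_ : gated EnsembleMember list
    weights_ : per-member weights (sum to 1)
    all_scores_ : DataFrame of every fit's evaluation metrics
    cutoff_ : TSS-maximizing binarization threshold on pooled held-out data
    pooled_auc_ : ensemble ROC AUC on the pooled held-out folds
    """

    def __init__(
        self,
        algorithms: list[str] | None = None,
        train_frac: float = 0.75,
        repeats: int = 10,
        tss_gate: float = 0.7,
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.train_frac = train_frac
        self.repeats = repeats
        self.tss_gate = tss_gate
        self.random_state = random_state

    def fit(self, X, y) -> "EnsembleSDM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        algs = self.algorithms or list(model_registry())
        splits = split_repeats(y, self.train_frac, self.repeats, self.random_state)
        registry = model_registry(self.random_state)
        unknown = set(algs) - set(registry)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}; registry: {sorted(registry)}")

        members: list[EnsembleMember] = []
        rows = []
        held_scores: dict[int, dict[str, np.ndarray]] = {}
        for r, (tr, te) in enumerate(splits):
            held_scores[r] = {}
            for alg in algs:
                model = clone(registry[alg]).fit(X[tr], y[tr])
                s = member_scores(model, X[te])
                ev = evaluate(s, y[te])
                members.append(EnsembleMember(alg, r, ev, model))
                held_scores[r][alg] = s
                rows.append({"algorithm": alg, "repeat": r, **asdict(ev)})
        self.all_scores_ = pd.DataFrame(rows)

        self.members_, self.weights_ = build_ensemble(members, self.tss_gate)
        gated = {(m.algorithm, m.repeat): w for m, w in zip(self.members_, self.weights_)}

        # pooled held-out ensemble scores: per repeat, average the gated members
        # evaluated on that repeat's test fold, then pool folds
        pooled_s, pooled_y = [], []
        for r, (tr, te) in enumerate(splits):
            w = np.array([gated.get((a, r), 0.0) for a in algs])
            if w.sum() == 0:
                continue
            w = w / w.sum()
            s = np.sum([wk * held_scores[r][a] for wk, a in zip(w, algs) if wk > 0], axis=0)
            pooled_s.append(s)
            pooled_y.append(y[te])
        self._pooled_scores = np.concatenate(pooled_s)
        self._pooled_y = np.concatenate(pooled_y)
        self.pooled_auc_ = float(roc_auc_score(self._pooled_y, self._pooled_scores))
        self.cutoff_, self.pooled_tss_ = max_tss_threshold(self._pooled_y, self._pooled_scores)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        s = np.zeros(X.shape[0])
        for m, w in zip(self.members_, self.weights_):
            s += w * member_scores(m.model, X)
        return np.column_stack([1.0 - s, s])

    def predict_suitability(self, X) -> np.ndarray:
        """Weighted-average ensemble suitability in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= self.cutoff_).astype(int)

    def predict_map(self, stack: EnvStack, feature_names: list[str] | None = None) -> SuitabilityMap:
        """Project the fitted ensemble over a raster stack and tier it."""
        check_is_fitted(self, "members_")
        sub = stack.subset(feature_names) if feature_names else stack
        table = sub.to_table().to_numpy()
        S = self.predict_suitability(table).reshape(stack.geometry.shape)
        return SuitabilityMap(stack.geometry, S, cutoff=float(self.cutoff_))

    def spec_json(self) -> dict:
        """Machine-readable ensemble specification (gated members and weights)."""
        check_is_fitted(self, "members_")
        return {
            "tss_gate": self.tss_gate,
            "members": [
                {"algorithm": m.algorithm, "repeat": m.repeat, "tss": m.score.tss, "weight": float(w)}
                for m, w in zip(self.members_, self.weights_)
            ],
        }
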