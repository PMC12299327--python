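"""Niche overlap in 2-D environmental PCA space (occupancy grids, Schoener's D).

The realized niche is represented as an occupancy density over the first two
principal components of the environmental background, estimated by Gaussian
kernel density on an R x R lattice and corrected for environmental
availability (occurrence density divided by background density where the
background is available, zero elsewhere), then normalized to sum to one.
Overlap between two occupancy grids on the same lattice is Schoener's
D = 1 - 0.5 * sum |z1 - z2|, which is 1 for identical niches and 0 for
disjoint ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .containers import EnvStack, OccurrenceSet

_BG_EPS = 1e-12  # availability below this is treated as absent


@dataclass
class NicheGrid:
    """Occupancy density z (sums to 1) over a PC1 x PC2 lattice."""

    z: np.ndarray  # (R, R)
    background: np.ndarray  # (R, R) availability density
    x_edges: np.ndarray  # PC1 axis, length R
    y_edges: np.ndarray  # PC2 axis, length R

    @property
    def R(self) -> int:
        return self.z.shape[0]

    def same_axes(self, other: "NicheGrid") -> bool:
        return (
            self.z.shape == other.z.shape
            and np.allclose(self.x_edges, other.x_edges)
            and np.allclose(self.y_edges, other.y_edges)
        )


@dataclass
class OverlapResult:
    D: float
    label_a: str = ""
    label_b: str = ""


def background_points(
    occurrences: OccurrenceSet,
    stack: EnvStack,
    buffer_deg: float = 1.0,
    n: int = 2000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Environmental values at background cells.

    The candidate region is the union of square (Chebyshev) buffers of
    ``buffer_deg`` degrees around the occurrence points, intersected with
    valid-data cells — or an explicit boolean ``mask`` (e.g. ensemble-suitable
    habitat for future climates). ``n`` cells are sampled uniformly with
    replacement-free draws where possible.
    """
    if buffer_deg <= 0:
        raise ValueError("buffer must be positive")
    geom = stack.geometry
    valid = np.isfinite(stack.layers).all(axis=0)
    if mask is None:
        lon_g, lat_g = np.meshgrid(geom.lon, geom.lat)
        region = np.zeros(geom.shape, dtype=bool)
        for lo, la in zip(occurrences.lon, occurrences.lat):
            region |= (np.abs(lon_g - lo) <= buffer_deg) & (np.abs(lat_g - la) <= buffer_deg)
    else:
        region = np.asarray(mask, dtype=bool)
    region &= valid
    candidates = np.flatnonzero(region)
    if candidates.size == 0:
        raise ValueError("background region is empty")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=candidates.size < n)
    i, j = np.unravel_index(chosen, geom.shape)
    return pd.DataFrame({name: stack.layers[k, i, j] for k, name in enumerate(stack.names)})


class EnvPCA:
    """Centered-and-scaled PCA of background environmental values.

    Fitted on the background sample; projects any table with the same columns
    onto the first ``n_components`` axes.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, values: pd.DataFrame) -> "EnvPCA":
        values = pd.DataFrame(values)
        if values.shape[1] < 3 or len(values) < 10:
            raise ValueError("PCA needs >= 3 variables and >= 10 samples")
        keep = [c for c in values.columns if values[c].std() > 0]
        if len(keep) < values.shape[1]:
            import warnings

            warnings.warn(f"dropping constant columns: {sorted(set(values.columns) - set(keep))}")
        self.columns_ = keep
        self.scaler_ = StandardScaler().fit(values[keep])
        self.pca_ = PCA(n_components=self.n_components).fit(self.scaler_.transform(values[keep]))
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self.loadings_ = pd.DataFrame(
            self.pca_.components_.T,
            index=keep,
            columns=[f"PC{k + 1}" for k in range(self.n_components)],
        )
        return self

    def transform(self, values: pd.DataFrame) -> np.ndarray:
        return self.pca_.transform(self.scaler_.transform(pd.DataFrame(values)[self.columns_]))


def pca_env(background_values: pd.DataFrame, n_components: int = 2) -> EnvPCA:
    """Fit the environmental-space PCA on a background sample."""
    return EnvPCA(n_components).fit(background_values)


def occupancy_grid(
    occ_scores: np.ndarray, bg_scores: np.ndarray, R: int = 100, bw_method: str = "silverman"
) -> NicheGrid:
    """Availability-corrected occurrence density on an R x R PC lattice."""
    if R < 10:
        raise ValueError("grid resolution R must be >= 10")
    occ_scores = np.asarray(occ_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    if occ_scores.size == 0 or bg_scores.size == 0:
        raise ValueError("both occurrence and background scores are required")
    both = np.vstack([occ_scores, bg_scores])
    x = np.linspace(both[:, 0].min(), both[:, 0].max(), R)
    y = np.linspace(both[:, 1].min(), both[:, 1].max(), R)
    xx, yy = np.meshgrid(x, y)
    grid = np.vstack([xx.ravel(), yy.ravel()])
    occ_d = gaussian_kde(occ_scores.T, bw_method=bw_method)(grid).reshape(R, R)
    bg_d = gaussian_kde(bg_scores.T, bw_method=bw_method)(grid).reshape(R, R)
    bg_d = bg_d / bg_d.sum()
    occ_d = occ_d / occ_d.sum()
    z = np.where(bg_d > _BG_EPS, occ_d / np.clip(bg_d, _BG_EPS, None), 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy density vanished everywhere on the lattice")
    return NicheGrid(z=z / total, background=bg_d, x_edges=x, y_edges=y)


def schoener_d(a: NicheGrid, b: NicheGrid, label_a: str = "", label_b: str = "") -> OverlapResult:
    """Schoener's D = 1 - 0.5 * sum |z_a - z_b| over matched lattices."""
    if not a.same_axes(b):
        raise ValueError("niche grids are on different lattices")
    D = 1.0 - 0.5 * float(np.abs(a.z - b.z).sum())
    # snap summation round-off so identical grids give exactly 1 and
    # disjoint supports exactly 0
    if D < 1e-12:
        D = 0.0
    elif D > 1.0 - 1e-12:
        D = 1.0
    return OverlapResult(D=min(max(D, 0.0), 1.0), label_a=label_a, label_b=label_b)


def plot_niche_shift(a: NicheGrid, b: NicheGrid, ax=None):
    """Density-shift plot: baseline occupancy in green, shifted in red,
    overlap in blue-ish blend. Returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    extent = (a.x_edges[0], a.x_edges[-1], a.y_edges[0], a.y_edges[-1])
    rgb = np.zeros(a.z.shape + (3,))
    rgb[..., 1] = a.z / a.z.max()  # green: baseline
    rgb[..., 0] = b.z / b.z.max()  # red: shifted
    rgb[..., 2] = np.minimum(rgb[..., 0], rgb[..., 1])  # blue where both
    ax.imshow(np.clip(rgb, 0, 1), origin="lower", extent=extent, aspect="auto")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax


def niche_shift_experiment(
    deltas: list[float],
    n_occ: int = 300,
    n_bg: int = 3000,
    seed: int = 0,
    R: int = 100,
) -> list[float]:
    """D between a baseline niche and niches shifted by delta SDs along PC1.

    A synthetic probe of the climate-shift / overlap relationship: occurrence
    environmental values are displaced along the dominant environmental axis
    by ``delta`` background standard deviations while availability stays
    common, so D should decay monotonically with delta.
    """
    rng = np.random.default_rng(seed)
    n_vars = 4
    # correlated background cloud with a dominant first axis
    cov = np.full((n_vars, n_vars), 0.5) + 0.5 * np.eye(n_vars)
    bg = rng.multivariate_normal(np.zeros(n_vars), 4.0 * cov, size=n_bg)
    occ = rng.multivariate_normal(np.zeros(n_vars), 0.5 * cov, size=n_occ)
    cols = [f"env_{k}" for k in range(n_vars)]
    proj = pca_env(pd.DataFrame(bg, columns=cols))
    bg_s = proj.transform(pd.DataFrame(bg, columns=cols))
    occ_s = proj.transform(pd.DataFrame(occ, columns=cols))
    sd1 = bg_s[:, 0].std()
    base = None
    out = []
    for delta in deltas:
        shifted = occ_s + np.array([delta * sd1, 0.0])
        # shared lattice spanning the largest shift so all grids are comparable
        span = np.vstack([bg_s, occ_s + np.array([max(deltas) * sd1, 0.0]), occ_s])
        x = np.linspace(span[:, 0].min(), span[:, 0].max(), R)
        y = np.linspace(span[:, 1].min(), span[:, 1].max(), R)
        xx, yy = np.meshgrid(x, y)
        grid = np.vstack([xx.ravel(), yy.ravel()])
        bg_d = gaussian_kde(bg_s.T, bw_method="silverman")(grid).reshape(R, R)
        bg_d /= bg_d.sum()

        def _grid_for(scores: np.ndarray) -> NicheGrid:
            d = gaussian_kde(scores.T, bw_method="silverman")(grid).reshape(R, R)
            d /= d.sum()
            z = np.where(bg_d > _BG_EPS, d / np.clip(bg_d, _BG_EPS, None), 0.0)
            return NicheGrid(z=z / z.sum(), background=bg_d, x_edges=x, y_edges=y)

        if base is None:
            base = _grid_for(occ_s)
        out.append(schoener_d(base, _grid_for(shifted)).D)
    return out
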