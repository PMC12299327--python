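"""Synthetic landscapes, occurrences and nutrition tables with known ground truth.

Every downstream stage of the pipeline is exercised against landscapes generated
here, where the true suitability surface is known exactly. Environmental layers
are spatially autocorrelated Gaussian random fields (white noise smoothed with a
Gaussian kernel); future scenarios are the current layers plus per-variable
additive shifts, mimicking warming-driven mean changes without modelling GCMs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .containers import EnvStack, GridGeometry, OccurrenceSet, SuitabilityMap, TIER_CODES


@dataclass
class LandscapeConfig:
    """Geometry, variable count and scenario shifts for a synthetic landscape.

    ``scenario_deltas`` maps a scenario label to a length-``n_vars`` vector of
    additive per-variable shifts applied on top of the current-climate stack.
    """

    grid_rows: int = 120
    grid_cols: int = 120
    lon_range: tuple[float, float] = (100.0, 104.0)
    lat_range: tuple[float, float] = (29.0, 33.0)
    n_vars: int = 16
    spatial_corr_length: float = 8.0  # Gaussian smoothing sigma, in cells
    scenario_deltas: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if self.n_vars < 3:
            raise ValueError("need at least 3 environmental variables")
        for name, delta in self.scenario_deltas.items():
            delta = np.asarray(delta, dtype=float)
            if delta.size != self.n_vars:
                raise ValueError(f"scenario '{name}' delta must have length n_vars={self.n_vars}")
            self.scenario_deltas[name] = delta

    def geometry(self) -> GridGeometry:
        lon_res = (self.lon_range[1] - self.lon_range[0]) / self.grid_cols
        lat_res = (self.lat_range[1] - self.lat_range[0]) / self.grid_rows
        lon = self.lon_range[0] + lon_res * (np.arange(self.grid_cols) + 0.5)
        lat = self.lat_range[0] + lat_res * (np.arange(self.grid_rows) + 0.5)
        return GridGeometry(lon, lat)


@dataclass
class TrueSuitability:
    """Logistic ground-truth response: S = sigmoid(intercept + sum(coef * z))."""

    coefficients: np.ndarray
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def surface(self, stack: EnvStack, seed: int | None = None) -> np.ndarray:
        """True probability surface on the stack's grid, clipped to [0, 1]."""
        if self.coefficients.size != stack.n_vars:
            raise ValueError("coefficient length must equal the stack's variable count")
        eta = self.intercept + np.tensordot(self.coefficients, stack.layers, axes=1)
        if self.noise_sd > 0:
            rng = np.random.default_rng(seed)
            eta = eta + rng.normal(0.0, self.noise_sd, size=eta.shape)
        return expit(eta)


def default_truth(n_vars: int) -> TrueSuitability:
    """Default ground truth: a sharply delimited niche controlled by the first
    four variables, occupying roughly 8% of the landscape — the low-prevalence,
    fragmented-habitat regime of a montane species with narrow climatic limits."""
    coef = np.zeros(n_vars)
    coef[: min(4, n_vars)] = [8.0, -6.0, 4.0, 3.0][: min(4, n_vars)]
    return TrueSuitability(coef, intercept=-16.0, noise_sd=0.0)


def generate_env_stack(config: LandscapeConfig, scenario: str = "current") -> EnvStack:
    """Generate a spatially autocorrelated environmental stack for one scenario.

    The current-climate stack depends only on ``config.seed``; a future scenario
    is the current stack plus that scenario's additive delta vector, so scenario
    differences are exactly the configured shifts.
    """
    if scenario != "current" and scenario not in config.scenario_deltas:
        raise ValueError(
            f"unknown scenario '{scenario}'; known: ['current'] + {sorted(config.scenario_deltas)}"
        )
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    layers = np.empty((config.n_vars,) + shape)
    for k in range(config.n_vars):
        field_ = gaussian_filter(rng.standard_normal(shape), sigma=config.spatial_corr_length, mode="reflect")
        sd = field_.std()
        layers[k] = (field_ - field_.mean()) / (sd if sd > 0 else 1.0)
    if scenario != "current":
        layers = layers + config.scenario_deltas[scenario][:, None, None]
    names = [f"env_{k + 1}" for k in range(config.n_vars)]
    return EnvStack(config.geometry(), layers, names, scenario=scenario)


def generate_occurrences(
    stack: EnvStack, truth: TrueSuitability, n_target: int, seed: int
) -> OccurrenceSet:
    """Sample presence points with probability proportional to true suitability.

    Cells are drawn with replacement (repeat visits to favourable cells are the
    norm in field surveys), and each point gets uniform within-cell jitter so
    that km-grid thinning downstream has duplicates to remove.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    S = truth.surface(stack)
    total = S.sum()
    if total <= 0:
        raise ValueError("degenerate truth: suitability is zero everywhere")
    rng = np.random.default_rng(seed)
    p = (S / total).ravel()
    idx = rng.choice(S.size, size=n_target, replace=True, p=p)
    i, j = np.unravel_index(idx, S.shape)
    geom = stack.geometry
    jitter_lon = rng.uniform(-0.5, 0.5, size=n_target) * geom.lon_res
    jitter_lat = rng.uniform(-0.5, 0.5, size=n_target) * geom.lat_res
    return OccurrenceSet(geom.lon[j] + jitter_lon, geom.lat[i] + jitter_lat)


def generate_nutrition_table(
    sites: OccurrenceSet,
    S_values: np.ndarray,
    true_weights: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_indicators: int = 4,
) -> pd.DataFrame:
    """Per-site nutritional indicator table whose entropy-weighted index tracks S.

    Each indicator is affine in the site suitability S plus Gaussian noise, with
    indicator-specific scale and offset, so that after min-max standardization
    the weighted sum correlates positively with S.
    """
    S_values = np.asarray(S_values, dtype=float)
    true_weights = np.asarray(true_weights, dtype=float)
    if S_values.size != len(sites):
        raise ValueError("one S value per site required")
    if not np.isclose(true_weights.sum(), 1.0):
        raise ValueError("true_weights must sum to 1")
    if true_weights.size != n_indicators:
        raise ValueError("one weight per indicator required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = S_values.size
    data = {"site": np.arange(1, n + 1), "lon": sites.lon, "lat": sites.lat, "S": S_values}
    # indicator-specific scales/offsets emulate heterogeneous assay units; the
    # S-loading of indicator k is proportional to its true weight
    scales = 1.0 + rng.uniform(0.5, 2.0, size=n_indicators)
    offsets = rng.uniform(0.0, 5.0, size=n_indicators)
    for k in range(n_indicators):
        signal = true_weights[k] * n_indicators * S_values
        data[f"indicator_{k + 1}"] = offsets[k] + scales[k] * signal + rng.normal(0, noise_sd, size=n)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# fixture construction: maps built to prescribed areas


def masks_from_areas(geometry: GridGeometry, targets_1e4km2: list[float]) -> list[np.ndarray]:
    """Disjoint boolean masks whose spherical areas match the targets.

    Cells are consumed in raster order; each mask stops once its cumulative
    area reaches the target, so the error per mask is below one cell area
    (well under 0.01 x 10^4 km^2 for sub-0.1-degree grids).
    """
    from .dynamics import cell_areas

    areas = cell_areas(geometry).ravel()
    masks = [np.zeros(areas.size, dtype=bool) for _ in targets_1e4km2]
    pos = 0
    for mask, target in zip(masks, targets_1e4km2):
        acc = 0.0
        goal = target * 1e4
        while acc < goal:
            if pos >= areas.size:
                raise ValueError("grid too small for the requested areas")
            mask[pos] = True
            acc += areas[pos]
            pos += 1
    return [m.reshape(geometry.shape) for m in masks]


def suitability_from_areas(
    geometry: GridGeometry,
    low: float,
    moderate: float,
    high: float,
    cutoff: float = 0.25,
) -> SuitabilityMap:
    """A SuitabilityMap whose per-tier areas (10^4 km^2) match the targets."""
    m_low, m_mod, m_high = masks_from_areas(geometry, [low, moderate, high])
    width = (1.0 - cutoff) / 3.0
    S = np.zeros(geometry.shape)
    S[m_low] = cutoff + 0.5 * width
    S[m_mod] = cutoff + 1.5 * width
    S[m_high] = cutoff + 2.5 * width
    smap = SuitabilityMap(geometry, S, cutoff=cutoff)
    assert (smap.tiers[m_low] == TIER_CODES["low"]).all()
    return smap


def fixture_geometry(resolution_deg: float = 0.05) -> GridGeometry:
    """A basin-scale fixture grid (100-104E, 29-33N) for area arithmetic."""
    lon = 100.0 + resolution_deg * (np.arange(int(4 / resolution_deg)) + 0.5)
    lat = 29.0 + resolution_deg * (np.arange(int(4 / resolution_deg)) + 0.5)
    return GridGeometry(lon, lat)
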