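"""Habitat area accounting and current-vs-future change overlays.

Areas are computed on a spherical Earth (R = 6371.0088 km): a grid cell
spanning longitudes [l1, l2] and latitudes [p1, p2] has area
R^2 * (l2 - l1 in radians) * (sin p2 - sin p1). Summaries are reported in
units of 10^4 km^2, the convention for basin-scale habitat tables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centroids import EARTH_RADIUS_KM
from .containers import GridGeometry, SuitabilityMap, TIER_CODES

CHANGE_CODES = {"none": 0, "loss": 1, "stable": 2, "gain": 3}


@dataclass
class AreaSummary:
    """Per-tier suitable areas in 10^4 km^2 plus shares of the suitable total."""

    low: float
    moderate: float
    high: float

    @property
    def total(self) -> float:
        return self.low + self.moderate + self.high

    def share(self, tier: str) -> float:
        """Percent of total suitable area in one tier."""
        if self.total == 0:
            return 0.0
        return 100.0 * getattr(self, tier) / self.total

    def to_row(self) -> dict:
        return {
            "low": self.low,
            "moderate": self.moderate,
            "high": self.high,
            "total": self.total,
            "low_share_pct": self.share("low"),
            "moderate_share_pct": self.share("moderate"),
            "high_share_pct": self.share("high"),
        }


@dataclass
class ChangeSummary:
    """Loss / stable / gain areas in 10^4 km^2 between two periods."""

    loss: float
    stable: float
    gain: float

    @property
    def current_total(self) -> float:
        return self.loss + self.stable

    @property
    def future_total(self) -> float:
        return self.stable + self.gain


def cell_areas(geometry: GridGeometry) -> np.ndarray:
    """Per-cell areas in km^2 on a spherical Earth."""
    if geometry.lon_res == 0 or geometry.lat_res == 0:
        raise ValueError("grid resolution must be non-zero")
    dlon = np.radians(abs(geometry.lon_res))
    lat_top = np.radians(geometry.lat + geometry.lat_res / 2.0)
    lat_bot = np.radians(geometry.lat - geometry.lat_res / 2.0)
    band = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    return np.tile(band[:, None], (1, geometry.lon.size))


def area_summary(smap: SuitabilityMap, areas: np.ndarray) -> AreaSummary:
    """Tier areas in 10^4 km^2."""
    if areas.shape != smap.tiers.shape:
        raise ValueError("tier map and cell areas have different shapes")
    per_tier = {
        name: float(areas[smap.tiers == code].sum()) / 1e4
        for name, code in TIER_CODES.items()
        if name != "unsuitable"
    }
    return AreaSummary(low=per_tier["low"], moderate=per_tier["moderate"], high=per_tier["high"])


def overlay_change(
    current: SuitabilityMap, future: SuitabilityMap, areas: np.ndarray
) -> tuple[ChangeSummary, np.ndarray]:
    """Per-cell loss/stable/gain classification and its area summary.

    'Suitable' means any tier at or above low (S >= cutoff). The summary
    satisfies loss + stable = current suitable total and stable + gain =
    future suitable total exactly by construction.
    """
    if not current.geometry.same_grid(future.geometry):
        raise ValueError("current and future maps are on different grids")
    if areas.shape != current.S.shape:
        raise ValueError("cell areas do not match the map grid")
    cur, fut = current.suitable, future.suitable
    change = np.zeros(cur.shape, dtype=np.uint8)
    change[cur & ~fut] = CHANGE_CODES["loss"]
    change[cur & fut] = CHANGE_CODES["stable"]
    change[~cur & fut] = CHANGE_CODES["gain"]
    summary = ChangeSummary(
        loss=float(areas[change == CHANGE_CODES["loss"]].sum()) / 1e4,
        stable=float(areas[change == CHANGE_CODES["stable"]].sum()) / 1e4,
        gain=float(areas[change == CHANGE_CODES["gain"]].sum()) / 1e4,
    )
    return summary, change


def percent_change(reference: float, comparison: float) -> float:
    """Signed percent change 100*(comparison - reference)/reference, 2 decimals."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference area")
    return round(100.0 * (comparison - reference) / reference, 2)


def area_table(summaries: dict[tuple[str, str], AreaSummary]) -> pd.DataFrame:
    """Suitable-area table, one row per (period, scenario)."""
    rows = []
    for (period, scenario), s in summaries.items():
        rows.append({"period": period, "scenario": scenario, **s.to_row()})
    return pd.DataFrame(rows)


def change_table(summaries: dict[tuple[str, str], ChangeSummary]) -> pd.DataFrame:
    """Change table, one row per (period, scenario)."""
    rows = []
    for (period, scenario), c in summaries.items():
        rows.append(
            {
                "period": period,
                "scenario": scenario,
                "habitat_area": c.future_total,
                "loss": c.loss,
                "stable": c.stable,
                "gain": c.gain,
            }
        )
    return pd.DataFrame(rows)
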