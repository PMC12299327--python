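"""Core gridded and tabular containers shared across the pipeline.

All grids are regular lon/lat grids. Layers are stored row-major with row 0 at
the *southern* edge (latitude increases with row index), so ``lat[i]`` and
``lon[j]`` give the cell-center coordinates of cell ``(i, j)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIER_CODES = {"unsuitable": 0, "low": 1, "moderate": 2, "high": 3}
TIER_NAMES = {v: k for k, v in TIER_CODES.items()}


@dataclass
class GridGeometry:
    """Regular geographic grid: cell-center coordinates in degrees.

    Cell sizes are inferred from consecutive centers; pass ``lon_res``/
    ``lat_res`` explicitly for single-row or single-column grids.
    """

    lon: np.ndarray  # (cols,) cell-center longitudes, ascending
    lat: np.ndarray  # (rows,) cell-center latitudes, ascending
    lon_res: float | None = None
    lat_res: float | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.ndim != 1 or self.lat.ndim != 1:
            raise ValueError("lon and lat must be 1-D arrays of cell centers")
        if self.lon_res is None:
            self.lon_res = float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 0.0
        if self.lat_res is None:
            self.lat_res = float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points (clipped)."""
        j = np.clip(np.round((np.asarray(lon) - self.lon[0]) / self.lon_res).astype(int), 0, self.lon.size - 1)
        i = np.clip(np.round((np.asarray(lat) - self.lat[0]) / self.lat_res).astype(int), 0, self.lat.size - 1)
        return i, j

    def same_grid(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.lat, other.lat)
        )


@dataclass
class EnvStack:
    """Named environmental raster layers on a shared lon/lat grid."""

    geometry: GridGeometry
    layers: np.ndarray  # (n_vars, rows, cols)
    names: list[str]
    scenario: str = "current"
    period: str = "current"

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be (n_vars, rows, cols)")
        if self.layers.shape[0] != len(self.names):
            raise ValueError("one name per layer required")
        if self.layers.shape[1:] != self.geometry.shape:
            raise ValueError("layer shape does not match grid geometry")

    @property
    def n_vars(self) -> int:
        return self.layers.shape[0]

    def values_at(self, lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
        """Extract per-layer values at point locations (containing cell)."""
        i, j = self.geometry.index_of(lon, lat)
        return pd.DataFrame({name: self.layers[k, i, j] for k, name in enumerate(self.names)})

    def to_table(self) -> pd.DataFrame:
        """Flatten to one row per cell, columns = variables."""
        return pd.DataFrame({name: self.layers[k].ravel() for k, name in enumerate(self.names)})

    def subset(self, names: list[str]) -> "EnvStack":
        idx = [self.names.index(n) for n in names]
        return EnvStack(self.geometry, self.layers[idx], list(names), self.scenario, self.period)

    def write_tiff(self, path: str | Path) -> None:
        """Multi-band TIFF with a JSON sidecar carrying grid geometry and band names."""
        import tifffile

        path = Path(path)
        # flip so row 0 is the northern edge, the usual raster convention
        tifffile.imwrite(
            path, self.layers[:, ::-1, :].astype(np.float32), photometric="minisblack"
        )
        sidecar = {
            "names": self.names,
            "lon": self.geometry.lon.tolist(),
            "lat": self.geometry.lat.tolist(),
            "scenario": self.scenario,
            "period": self.period,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "EnvStack":
        import tifffile

        path = Path(path)
        layers = np.asarray(tifffile.imread(path), dtype=float)[:, ::-1, :]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        geom = GridGeometry(np.array(meta["lon"]), np.array(meta["lat"]))
        return cls(geom, layers, list(meta["names"]), meta.get("scenario", "current"), meta.get("period", "current"))


@dataclass
class OccurrenceSet:
    """Presence and pseudo-absence points in geographic coordinates."""

    lon: np.ndarray
    lat: np.ndarray
    label: np.ndarray = field(default=None)  # "presence" | "pseudo_absence"
    weight: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = self.lon.size
        if self.label is None:
            self.label = np.full(n, "presence", dtype=object)
        else:
            self.label = np.asarray(self.label, dtype=object)
        if self.weight is None:
            self.weight = np.ones(n)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        if not (self.lat.size == self.label.size == self.weight.size == n):
            raise ValueError("lon, lat, label, weight must have equal length")
        if n and (np.abs(self.lon).max() > 180 or np.abs(self.lat).max() > 90):
            raise ValueError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return self.lon.size

    @property
    def is_presence(self) -> np.ndarray:
        return self.label == "presence"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lon, "lat": self.lat, "label": self.label, "weight": self.weight})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        label = df["label"].to_numpy(dtype=object) if "label" in df else None
        weight = df["weight"].to_numpy(dtype=float) if "weight" in df else None
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy(), label, weight)

    @classmethod
    def concat(cls, a: "OccurrenceSet", b: "OccurrenceSet") -> "OccurrenceSet":
        return cls(
            np.concatenate([a.lon, b.lon]),
            np.concatenate([a.lat, b.lat]),
            np.concatenate([a.label, b.label]),
            np.concatenate([a.weight, b.weight]),
        )


@dataclass
class SuitabilityMap:
    """Continuous presence probability plus the derived tier map.

    Tier convention: cells with S < cutoff are unsuitable; [cutoff, 1] is split
    into three equal-width bands (low / moderate / high), upper bound closed.
    """

    geometry: GridGeometry
    S: np.ndarray  # (rows, cols) in [0, 1]
    cutoff: float
    tiers: np.ndarray = None  # (rows, cols) byte codes per TIER_CODES

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != self.geometry.shape:
            raise ValueError("S shape does not match geometry")
        if np.nanmin(self.S) < -1e-9 or np.nanmax(self.S) > 1 + 1e-9:
            raise ValueError("S must lie in [0, 1]")
        if not 0 <= self.cutoff < 1:
            raise ValueError("cutoff must lie in [0, 1); cutoff = 1 leaves no suitable band")
        if self.tiers is None:
            self.tiers = tier_classify(self.S, self.cutoff)

    @property
    def suitable(self) -> np.ndarray:
        return self.tiers > 0

    def write_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.S[::-1, :].astype(np.float32))
        tifffile.imwrite(path.with_suffix(".tiers" + path.suffix), self.tiers[::-1, :].astype(np.uint8))
        sidecar = {"lon": self.geometry.lon.tolist(), "lat": self.geometry.lat.tolist(), "cutoff": self.cutoff}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "SuitabilityMap":
        import tifffile

        path = Path(path)
        S = np.asarray(tifffile.imread(path), dtype=float)[::-1, :]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        geom = GridGeometry(np.array(meta["lon"]), np.array(meta["lat"]))
        return cls(geom, S, float(meta["cutoff"]))


def tier_classify(S: np.ndarray, cutoff: float) -> np.ndarray:
    """Equal-width low/moderate/high tiers over [cutoff, 1]; S < cutoff unsuitable.

    Band boundaries b1 = cutoff + (1-cutoff)/3 and b2 = cutoff + 2(1-cutoff)/3;
    low = [cutoff, b1], moderate = (b1, b2], high = (b2, 1] (upper-closed).
    """
    S = np.asarray(S, dtype=float)
    if cutoff >= 1:
        raise ValueError("degenerate cutoff = 1: no suitable band remains")
    width = (1.0 - cutoff) / 3.0
    b1, b2 = cutoff + width, cutoff + 2 * width
    tiers = np.zeros(S.shape, dtype=np.uint8)
    tiers[(S >= cutoff) & (S <= b1)] = TIER_CODES["low"]
    tiers[(S > b1) & (S <= b2)] = TIER_CODES["moderate"]
    tiers[S > b2] = TIER_CODES["high"]
    return tiers
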