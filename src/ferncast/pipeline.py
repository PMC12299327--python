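"""End-to-end pipeline: synthesize -> screen -> fit -> project -> account.

A single :class:`RunConfig` drives every stage; one global seed is fanned out
deterministically to the stages (stage k uses
``SeedSequence([seed, k]).generate_state(1)[0] % 2**31``), so any stage can be
re-run standalone and reproduce its in-pipeline behaviour. Every output file
is recorded in a manifest with its SHA-256 checksum; identical config + seed
yields an identical manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import centroids as ctr
from . import cultivation as cult
from . import dynamics as dyn
from . import niche as nch
from . import screening as scr
from . import sdm as sdm_mod
from . import synthetic as syn
from .containers import OccurrenceSet

log = logging.getLogger("ferncast")

STAGES = ["synth", "screen", "sdm", "tier", "change", "centroid", "niche", "zones"]


class RunConfig(BaseModel):
    """Validated pipeline configuration with the study-condition defaults."""

    model_config = ConfigDict(extra="forbid")

    # landscape
    grid_rows: int = Field(120, ge=10)
    grid_cols: int = Field(120, ge=10)
    n_vars: int = Field(16, ge=3)
    lon_range: tuple[float, float] = (100.0, 104.0)
    lat_range: tuple[float, float] = (29.0, 33.0)
    spatial_corr_length: float = Field(8.0, gt=0)
    scenarios: dict[str, list[float]] = Field(default_factory=dict)
    # occurrences
    n_occ_raw: int = Field(256, ge=1)
    thin_cell_km: float = Field(1.0, gt=0)
    # screening
    rho_max: float = Field(0.7, gt=0, le=1)
    vif_max: float = Field(5.0, gt=1)
    # sdm
    n_pseudo: int = Field(1200, ge=10)
    train_frac: float = Field(0.75, gt=0, lt=1)
    repeats: int = Field(10, ge=1)
    tss_gate: float = Field(0.7, ge=-1, le=1)
    algorithms: Optional[list[str]] = None
    # niche
    niche_R: int = Field(100, ge=10)
    buffer_deg: float = Field(1.0, gt=0)
    n_background: int = Field(2000, ge=100)
    # cultivation
    n_nutrition_sites: int = Field(36, ge=8)
    nutrition_noise_sd: float = Field(0.05, ge=0)
    zone_core: float = 0.58
    zone_general: float = 0.37
    # reproducibility
    seed: int = Field(0, ge=0)

    @field_validator("scenarios")
    @classmethod
    def _check_deltas(cls, v, info):
        n_vars = info.data.get("n_vars", 16)
        for name, delta in v.items():
            if len(delta) != n_vars:
                raise ValueError(f"scenario '{name}' delta must have length n_vars={n_vars}")
        return v

    @model_validator(mode="after")
    def _check_zones(self):
        if not 0 < self.zone_general < self.zone_core < 1:
            raise ValueError("zoning thresholds must satisfy 0 < general < core < 1")
        return self

    def with_default_scenarios(self) -> "RunConfig":
        """Three emission scenarios x two periods as graded mean shifts.

        Shift magnitudes grow with forcing (SSP126 < SSP245 < SSP585) and
        with horizon (2090 > 2050), applied to the climate-like leading
        variables, emulating warming-driven environmental drift.
        """
        if self.scenarios:
            return self
        base = {"SSP126": 0.3, "SSP245": 0.6, "SSP585": 1.0}
        horizon = {"2050": 1.0, "2090": 2.0}
        scen = {}
        for s, mag in base.items():
            for p, h in horizon.items():
                delta = np.zeros(self.n_vars)
                k = min(6, self.n_vars)
                delta[:k] = mag * h * np.linspace(1.0, 0.4, k)
                scen[f"{s}-{p}"] = delta.tolist()
        return self.model_copy(update={"scenarios": scen})


def validate_config(raw: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config (path, YAML text, or dict).

    All schema violations are reported together (pydantic aggregates them).
    """
    if isinstance(raw, dict):
        data = raw
    else:
        text = Path(raw).read_text() if Path(str(raw)).exists() else str(raw)
        data = yaml.safe_load(text) or {}
    return RunConfig(**data).with_default_scenarios()


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    k = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path, upto: str = "zones") -> dict:
    """Run the pipeline through stage ``upto``; return the manifest dict."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage '{upto}'; stages: {STAGES}")
    config = config.with_default_scenarios()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    last = STAGES.index(upto)

    def done(stage: str) -> bool:
        return STAGES.index(stage) > last

    # --- synth -----------------------------------------------------------
    log.info("stage synth")
    lc = syn.LandscapeConfig(
        grid_rows=config.grid_rows,
        grid_cols=config.grid_cols,
        lon_range=config.lon_range,
        lat_range=config.lat_range,
        n_vars=config.n_vars,
        spatial_corr_length=config.spatial_corr_length,
        scenario_deltas={k: np.array(v) for k, v in config.scenarios.items()},
        seed=stage_seed(config.seed, "synth"),
    )
    truth = syn.default_truth(config.n_vars)
    stacks = {"current": syn.generate_env_stack(lc, "current")}
    for scen in config.scenarios:
        stacks[scen] = syn.generate_env_stack(lc, scen)
    raw_occ = syn.generate_occurrences(
        stacks["current"], truth, config.n_occ_raw, seed=stage_seed(config.seed, "synth") + 1
    )
    presences = sdm_mod.thin_occurrences(raw_occ, config.thin_cell_km)
    for name, stack in stacks.items():
        p = out / f"stack_{name}.tif"
        stack.write_tiff(p)
        files.extend([p, p.with_suffix(p.suffix + ".json")])
    p = out / "occurrences.csv"
    presences.to_csv(p)
    files.append(p)
    if done("synth"):
        return _finish(out, files, config)

    # --- screen ----------------------------------------------------------
    log.info("stage screen")
    pa = sdm_mod.sample_pseudo_absences(
        stacks["current"], presences, config.n_pseudo, seed=stage_seed(config.seed, "sdm")
    )
    pts = OccurrenceSet.concat(presences, pa)
    values = stacks["current"].values_at(pts.lon, pts.lat)
    screener = scr.CollinearityScreener(rho_max=config.rho_max, vif_max=config.vif_max)
    screener.fit(values)
    retained = screener.retained_
    p = out / "screening_report.json"
    screener.report_.to_json(p)
    files.append(p)
    if done("screen"):
        return _finish(out, files, config)

    # --- sdm -------------------------------------------------------------
    log.info("stage sdm: %d algorithms x %d repeats", len(config.algorithms or sdm_mod.model_registry()), config.repeats)
    X = values[retained].to_numpy()
    y = pts.is_presence.astype(int)
    model = sdm_mod.EnsembleSDM(
        algorithms=config.algorithms,
        train_frac=config.train_frac,
        repeats=config.repeats,
        tss_gate=config.tss_gate,
        random_state=stage_seed(config.seed, "sdm"),
    ).fit(X, y)
    p = out / "scores.json"
    p.write_text(model.all_scores_.to_json(orient="records", indent=2))
    files.append(p)
    p = out / "ensemble_spec.json"
    p.write_text(json.dumps(model.spec_json(), indent=2))
    files.append(p)
    if done("sdm"):
        return _finish(out, files, config)

    # --- tier ------------------------------------------------------------
    log.info("stage tier")
    maps = {name: model.predict_map(stack, retained) for name, stack in stacks.items()}
    areas = dyn.cell_areas(stacks["current"].geometry)
    summaries = {}
    for name, smap in maps.items():
        period, scen = _split_label(name)
        summaries[(period, scen)] = dyn.area_summary(smap, areas)
        p = out / f"suitability_{name}.tif"
        smap.write_tiff(p)
        files.extend([p, p.with_suffix(".tiers" + p.suffix), p.with_suffix(p.suffix + ".json")])
    p = out / "table1_suitable_areas.csv"
    dyn.area_table(summaries).to_csv(p, index=False)
    files.append(p)
    if done("tier"):
        return _finish(out, files, config)

    # --- change ----------------------------------------------------------
    log.info("stage change")
    changes = {}
    for name, smap in maps.items():
        if name == "current":
            continue
        period, scen = _split_label(name)
        summary, _ = dyn.overlay_change(maps["current"], smap, areas)
        changes[(period, scen)] = summary
    p = out / "table2_change.csv"
    dyn.change_table(changes).to_csv(p, index=False)
    files.append(p)
    if done("change"):
        return _finish(out, files, config)

    # --- centroid --------------------------------------------------------
    log.info("stage centroid")
    rows = []
    for scen_base in sorted({_split_label(n)[1] for n in maps if n != "current"}):
        series = [ctr.habitat_centroid(maps["current"], areas, period="current", scenario=scen_base)]
        for name in sorted(n for n in maps if n != "current" and _split_label(n)[1] == scen_base):
            period, _ = _split_label(name)
            series.append(ctr.habitat_centroid(maps[name], areas, period=period, scenario=scen_base))
        segs = ctr.build_trajectory(series)
        rows.append(ctr.trajectory_frame(segs))
        ctr.trajectory_geojson(series, out / f"trajectory_{scen_base}.geojson")
        files.append(out / f"trajectory_{scen_base}.geojson")
    p = out / "centroid_trajectories.csv"
    pd.concat(rows, ignore_index=True).to_csv(p, index=False)
    files.append(p)
    if done("centroid"):
        return _finish(out, files, config)

    # --- niche -----------------------------------------------------------
    log.info("stage niche")
    bg = nch.background_points(
        presences,
        stacks["current"],
        buffer_deg=config.buffer_deg,
        n=config.n_background,
        seed=stage_seed(config.seed, "niche"),
    )
    proj = nch.pca_env(bg[retained])
    bg_s = proj.transform(bg[retained])
    occ_now = stacks["current"].values_at(presences.lon, presences.lat)[retained]
    overlaps = {}
    for name, stack in stacks.items():
        if name == "current":
            continue
        occ_fut = stack.values_at(presences.lon, presences.lat)[retained]
        both = np.vstack([proj.transform(occ_now), proj.transform(occ_fut), bg_s])
        R = config.niche_R
        x = np.linspace(both[:, 0].min(), both[:, 0].max(), R)
        y_ax = np.linspace(both[:, 1].min(), both[:, 1].max(), R)
        g_now = _occupancy_on(proj.transform(occ_now), bg_s, x, y_ax)
        g_fut = _occupancy_on(proj.transform(occ_fut), bg_s, x, y_ax)
        overlaps[name] = nch.schoener_d(g_now, g_fut, "current", name).D
    p = out / "niche_overlap.json"
    p.write_text(json.dumps({"D": overlaps, "explained_variance_ratio": proj.explained_variance_ratio_.tolist()}, indent=2))
    files.append(p)
    if done("niche"):
        return _finish(out, files, config)

    # --- zones -----------------------------------------------------------
    log.info("stage zones")
    rng = np.random.default_rng(stage_seed(config.seed, "zones"))
    site_idx = rng.choice(len(presences), size=min(config.n_nutrition_sites, len(presences)), replace=False)
    sites = OccurrenceSet(presences.lon[site_idx], presences.lat[site_idx])
    S_sites = maps["current"].S[maps["current"].geometry.index_of(sites.lon, sites.lat)]
    table = syn.generate_nutrition_table(
        sites,
        S_sites,
        true_weights=np.array([0.4, 0.3, 0.2, 0.1]),
        noise_sd=config.nutrition_noise_sd,
        seed=stage_seed(config.seed, "zones"),
    )
    p = out / "nutrition_sites.csv"
    table.to_csv(p, index=False)
    files.append(p)
    indicators = table[[c for c in table.columns if c.startswith("indicator_")]]
    X_norm = cult.standardize(indicators)
    w = cult.entropy_weights(X_norm)
    N = cult.nutrition_index(X_norm, w)
    P = cult.site_productivity(S_sites, N)
    model_p = cult.fit_productivity_model(S_sites, P)
    p = out / "entropy_weights.json"
    p.write_text(w.to_json(indent=2))
    files.append(p)
    p = out / "model_selection.csv"
    model_p.aic_table_.to_csv(p, index=False)
    files.append(p)
    zone_maps = {}
    for name, smap in maps.items():
        period, scen = _split_label(name)
        zone_maps[(period, scen)] = cult.project_zones(model_p, smap, areas)
    p = out / "table3_cultivation_zones.csv"
    cult.zone_table(zone_maps).to_csv(p, index=False)
    files.append(p)
    return _finish(out, files, config)


def _occupancy_on(occ_s: np.ndarray, bg_s: np.ndarray, x: np.ndarray, y: np.ndarray) -> nch.NicheGrid:
    """Occupancy grid on an explicit shared lattice."""
    from scipy.stats import gaussian_kde

    R = x.size
    xx, yy = np.meshgrid(x, y)
    grid = np.vstack([xx.ravel(), yy.ravel()])
    occ_d = gaussian_kde(occ_s.T, bw_method="silverman")(grid).reshape(R, R)
    bg_d = gaussian_kde(bg_s.T, bw_method="silverman")(grid).reshape(R, R)
    bg_d /= bg_d.sum()
    occ_d /= occ_d.sum()
    z = np.where(bg_d > nch._BG_EPS, occ_d / np.clip(bg_d, nch._BG_EPS, None), 0.0)
    return nch.NicheGrid(z=z / z.sum(), background=bg_d, x_edges=x, y_edges=y)


def _split_label(name: str) -> tuple[str, str]:
    """'SSP126-2050' -> ('2050', 'SSP126'); 'current' -> ('current', '')."""
    if name == "current":
        return "current", ""
    scen, _, period = name.partition("-")
    return period or "future", scen


def _finish(out: Path, files: list[Path], config: RunConfig) -> dict:
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "files": {f.name: _sha256(f) for f in sorted(set(files))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
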