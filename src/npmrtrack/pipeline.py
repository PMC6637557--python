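"""End-to-end orchestration: prep -> extract -> fit -> validate -> evaluate.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Tracks and
fields are either read from files or simulated; the stages mirror the
analysis: behavioral-mode classification and filtering, kernel-weighted
environmental extraction with latitudinal detrending, a climatic-regime
split into building and validation sets, collinearity screening, NPMR free
search with tuning on the building set, prediction onto the validation set,
a spatial-coordinates model for comparison, TSS-based binary classification
of all four fits, and variogram diagnostics.  Every stage writes its
artifact and the manifest reconciles row counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envextract, evaluate as ev, spatial, synthetic, trackprep
from .npmr import NPMRConfig, NPMREngine, predict, sensitivity
from .synthetic import SimConfig, SwitchLink
from .trackprep import FilterConfig


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    seed: int = 0
    out_dir: str = "npmrtrack_run"
    # regime split: building years are the cool/productive phase
    building_years: tuple = (2000, 2001)
    validation_years: tuple = (2005,)
    # synthetic generation (used when tracks_csv is None)
    n_whales_per_year: int = 5
    days_per_whale: int = 100
    tracks_csv: str | None = None
    fields_nc: dict = field(default_factory=dict)     # regime -> path
    polygon_geojson: str | None = None
    # stages
    predictors: tuple = ("CHL", "SST", "DEPTH", "EASTNESS")
    detrend: tuple = ("SST",)
    min_days: float = 14.0
    min_distance_km: float = 888.0
    max_ci_radius_km: float = 100.0
    max_depth_m: float = 2000.0
    months: tuple = (7, 8, 9, 10, 11)
    collinearity_threshold: float = 0.7
    n_boot: int = 100
    n_randomizations: int = 100
    run_bootstrap: bool = True
    run_randomization: bool = True
    variogram_bin_km: float = 20.0
    variogram_max_lag_km: float = 500.0

    def year_regime(self, year: int) -> str:
        if year in tuple(self.building_years):
            return "positive"
        if year in tuple(self.validation_years):
            return "negative"
        raise KeyError(f"year {year} not covered by the regime map")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for name in ("building_years", "validation_years", "predictors",
                     "detrend", "months"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def demo_config(seed: int = 0, out_dir: str = "npmrtrack_demo") -> RunConfig:
    """Bundled synthetic end-to-end configuration (runs in minutes)."""
    return RunConfig(seed=seed, out_dir=out_dir, n_boot=25, n_randomizations=19)


def validate_config(config: RunConfig) -> list[str]:
    """All violations that would make the run fail; empty iff runnable."""
    v = []
    for name in ("min_days", "min_distance_km", "max_ci_radius_km", "max_depth_m"):
        if getattr(config, name) <= 0:
            v.append(f"non-positive threshold: {name}")
    if not config.building_years:
        v.append("no building years configured")
    overlap = set(config.building_years) & set(config.validation_years)
    if overlap:
        v.append(f"years in both regimes: {sorted(overlap)}")
    for p in config.predictors:
        base = p[2:] if p.startswith("dt") else p
        if config.fields_nc:
            for regime, path in config.fields_nc.items():
                if not Path(path).exists():
                    v.append(f"fields file for regime {regime!r} unreadable: {path}")
        elif base not in ("CHL", "SST", "DEPTH", "EASTNESS"):
            v.append(f"predictor {p!r} has no grid (simulator emits "
                     "CHL, SST, DEPTH, EASTNESS)")
    for p in config.detrend:
        if p not in config.predictors:
            v.append(f"detrend variable {p!r} not among predictors")
    if config.tracks_csv and not Path(config.tracks_csv).exists():
        v.append(f"tracks file unreadable: {config.tracks_csv}")
    if config.polygon_geojson and not Path(config.polygon_geojson).exists():
        v.append(f"polygon file unreadable: {config.polygon_geojson}")
    return v


def _load_polygon(path):
    from shapely.geometry import shape
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    return shape(gj)


def _simulate(config: RunConfig):
    """One season per configured year; fields per climatic regime."""
    tracks, fields = [], {}
    years = list(config.building_years) + list(config.validation_years)
    for k, year in enumerate(years):
        regime = config.year_regime(year)
        sim = SimConfig(
            n_whales=config.n_whales_per_year,
            days_per_whale=config.days_per_whale,
            seed=config.seed + 101 * k,
            regime=regime,
            start_date=f"{year}-06-26",
        )
        if regime not in fields:
            f_sim = SimConfig(seed=config.seed, regime=regime)
            fields[regime] = synthetic.gen_env_fields(f_sim)
        t, _ = synthetic.gen_tracks(sim, fields[regime])
        t["whale_id"] = t["whale_id"] + f"_{year}"
        tracks.append(t)
    return pd.concat(tracks, ignore_index=True), fields


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest(), "seed": config.seed, "stages": {}}
    report: dict = {}

    # -- inputs ----------------------------------------------------------
    if config.tracks_csv:
        tracks = synthetic.read_tracks(config.tracks_csv)
        fields = {regime: synthetic.read_fields(path)
                  for regime, path in config.fields_nc.items()}
    else:
        tracks, fields = _simulate(config)
    synthetic.write_tracks(tracks, out / "tracks_raw.csv")
    manifest["stages"]["input"] = {"rows": len(tracks),
                                   "whales": tracks["whale_id"].nunique()}

    polygon = _load_polygon(config.polygon_geojson) if config.polygon_geojson else None
    fcfg = FilterConfig(
        min_days=config.min_days, min_distance_km=config.min_distance_km,
        max_ci_radius_km=config.max_ci_radius_km, max_depth_m=config.max_depth_m,
        months=tuple(config.months), study_polygon=polygon)

    # -- prep ------------------------------------------------------------
    tracks["bmode_class"] = trackprep.classify_modes(tracks["bmode"])
    tracks, track_log = trackprep.filter_tracks(tracks, fcfg)
    tracks["date"] = pd.to_datetime(tracks["date"])
    tracks["year"] = tracks["date"].dt.year
    tracks["regime"] = [config.year_regime(y) for y in tracks["year"]]

    # depth must be attached before the depth rule can fire
    parts = []
    for regime, grp in tracks.groupby("regime", sort=False):
        g = envextract.extract_table(grp, fields[regime], predictors=["DEPTH"])
        parts.append(g.rename(columns={"DEPTH": "depth_m"}))
    tracks = pd.concat(parts).sort_index()

    filtered, loc_log = trackprep.filter_locations(tracks, fcfg)
    filtered.to_csv(out / "tracks_filtered.csv", index=False)
    (out / "filter_log.json").write_text(json.dumps(
        {"tracks_removed": track_log, "locations_removed": loc_log}, indent=1))
    manifest["stages"]["prep"] = {
        "rows_in": len(tracks), "rows_out": len(filtered),
        "removed": loc_log, "tracks_removed": len(track_log)}
    try:
        mstats = trackprep.movement_stats(filtered)
        report["movement_stats"] = json.loads(mstats.to_json(orient="index"))
    except ValueError:
        report["movement_stats"] = None

    # -- extract ---------------------------------------------------------
    base_predictors = sorted({p[2:] if p.startswith("dt") else p
                              for p in config.predictors} | set(config.detrend))
    parts = []
    for regime, grp in filtered.groupby("regime", sort=False):
        parts.append(envextract.extract_table(grp, fields[regime],
                                              predictors=base_predictors))
    table = pd.concat(parts).sort_index()
    if config.detrend:
        table = envextract.add_detrended(table, list(config.detrend))
    table["y"] = (table["bmode_class"] == "ARS").astype(float)
    table["split"] = np.where(table["regime"] == "positive",
                              "building", "validation")
    table.to_csv(out / "sample_table.csv", index=False)
    manifest["stages"]["extract"] = {
        "rows": len(table),
        "building": int((table["split"] == "building").sum()),
        "validation": int((table["split"] == "validation").sum())}

    building = table[table["split"] == "building"].reset_index(drop=True)
    validation = table[table["split"] == "validation"].reset_index(drop=True)
    if building.empty:
        raise RuntimeError("stage fit: building set is empty")

    npmr_cfg = NPMRConfig(seed=config.seed, n_boot=config.n_boot,
                          n_randomizations=config.n_randomizations)
    eng = NPMREngine(building, config=npmr_cfg)

    # -- collinearity screen --------------------------------------------
    candidates = [p for p in config.predictors] + \
        [f"dt{p}" for p in config.detrend if f"dt{p}" not in config.predictors]
    single_scores = {}
    for cand in candidates:
        got = eng.scan_candidate({}, (), cand, set())
        single_scores[cand] = got[0] if got else -np.inf
    retained, screen_report = envextract.collinearity_screen(
        building, candidates, single_scores, config.collinearity_threshold)
    screen_report["single_predictor_logB"] = {
        k: (None if not np.isfinite(v) else v) for k, v in single_scores.items()}
    (out / "collinearity.json").write_text(json.dumps(screen_report, indent=1))
    manifest["stages"]["screen"] = {"candidates": len(candidates),
                                    "retained": len(retained)}

    # -- environmental model ---------------------------------------------
    search = eng.free_search(retained)
    env_fit = eng.tune(search.fit)
    for p, _ in env_fit.spec.tolerances:
        env_fit.sensitivities[p] = sensitivity(env_fit, building, p)
    env_val = predict(env_fit, building, validation) if not validation.empty else None

    # -- spatial model ----------------------------------------------------
    sp_fit, anisotropy = spatial.fit_spatial_model(building, config=npmr_cfg)
    sp_val = predict(sp_fit, building, validation) if not validation.empty else None

    fits = {"environmental": {"building": env_fit.summary(),
                              "validation": env_val.summary() if env_val else None},
            "spatial": {"building": sp_fit.summary(),
                        "validation": sp_val.summary() if sp_val else None,
                        "anisotropy": anisotropy}}
    (out / "search.json").write_text(json.dumps(
        {"best_per_size": search.best_per_size, "notes": search.notes},
        indent=1, default=float))

    # -- classification ---------------------------------------------------
    classification = {}
    pairs = [("environmental_building", building, env_fit),
             ("spatial_building", building, sp_fit)]
    if env_val is not None:
        pairs += [("environmental_validation", validation, env_val),
                  ("spatial_validation", validation, sp_val)]
    for label, tab, f in pairs:
        yv = tab.loc[f.index, "y"].to_numpy(dtype=float)
        classification[label] = ev.evaluate(yv, f.estimates).to_dict()

    # -- resampling diagnostics ------------------------------------------
    resampling = {}
    if config.run_bootstrap:
        resampling["bootstrap_logB"] = {
            k: v for k, v in eng.bootstrap_logB(env_fit.spec).items()
            if k != "logB"}
    if config.run_randomization:
        rnd = eng.randomization_test(retained, env_fit.logB)
        resampling["randomization"] = {k: v for k, v in rnd.items()
                                       if k != "null_logB"}

    # -- variograms -------------------------------------------------------
    comparison = spatial.compare_models(sp_fit, env_fit, building,
                                        bin_width_km=config.variogram_bin_km,
                                        max_lag_km=config.variogram_max_lag_km)
    vg_frames = []
    for label, vg in comparison["variograms"].items():
        if vg is None:
            continue
        fr = vg.to_frame()
        fr.insert(0, "series", label)
        vg_frames.append(fr)
    if vg_frames:
        pd.concat(vg_frames, ignore_index=True).to_csv(
            out / "variograms.csv", index=False)
    report["model_comparison"] = {
        "rows_compared": comparison["rows_compared"],
        "rows_excluded": comparison["rows_excluded"],
        "mean_abs_delta_nstar": comparison["mean_abs_delta_nstar"],
        "mean_abs_delta_estimate": comparison["mean_abs_delta_estimate"]}

    report.update({"fits": fits, "classification": classification,
                   "resampling": resampling,
                   "screen": {"retained": retained}})
    (out / "summary.json").write_text(json.dumps(report, indent=1,
                                                 sort_keys=True, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True, default=float))
    return report
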