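"""Post-processing of regularized daily whale tracks.

Tracks arrive as one state-space-estimated location per day with a continuous
behavioral-mode value in [1, 2] (1 = transiting, 2 = area-restricted search)
and a posterior 95% credible-limit box per location.  This module applies the
study's filtering rules (track duration/distance, study months, study-area
polygon, location uncertainty, uncertain mode, unclassified terminal location,
seafloor depth) and computes per-mode movement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG_LAT = 111.32

#: bmode strictly below this -> transiting; strictly above MODE_ARS -> ARS
MODE_TRANSIT = 1.25
MODE_ARS = 1.75

TRACK_COLUMNS = [
    "whale_id", "date", "lon", "lat",
    "ci_lon_lo", "ci_lon_hi", "ci_lat_lo", "ci_lat_hi", "bmode",
]


def classify_mode(bmode: float) -> str:
    """Classify a continuous behavioral-mode value.

    Values above 1.75 are area-restricted search ("ARS"), values below 1.25
    are "transiting", anything in between (boundaries included) is
    "uncertain".  Raises ``ValueError`` outside [1, 2].
    """
    if not 1.0 <= bmode <= 2.0:
        raise ValueError(f"bmode {bmode!r} outside [1, 2]")
    if bmode > MODE_ARS:
        return "ARS"
    if bmode < MODE_TRANSIT:
        return "transiting"
    return "uncertain"


def classify_modes(bmode: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_mode`; missing bmode -> 'unclassified'."""
    vals = bmode.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if np.any((vals[finite] < 1.0) | (vals[finite] > 2.0)):
        raise ValueError("bmode values outside [1, 2]")
    out = np.full(vals.shape, "uncertain", dtype=object)
    out[finite & (vals > MODE_ARS)] = "ARS"
    out[finite & (vals < MODE_TRANSIT)] = "transiting"
    out[~finite] = "unclassified"
    return pd.Series(out, index=bmode.index, name="bmode_class")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a 6371-km sphere.

    Accepts scalars or array-likes (broadcast).
    """
    lat1a, lat2a = np.asarray(lat1, dtype=float), np.asarray(lat2, dtype=float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1a), np.radians(lat2a)
    dlat = p2 - p1
    dlon = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dlat / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


@dataclass
class FilterConfig:
    """Thresholds for track- and location-level filtering.

    ``min_days``/``min_distance_km`` form a disjunction at the track level: a
    track is kept if it lasts longer than ``min_days`` OR covers at least
    ``min_distance_km``.  Location-level rules are applied in a fixed order
    (months, polygon, uncertainty, uncertain mode, terminal, depth).
    """

    min_days: float = 14.0
    min_distance_km: float = 888.0
    max_ci_radius_km: float = 100.0
    max_depth_m: float = 2000.0
    months: tuple[int, ...] = (7, 8, 9, 10, 11)
    study_polygon: Polygon | None = None

    def __post_init__(self) -> None:
        for name in ("min_days", "min_distance_km", "max_ci_radius_km", "max_depth_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.study_polygon is not None and not self.study_polygon.is_valid:
            raise ValueError("study polygon invalid (self-intersecting?)")


def track_path_length_km(track: pd.DataFrame) -> float:
    """Cumulative great-circle path length of one whale's daily locations."""
    if len(track) < 2:
        return 0.0
    t = track.sort_values("date")
    lon, lat = t["lon"].to_numpy(), t["lat"].to_numpy()
    return float(np.sum(great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))


def filter_tracks(tracks: pd.DataFrame, cfg: FilterConfig):
    """Keep tracks longer than ``min_days`` OR covering >= ``min_distance_km``.

    Returns ``(retained, log)`` where the log lists each rejected track with
    its duration, path length and removal reason.
    """
    if tracks.empty:
        raise ValueError("no tracks supplied")
    keep_ids, log = [], []
    for wid, grp in tracks.groupby("whale_id", sort=False):
        dates = pd.to_datetime(grp["date"])
        duration = (dates.max() - dates.min()).days
        dist = track_path_length_km(grp)
        if duration > cfg.min_days or dist >= cfg.min_distance_km:
            keep_ids.append(wid)
        else:
            log.append({
                "whale_id": wid, "duration_d": duration,
                "distance_km": round(dist, 2), "reason": "duration-and-distance",
            })
    retained = tracks[tracks["whale_id"].isin(keep_ids)].copy()
    return retained, log


def ci_halfwidth_km(df: pd.DataFrame) -> pd.Series:
    """Larger credible-limit half-width of the two axes, in km at each latitude."""
    hw_lon_deg = (df["ci_lon_hi"] - df["ci_lon_lo"]).to_numpy() / 2.0
    hw_lat_deg = (df["ci_lat_hi"] - df["ci_lat_lo"]).to_numpy() / 2.0
    coslat = np.cos(np.radians(df["lat"].to_numpy()))
    hw_km = np.maximum(hw_lon_deg * KM_PER_DEG_LAT * coslat,
                       hw_lat_deg * KM_PER_DEG_LAT)
    return pd.Series(hw_km, index=df.index, name="ci_halfwidth_km")


# location filter rules, applied in this order; names appear in removal logs
LOCATION_RULES = ("month", "polygon", "ci_radius", "uncertain", "terminal", "depth")


def filter_locations(track: pd.DataFrame, cfg: FilterConfig):
    """Apply the location-level exclusion rules to a (multi-)track table.

    Rules, in order: study months; study-area polygon (boundary counts as
    inside); credible-limit half-width above ``max_ci_radius_km``; uncertain
    behavioral mode; unclassified terminal locations (last-dated point of a
    track with missing bmode); seafloor depth beyond ``max_depth_m`` (only
    where a ``depth_m`` column is attached).  Returns ``(retained, log)``
    with per-rule removal counts; counts plus retained rows equal the input.
    """
    df = track.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "bmode_class" not in df.columns:
        df["bmode_class"] = classify_modes(df["bmode"])
    log = {rule: 0 for rule in LOCATION_RULES}

    mask = ~df["date"].dt.month.isin(cfg.months)
    log["month"] = int(mask.sum())
    df = df[~mask]

    if cfg.study_polygon is not None and not df.empty:
        poly = prep(cfg.study_polygon)
        inside = np.fromiter(
            (poly.intersects(Point(x, y)) for x, y in zip(df["lon"], df["lat"])),
            dtype=bool, count=len(df))
        log["polygon"] = int((~inside).sum())
        df = df[inside]

    if not df.empty:
        mask = ci_halfwidth_km(df) > cfg.max_ci_radius_km
        log["ci_radius"] = int(mask.sum())
        df = df[~mask]

    mask = df["bmode_class"] == "uncertain"
    log["uncertain"] = int(mask.sum())
    df = df[~mask]

    # terminal: last-dated location of each track, identifiable by its
    # missing behavioral classification (keeps the rule idempotent)
    if not df.empty:
        last = df.groupby("whale_id")["date"].transform("max") == df["date"]
        mask = last & (df["bmode_class"] == "unclassified")
        log["terminal"] = int(mask.sum())
        df = df[~mask]
    # any remaining unclassified rows also lack a usable response
    mask = df["bmode_class"] == "unclassified"
    log["terminal"] += int(mask.sum())
    df = df[~mask]

    if "depth_m" in df.columns and not df.empty:
        mask = df["depth_m"].to_numpy(dtype=float) > cfg.max_depth_m
        log["depth"] = int(mask.sum())
        df = df[~mask]

    return df, log


def movement_stats(points: pd.DataFrame) -> pd.DataFrame:
    """Daily displacement (km) and speed (km/h) between consecutive locations.

    Pairs are formed within a whale between locations exactly one day apart;
    each pair is attributed to the behavioral mode of its earlier point.
    Returns a table indexed by mode (plus ``overall``) with mean/median
    distance and speed and the pair count.  Raises if no pair qualifies.
    """
    rows = []
    for wid, grp in points.groupby("whale_id", sort=False):
        g = grp.sort_values("date")
        dates = pd.to_datetime(g["date"]).to_numpy()
        if len(g) < 2:
            continue
        gap_days = (dates[1:] - dates[:-1]) / np.timedelta64(1, "D")
        lon, lat = g["lon"].to_numpy(), g["lat"].to_numpy()
        dist = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        mode = (g["bmode_class"].to_numpy() if "bmode_class" in g.columns
                else classify_modes(g["bmode"]).to_numpy())
        ok = gap_days == 1.0
        rows.append(pd.DataFrame({"mode": mode[:-1][ok], "distance_km": dist[ok]}))
    if not rows:
        raise ValueError("no consecutive daily pairs")
    pairs = pd.concat(rows, ignore_index=True)
    if pairs.empty:
        raise ValueError("no consecutive daily pairs")
    pairs["speed_kmh"] = pairs["distance_km"] / 24.0

    def summarize(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "n_pairs": len(g),
            "mean_distance_km": g["distance_km"].mean(),
            "median_distance_km": g["distance_km"].median(),
            "mean_speed_kmh": g["speed_kmh"].mean(),
            "median_speed_kmh": g["speed_kmh"].median(),
        })

    by_mode = pairs.groupby("mode").apply(summarize, include_groups=False)
    overall = summarize(pairs).to_frame().T
    overall.index = pd.Index(["overall"], name="mode")
    return pd.concat([by_mode, overall])
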