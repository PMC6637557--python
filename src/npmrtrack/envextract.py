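"""Attach gridded environmental predictors to track locations.

Location uncertainty is propagated into the extraction: each predictor value
is a kernel-weighted average of the grid cells whose centers fall inside the
location's posterior 95% credible-limit box, with weights tapering smoothly
from 1 at the estimated location to 0 at the farthest box corner (a Bézier
profile; the quartic bump (1 - (d/d_max)^2)^2 by default).  Variables with a
basin-scale latitudinal trend (temperature, sea-surface height) can be
detrended by a locally linear loess fit on latitude, yielding "spatial
anomaly" predictors.  A pairwise-correlation screen drops the weaker member
of redundant predictor pairs.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
import xarray as xr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .trackprep import great_circle_km


def bezier_quartic(u: np.ndarray) -> np.ndarray:
    """Default kernel profile: (1 - u^2)^2 on u = d/d_max in [0, 1]."""
    return (1.0 - u ** 2) ** 2


def _nearest_time_index(time_vals: np.ndarray, when: np.datetime64):
    """Nearest slice index, or None if beyond one compositing period."""
    t = np.asarray(time_vals, dtype="datetime64[ns]")
    diffs = np.abs((t - np.datetime64(when, "ns")) / np.timedelta64(1, "D"))
    i = int(np.argmin(diffs))
    if t.size > 1:
        period = float(np.median(np.diff(t) / np.timedelta64(1, "D")))
    else:
        period = np.inf
    return i if diffs[i] <= period else None


def kernel_weighted_extract(point, grid: xr.DataArray,
                            profile: Callable[[np.ndarray], np.ndarray] = bezier_quartic):
    """Credible-box kernel-weighted average of one grid variable.

    ``point`` is a mapping (e.g. a track-table row) with lon, lat, the
    credible limits, and — for time-resolved grids — a ``date``.  Cells
    belong to the box if their center satisfies lo <= c < hi on each axis
    (half-open on the east/north edges).  Weight w(d) = profile(d / d_max)
    with d the great-circle distance from cell center to the location and
    d_max the distance to the farthest box corner.  Returns NaN iff no
    non-missing cell center lies inside the box.
    """
    lon0, lat0 = float(point["lon"]), float(point["lat"])
    lo_x, hi_x = float(point["ci_lon_lo"]), float(point["ci_lon_hi"])
    lo_y, hi_y = float(point["ci_lat_lo"]), float(point["ci_lat_hi"])

    if "time" in grid.dims:
        i = _nearest_time_index(grid["time"].values,
                                np.datetime64(pd.Timestamp(point["date"])))
        if i is None:
            return np.nan
        grid = grid.isel(time=i)

    lon_ax = grid["lon"].values
    lat_ax = grid["lat"].values
    sel_x = (lon_ax >= lo_x) & (lon_ax < hi_x)
    sel_y = (lat_ax >= lo_y) & (lat_ax < hi_y)
    if not sel_x.any() or not sel_y.any():
        return np.nan
    sub = grid.values[np.ix_(sel_y, sel_x)]
    lons = lon_ax[sel_x]
    lats = lat_ax[sel_y]
    ok = np.isfinite(sub)
    if not ok.any():
        return np.nan

    corners = [(lo_x, lo_y), (lo_x, hi_y), (hi_x, lo_y), (hi_x, hi_y)]
    d_max = max(great_circle_km(lon0, lat0, cx, cy) for cx, cy in corners)
    lon2d, lat2d = np.meshgrid(lons, lats)
    if d_max <= 0:
        return float(np.nanmean(sub))
    d = great_circle_km(lon0, lat0, lon2d, lat2d)
    w = profile(np.clip(d / d_max, 0.0, 1.0))
    w = np.where(ok, w, 0.0)
    sw = w.sum()
    if sw <= 0:  # only corner-distance cells contribute: fall back to flat mean
        return float(np.nanmean(sub))
    return float(np.nansum(w * np.where(ok, sub, 0.0)) / sw)


def extract_table(points: pd.DataFrame, fields: xr.Dataset,
                  predictors: list[str] | None = None,
                  profile=bezier_quartic) -> pd.DataFrame:
    """Kernel-extract every predictor for every location.

    Returns ``points`` with one new column per predictor (NaN where the box
    holds no usable cells).
    """
    predictors = list(fields.data_vars) if predictors is None else predictors
    out = points.copy()
    for name in predictors:
        grid = fields[name]
        out[name] = [kernel_weighted_extract(row, grid, profile=profile)
                     for _, row in points.iterrows()]
    return out


def detrend_latitude(values, lats, degree: int = 1, span: float = 0.75):
    """Latitudinal anomalies: value minus a loess trend fitted on latitude.

    Locally linear fit with tricube weighting, neighborhood fraction
    ``span``.  Only degree 1 is supported.  Missing values are preserved;
    requires at least 10 non-missing pairs.
    """
    if degree != 1:
        raise NotImplementedError("only locally linear (degree=1) loess is supported")
    v = np.asarray(values, dtype=float)
    x = np.asarray(lats, dtype=float)
    ok = np.isfinite(v) & np.isfinite(x)
    if ok.sum() == 0:
        raise ValueError("all values missing")
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing (value, latitude) pairs")
    fitted = lowess(v[ok], x[ok], frac=span, it=0, return_sorted=False)
    out = np.full(v.shape, np.nan)
    out[ok] = v[ok] - fitted
    return out


def add_detrended(table: pd.DataFrame, columns: list[str],
                  lat_col: str = "lat", prefix: str = "dt") -> pd.DataFrame:
    """Append loess-detrended variants (e.g. SST -> dtSST) to a table."""
    out = table.copy()
    for col in columns:
        out[prefix + col] = detrend_latitude(out[col].to_numpy(),
                                             out[lat_col].to_numpy())
    return out


def collinearity_screen(table: pd.DataFrame, predictors: list[str],
                        single_predictor_scores: dict[str, float],
                        threshold: float = 0.7):
    """Iteratively drop the weaker member of each redundant predictor pair.

    Pearson r is computed on pairwise-complete observations (>= 3 pairs
    required, else the pair is not flagged).  While any retained pair has
    |r| >= threshold, the pair with the largest |r| loses its member with
    the lower single-predictor logB.  Zero-variance predictors are dropped
    as degenerate.  Returns ``(retained, report)`` where the report lists
    flagged pairs and dropped predictors with reasons.
    """
    retained = list(predictors)
    report = {"flagged_pairs": [], "dropped": []}

    for p in list(retained):
        col = table[p].dropna()
        if col.nunique() <= 1:
            retained.remove(p)
            report["dropped"].append({"predictor": p, "reason": "degenerate"})

    def corr(a: str, b: str):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            return np.nan
        return float(sub[a].corr(sub[b]))

    while True:
        worst, worst_r = None, threshold
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = corr(a, b)
                if np.isfinite(r) and abs(r) >= worst_r:
                    worst, worst_r = (a, b), abs(r)
        if worst is None:
            break
        a, b = worst
        drop = a if single_predictor_scores.get(a, -np.inf) <= \
            single_predictor_scores.get(b, -np.inf) else b
        keep = b if drop == a else a
        report["flagged_pairs"].append({"pair": [a, b], "abs_r": round(worst_r, 4),
                                        "kept": keep, "dropped": drop})
        report["dropped"].append({"predictor": drop,
                                  "reason": f"|r|>={threshold} with {keep}"})
        retained.remove(drop)
    return retained, report
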