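"""Spatial-coordinates model and variogram autocorrelation diagnostics.

A purely spatial (longitude x latitude) NPMR model captures the geographic
clustering of the behavioral response; comparing its neighborhood sizes,
predictions and their empirical variograms with the environmental model's
shows how much of the apparent environmental signal is spatial structure.
Tolerances of the two coordinate axes, as percentages of their ranges, give
the anisotropy of the behavioral field (the published fits show a 1:2
longitude:latitude anisotropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .npmr import NPMRConfig, NPMREngine, NPMRFit, ModelSpec, tolerance_pct
from .trackprep import great_circle_km


@dataclass
class Variogram:
    """Classical (Matheron) sample semivariogram over great-circle lags."""

    lag_km: np.ndarray      # bin centers
    gamma: np.ndarray       # semivariance per bin (NaN where empty)
    n_pairs: np.ndarray
    bin_width_km: float
    max_lag_km: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_km": self.lag_km, "gamma": self.gamma,
                             "n_pairs": self.n_pairs})

    @property
    def sill_estimate(self) -> float:
        ok = np.isfinite(self.gamma) & (self.n_pairs > 0)
        if not ok.any():
            return np.nan
        return float(np.average(self.gamma[ok], weights=self.n_pairs[ok]))


def fit_spatial_model(table: pd.DataFrame, config: NPMRConfig | None = None,
                      lon_col: str = "lon", lat_col: str = "lat",
                      y_col: str = "y", tune: bool = True):
    """Fit the longitude x latitude NPMR model (both predictors forced).

    The tolerance grid is scanned exhaustively over the two axes, then
    refined coordinate-wise.  Returns ``(fit, anisotropy)`` where
    anisotropy maps each axis to its tolerance as a percent of range plus
    the lon:lat ratio.
    """
    eng = NPMREngine(table, y_col=y_col, config=config)
    cfg = eng.config
    rng_x = eng.predictor_range(lon_col)
    rng_y = eng.predictor_range(lat_col)
    best = None
    for fx in sorted(cfg.tolerance_grid, reverse=True):
        for fy in sorted(cfg.tolerance_grid, reverse=True):
            spec = ModelSpec.of({lon_col: fx * rng_x, lat_col: fy * rng_y})
            try:
                f = eng.fit(spec)
            except ValueError:
                continue
            if best is None or f.logB > best.logB + 1e-12:
                best = f
    if best is None:
        raise ValueError("no tolerance pair produced a populated fit")
    if tune:
        best = eng.tune(best)
    pct_x = tolerance_pct(dict(best.spec.tolerances)[lon_col], rng_x)
    pct_y = tolerance_pct(dict(best.spec.tolerances)[lat_col], rng_y)
    anisotropy = {lon_col: pct_x, lat_col: pct_y,
                  "lon_lat_ratio": pct_x / pct_y if pct_y else np.nan}
    return best, anisotropy


def empirical_variogram(lons, lats, values, bin_width_km: float = 20.0,
                        max_lag_km: float = 500.0) -> Variogram:
    """gamma(h) = (1/2N(h)) sum (z_i - z_j)^2 over pairs binned by distance.

    Pair distances are great-circle km; pairs beyond ``max_lag_km`` are
    ignored; missing values are dropped (at least 2 required).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    z = np.asarray(values, dtype=float)
    ok = np.isfinite(z) & np.isfinite(lons) & np.isfinite(lats)
    lons, lats, z = lons[ok], lats[ok], z[ok]
    if z.size < 2:
        raise ValueError("need at least 2 points with non-missing values")

    i, j = np.triu_indices(z.size, k=1)
    d = great_circle_km(lons[i], lats[i], lons[j], lats[j])
    in_range = d < max_lag_km
    d = d[in_range]
    dz2 = (z[i[in_range]] - z[j[in_range]]) ** 2

    edges = np.arange(0.0, max_lag_km + bin_width_km, bin_width_km)
    which = np.digitize(d, edges) - 1
    nbins = edges.size - 1
    counts = np.bincount(which, minlength=nbins)[:nbins]
    sums = np.bincount(which, weights=dz2, minlength=nbins)[:nbins]
    gamma = np.full(nbins, np.nan)
    nz = counts > 0
    gamma[nz] = sums[nz] / (2.0 * counts[nz])
    centers = edges[:-1] + bin_width_km / 2.0
    return Variogram(lag_km=centers, gamma=gamma, n_pairs=counts,
                     bin_width_km=bin_width_km, max_lag_km=max_lag_km)


def variogram_range_km(vg: Variogram, sill: float, frac: float = 0.95) -> float:
    """Lag at which semivariance first reaches ``frac`` of the sill.

    The crossing is linearly interpolated between the bracketing bin
    centers (taking the first bin center when the first populated bin is
    already above the threshold), which removes most of the bin-width
    discretization bias.  Pass the sample variance of the values as the
    sill.  Returns NaN when no populated bin reaches the threshold.
    """
    ok = np.isfinite(vg.gamma) & (vg.n_pairs > 0)
    lag = vg.lag_km[ok]
    g = vg.gamma[ok]
    target = frac * sill
    above = g >= target
    if not above.any():
        return np.nan
    k = int(np.argmax(above))
    if k == 0:
        return float(lag[0])
    x0, x1 = lag[k - 1], lag[k]
    y0, y1 = g[k - 1], g[k]
    if y1 == y0:
        return float(x1)
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def compare_models(spatial_fit: NPMRFit, env_fit: NPMRFit,
                   table: pd.DataFrame,
                   lon_col: str = "lon", lat_col: str = "lat",
                   bin_width_km: float = 20.0, max_lag_km: float = 500.0) -> dict:
    """Per-row differences and variograms of n* and estimates for two fits.

    Rows must overlap between the fits; rows with a missing estimate in
    either model are excluded from the differences and counted.
    """
    common = spatial_fit.index.intersection(env_fit.index)
    if len(common) == 0:
        raise ValueError("the two fits share no rows")
    s_pos = pd.Series(np.arange(len(spatial_fit.index)), index=spatial_fit.index)
    e_pos = pd.Series(np.arange(len(env_fit.index)), index=env_fit.index)
    s_est = spatial_fit.estimates[s_pos[common].to_numpy()]
    e_est = env_fit.estimates[e_pos[common].to_numpy()]
    s_ns = spatial_fit.nstar[s_pos[common].to_numpy()]
    e_ns = env_fit.nstar[e_pos[common].to_numpy()]
    ok = np.isfinite(s_est) & np.isfinite(e_est)

    lons = table.loc[common, lon_col].to_numpy(dtype=float)
    lats = table.loc[common, lat_col].to_numpy(dtype=float)
    vg = {}
    for label, vals in (("spatial_nstar", s_ns), ("env_nstar", e_ns),
                        ("spatial_estimate", s_est), ("env_estimate", e_est)):
        try:
            vg[label] = empirical_variogram(lons, lats, vals,
                                            bin_width_km, max_lag_km)
        except ValueError:
            vg[label] = None
    return {
        "rows_compared": int(ok.sum()),
        "rows_excluded": int(len(common) - ok.sum()),
        "delta_nstar": s_ns[ok] - e_ns[ok],
        "delta_estimate": s_est[ok] - e_est[ok],
        "mean_abs_delta_nstar": float(np.mean(np.abs(s_ns[ok] - e_ns[ok]))) if ok.any() else np.nan,
        "mean_abs_delta_estimate": float(np.mean(np.abs(s_est[ok] - e_est[ok]))) if ok.any() else np.nan,
        "variograms": vg,
    }
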