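"""Synthetic tracks and ocean fields with known ground truth.

Every downstream stage of the pipeline (filtering, kernel extraction, NPMR
fitting, classification, variograms) is exercised against data produced here,
where the generative link between local environment and area-restricted-search
(ARS) behavior is known exactly.  The simulator emulates:

* daily locations from a two-state correlated random walk — transiting with
  persistent heading and mean daily displacement 81.5 km, ARS with
  near-uniform turning and mean 27.3 km;
* a continuous behavioral-mode value in [1, 2] whose thresholding at
  1.25/1.75 recovers the true state on the ~90% of locations drawn outside
  the deliberately "uncertain" band;
* rectangular posterior credible-limit boxes with gamma-distributed
  half-widths;
* gridded fields: lognormal chlorophyll (CHL), temperature (SST) with a
  deterministic latitudinal trend plus a spatially correlated anomaly, a
  static depth ramp with a shelf (DEPTH), and slope eastness in [-1, 1]
  (EASTNESS); a configurable fraction of dynamic-field cells is missing,
  emulating cloud cover;
* a "warm regime" switch (negative North Pacific Gyre Oscillation phase):
  warmer SST, depressed CHL, hence reduced ARS probability through the link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .trackprep import KM_PER_DEG_LAT, TRACK_COLUMNS

# distance (km) at which the semivariance of a simulated field first reaches
# 95% of its sill equals the configured correlation range; for a Gaussian
# covariance produced by kernel smoothing this fixes kernel sd = range/3.4616
_RANGE_TO_KERNEL_SD = 1.0 / (2.0 * np.sqrt(np.log(20.0)))


@dataclass(frozen=True)
class SwitchLink:
    """Named response function: local predictor values -> P(ARS) per day.

    Kinds:
      ``constant``       params: p
      ``logistic``       params: predictor, midpoint, slope, lo, hi
      ``gaussian_bump``  params: predictor, optimum, width, lo, hi
    """

    kind: str = "logistic"
    params: dict = field(default_factory=lambda: {
        "predictor": "CHL", "midpoint": 0.65, "slope": 4.0, "lo": 0.08, "hi": 0.92})

    def prob(self, env: dict[str, float]) -> float:
        p = self.params
        if self.kind == "constant":
            val = p["p"]
        elif self.kind == "logistic":
            x = env[p["predictor"]]
            val = p["lo"] + (p["hi"] - p["lo"]) / (
                1.0 + np.exp(-p["slope"] * (x - p["midpoint"])))
        elif self.kind == "gaussian_bump":
            x = env[p["predictor"]]
            val = p["lo"] + (p["hi"] - p["lo"]) * np.exp(
                -((x - p["optimum"]) / p["width"]) ** 2)
        else:
            raise ValueError(f"unknown switch link kind {self.kind!r}")
        return float(np.clip(val, 0.0, 1.0))


@dataclass
class SimConfig:
    """Study conditions for one simulated deployment season."""

    n_whales: int = 10
    days_per_whale: int = 110
    seed: int = 0
    step_mean_transit: float = 81.5   # km/day
    step_mean_ars: float = 27.3       # km/day
    switch_link: SwitchLink = field(default_factory=SwitchLink)
    regime: str = "positive"          # NPGO phase: positive (cool) / negative (warm)
    grid_extent: tuple[float, float, float, float] = (-129.0, -117.0, 30.0, 49.0)
    grid_resolution: float = 0.25     # degrees
    field_range_km: float = 100.0     # spatial correlation range of anomalies
    missing_fraction: float = 0.15    # cloud cover on dynamic fields
    ci_halfwidth_mean_km: float = 30.0
    ci_halfwidth_shape: float = 4.0   # gamma shape of credible half-widths
    start_date: str = "2000-06-26"
    uncertain_fraction: float = 0.10  # bmode drawn inside the uncertain band
    step_shape: float = 4.0           # gamma shape of daily step lengths
    heading_kappa_transit: float = 8.0  # wrapped-normal-ish persistence

    def __post_init__(self) -> None:
        if not self.step_mean_transit > self.step_mean_ars > 0:
            raise ValueError("require step_mean_transit > step_mean_ars > 0")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        lo_x, hi_x, lo_y, hi_y = self.grid_extent
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ValueError("degenerate grid extent")
        if self.regime not in ("positive", "negative"):
            raise ValueError("regime must be 'positive' or 'negative'")


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    states: list            # per retained location: 1 transiting / 2 ARS
    p_ars: list             # per-location P(ARS) actually used for the draw
    link_kind: str
    link_params: dict
    field_range_km: float
    regime: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def correlated_field(shape, sigma_cells, rng) -> np.ndarray:
    """Unit-variance Gaussian random field via kernel-smoothed white noise.

    ``sigma_cells`` may be a (sigma_y, sigma_x) pair for anisotropic grids
    (so the correlation range is isotropic in km on a lon/lat grid).  A
    sigma of 0 returns plain white noise.
    """
    z = rng.standard_normal(shape)
    if np.all(np.asarray(sigma_cells) <= 0):
        return z
    f = gaussian_filter(z, sigma=sigma_cells, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _axes(config: SimConfig):
    lo_x, hi_x, lo_y, hi_y = config.grid_extent
    res = config.grid_resolution
    lon = np.arange(lo_x + res / 2.0, hi_x, res)
    lat = np.arange(lo_y + res / 2.0, hi_y, res)
    return lon, lat


def gen_env_fields(config: SimConfig) -> xr.Dataset:
    """Generate the predictor grids for one season.

    SST carries a deterministic linear latitudinal trend (−0.5 °C per degree
    of latitude northward) plus a correlated anomaly; CHL is lognormal over a
    correlated field; DEPTH is a static shelf-to-abyss ramp deepening away
    from the eastern (coastal) boundary; EASTNESS is a squashed correlated
    field in [−1, 1].  The negative (warm) regime adds 2 °C and halves
    median CHL.  ``missing_fraction`` of CHL and SST cells are NaN.
    """
    lon, lat = _axes(config)
    if lon.size == 0 or lat.size == 0:
        raise ValueError("degenerate grid extent for the given resolution")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lat_mid = float(lat.mean())
    km_x = KM_PER_DEG_LAT * np.cos(np.radians(lat_mid)) * config.grid_resolution
    km_y = KM_PER_DEG_LAT * config.grid_resolution
    s_km = config.field_range_km * _RANGE_TO_KERNEL_SD
    sigma = (s_km / km_y, s_km / km_x) if config.field_range_km > 0 else (0.0, 0.0)
    shape = (lat.size, lon.size)

    warm = config.regime == "negative"
    lat2d = lat[:, None] * np.ones((1, lon.size))
    lon2d = np.ones((lat.size, 1)) * lon[None, :]

    chl_mu = np.log(0.45 if warm else 1.0)
    chl = np.exp(chl_mu + 0.9 * correlated_field(shape, sigma, rng))

    sst_trend = 22.0 - 0.5 * (lat2d - config.grid_extent[2])
    sst = sst_trend + (2.0 if warm else 0.0) + 0.8 * correlated_field(shape, sigma, rng)

    # shelf: shallow within ~1 deg of the eastern boundary, ramping to abyss
    off_coast = config.grid_extent[1] - lon2d
    depth = 30.0 + 3970.0 / (1.0 + np.exp(-(off_coast - 1.8) / 0.45))

    eastness = np.tanh(1.2 * correlated_field(shape, sigma, rng))

    if config.missing_fraction > 0:
        for arr in (chl, sst):
            cloud = rng.random(shape) < config.missing_fraction
            arr[cloud] = np.nan

    ds = xr.Dataset(
        {
            "CHL": (("lat", "lon"), chl, {"units": "mg m-3"}),
            "SST": (("lat", "lon"), sst, {"units": "degC"}),
            "DEPTH": (("lat", "lon"), depth, {"units": "m"}),
            "EASTNESS": (("lat", "lon"), eastness, {"units": "1"}),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"regime": config.regime, "field_range_km": config.field_range_km,
               "sst_lat_slope": -0.5},
    )
    return ds


def sample_env(fields: xr.Dataset, lon: float, lat: float) -> dict[str, float]:
    """Nearest-cell predictor values; NaN cells fall back to a 3x3 mean,
    then to the field median (the simulator needs a defined link input)."""
    out = {}
    ilat = int(np.clip(np.searchsorted(fields["lat"].values, lat), 1,
                       fields.sizes["lat"] - 1))
    ilon = int(np.clip(np.searchsorted(fields["lon"].values, lon), 1,
                       fields.sizes["lon"] - 1))
    if abs(fields["lat"].values[ilat - 1] - lat) < abs(fields["lat"].values[ilat] - lat):
        ilat -= 1
    if abs(fields["lon"].values[ilon - 1] - lon) < abs(fields["lon"].values[ilon] - lon):
        ilon -= 1
    for name, da in fields.data_vars.items():
        v = float(da.values[ilat, ilon])
        if np.isnan(v):
            sl = da.values[max(ilat - 1, 0):ilat + 2, max(ilon - 1, 0):ilon + 2]
            v = float(np.nanmean(sl)) if np.isfinite(sl).any() else float(
                np.nanmedian(da.values))
        out[name] = v
    return out


def gen_tracks(config: SimConfig, fields: xr.Dataset):
    """Simulate daily tracks over the fields.

    Each day the whale is in ARS with probability ``switch_link`` evaluated
    at its current location, then takes a gamma step (mean per state) with a
    persistent heading while transiting and near-uniform turning in ARS.
    The terminal location of every track carries a missing behavioral-mode
    value (it receives no classification), matching the input contract of
    the filtering stage.  Returns ``(tracks, truth)``.
    """
    link = config.switch_link
    for need in _link_predictors(link):
        if need not in fields.data_vars:
            raise KeyError(f"fields missing predictor {need!r} required by the link")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    lo_x, hi_x, lo_y, hi_y = config.grid_extent
    start = pd.Timestamp(config.start_date)
    shelf_ok = fields["DEPTH"].values < 1500.0
    lat_idx, lon_idx = np.nonzero(shelf_ok)

    rows, states, probs = [], [], []
    for w in range(config.n_whales):
        k = rng.integers(lat_idx.size)
        lat = float(fields["lat"].values[lat_idx[k]])
        lon = float(fields["lon"].values[lon_idx[k]])
        heading = rng.uniform(0, 2 * np.pi)
        wid = f"whale_{w:02d}"
        for d in range(config.days_per_whale):
            env = sample_env(fields, lon, lat)
            p_ars = link.prob(env)
            ars = rng.random() < p_ars
            state = 2 if ars else 1
            terminal = d == config.days_per_whale - 1
            if terminal:
                bmode = np.nan
            elif rng.random() < config.uncertain_fraction:
                bmode = rng.uniform(1.25, 1.75)
            elif ars:
                bmode = 2.0 - rng.uniform(0.0, 0.2)
            else:
                bmode = 1.0 + rng.uniform(0.0, 0.2)
            hw_lon = rng.gamma(config.ci_halfwidth_shape,
                               config.ci_halfwidth_mean_km / config.ci_halfwidth_shape)
            hw_lat = rng.gamma(config.ci_halfwidth_shape,
                               config.ci_halfwidth_mean_km / config.ci_halfwidth_shape)
            dlon_ci = hw_lon / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
            dlat_ci = hw_lat / KM_PER_DEG_LAT
            rows.append((wid, (start + pd.Timedelta(days=d)).date().isoformat(),
                         lon, lat, lon - dlon_ci, lon + dlon_ci,
                         lat - dlat_ci, lat + dlat_ci, bmode))
            states.append(state)
            probs.append(p_ars)

            mean = config.step_mean_ars if ars else config.step_mean_transit
            step = rng.gamma(config.step_shape, mean / config.step_shape)
            if ars:
                heading = rng.uniform(0, 2 * np.pi)
            else:
                heading = heading + rng.normal(0.0, 1.0 / np.sqrt(
                    config.heading_kappa_transit))
            # bounce the heading off the extent edges so the full step
            # length is realized inside the fields (folding the endpoint
            # would systematically shorten observed displacements)
            for _ in range(8):
                dx = step * np.cos(heading)
                dy = step * np.sin(heading)
                lon2 = lon + dx / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
                lat2 = lat + dy / KM_PER_DEG_LAT
                if lo_x <= lon2 <= hi_x and lo_y <= lat2 <= hi_y:
                    break
                if lon2 < lo_x or lon2 > hi_x:
                    heading = np.pi - heading
                if lat2 < lo_y or lat2 > hi_y:
                    heading = -heading
            lon = float(np.clip(lon2, lo_x, hi_x))
            lat = float(np.clip(lat2, lo_y, hi_y))

    tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    truth = GroundTruth(states=states, p_ars=probs, link_kind=link.kind,
                        link_params=dict(link.params),
                        field_range_km=config.field_range_km,
                        regime=config.regime)
    return tracks, truth


def _link_predictors(link: SwitchLink) -> tuple[str, ...]:
    return ((link.params["predictor"],) if "predictor" in link.params else ())


# ---------------------------------------------------------------------------
# printed-table fixtures

def fixture_confusion_tables():
    """The four published confusion matrices, ordered (tn, fp, fn, tp).

    Cells are (true absence predicted absent, true absence predicted present,
    true presence predicted absent, true presence predicted present) for the
    environmental and spatial-coordinates models on the building and
    validation sets.
    """
    from .evaluate import ConfusionMatrix
    return [
        ("environmental_building", ConfusionMatrix(tn=149, fp=77, fn=401, tp=665)),
        ("environmental_validation", ConfusionMatrix(tn=17, fp=47, fn=12, tp=112)),
        ("spatial_building", ConfusionMatrix(tn=113, fp=45, fn=404, tp=696)),
        ("spatial_validation", ConfusionMatrix(tn=83, fp=39, fn=59, tp=146)),
    ]


def fixture_filter_track():
    """A deterministic 30-location toy track with known rule violations.

    Returns ``(track, polygon, expected_log, expected_retained)`` where
    ``expected_log`` gives the per-rule removal counts the location filter
    must report: 5 June dates, 3 outside the polygon, 4 over-wide credible
    boxes, 3 uncertain modes, 1 unclassified terminal, 2 deep locations,
    leaving 12 retained.
    """
    from shapely.geometry import Polygon

    n = 30
    dates = pd.date_range("2001-06-26", periods=n, freq="D")
    lon = np.full(n, -123.0)
    lat = np.full(n, 36.0)
    bmode = np.full(n, 1.9)
    depth = np.full(n, 500.0)
    hw_lon = np.full(n, 0.2)   # ~18 km at 36N
    hw_lat = np.full(n, 0.2)

    lon[[7, 12, 18]] = -130.0                  # outside polygon
    hw_lat[[8, 13, 20, 22]] = 1.5              # ~167 km half-width
    bmode[[9, 15, 24]] = 1.5                   # uncertain band
    bmode[29] = np.nan                         # unclassified terminal
    depth[[10, 26]] = 2500.0                   # beyond the 2000-m rule

    track = pd.DataFrame({
        "whale_id": "toy", "date": dates.date.astype(str),
        "lon": lon, "lat": lat,
        "ci_lon_lo": lon - hw_lon, "ci_lon_hi": lon + hw_lon,
        "ci_lat_lo": lat - hw_lat, "ci_lat_hi": lat + hw_lat,
        "bmode": bmode, "depth_m": depth,
    })
    polygon = Polygon([(-126, 33), (-120, 33), (-120, 40), (-126, 40)])
    expected_log = {"month": 5, "polygon": 3, "ci_radius": 4,
                    "uncertain": 3, "terminal": 1, "depth": 2}
    return track, polygon, expected_log, n - sum(expected_log.values())


# ---------------------------------------------------------------------------
# plain-text I/O

def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    return df


def write_fields(fields: xr.Dataset, path) -> None:
    fields.to_netcdf(path, engine="scipy")


def read_fields(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()
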