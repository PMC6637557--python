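"""Kernel-weighted box extraction, loess detrending, collinearity screen."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import npmrtrack as nt
from npmrtrack.envextract import add_detrended, extract_table


def _grid(values, lons, lats, name="V"):
    return xr.DataArray(np.asarray(values, dtype=float),
                        coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"), name=name)


def _point(lon, lat, hw_lon, hw_lat, date="2001-08-01"):
    return {"lon": lon, "lat": lat, "date": date,
            "ci_lon_lo": lon - hw_lon, "ci_lon_hi": lon + hw_lon,
            "ci_lat_lo": lat - hw_lat, "ci_lat_hi": lat + hw_lat}


class TestKernelExtract:
    def test_constant_field_returns_constant(self):
        g = _grid(np.full((5, 5), 3.25), np.linspace(-1, 1, 5),
                  np.linspace(-1, 1, 5))
        v = nt.kernel_weighted_extract(_point(0.0, 0.0, 0.9, 0.9), g)
        assert v == pytest.approx(3.25, abs=1e-12)

    def test_single_contributor_returns_center_value(self):
        vals = np.full((3, 3), np.nan)
        vals[1, 1] = 7.5
        g = _grid(vals, [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        v = nt.kernel_weighted_extract(_point(0.0, 0.0, 1.4, 1.4), g)
        assert v == pytest.approx(7.5, abs=1e-12)

    def test_quartic_taper_hand_value(self):
        # cells at d/d_max = 0, 0.5, 1.0 with values 10, 20, 30:
        # (1*10 + 0.5625*20 + 0*30) / 1.5625 = 13.6
        eps = 1e-7
        g = _grid([[10.0, 20.0, 30.0]], [0.0, 0.5, 1.0], [0.0])
        p = {"lon": 0.0, "lat": 0.0, "date": "2001-08-01",
             "ci_lon_lo": -1.0, "ci_lon_hi": 1.0 + 1e-9,
             "ci_lat_lo": -eps, "ci_lat_hi": eps}
        v = nt.kernel_weighted_extract(p, g)
        assert v == pytest.approx(13.6, abs=1e-6)

    def test_box_shrunk_to_one_cell_is_nearest_cell(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 5))
        lons = np.linspace(-2, 2, 5)
        lats = np.linspace(-2, 2, 5)
        g = _grid(vals, lons, lats)
        v = nt.kernel_weighted_extract(_point(0.05, -0.04, 0.4, 0.4), g)
        assert v == pytest.approx(vals[2, 2], abs=1e-12)

    def test_weighted_mean_within_contributor_hull(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(5, 9, (7, 7))
        g = _grid(vals, np.linspace(-3, 3, 7), np.linspace(-3, 3, 7))
        v = nt.kernel_weighted_extract(_point(0.3, -0.2, 2.0, 2.5), g)
        assert vals.min() <= v <= vals.max()

    def test_missing_when_box_empty_or_all_nan(self):
        g = _grid(np.full((3, 3), np.nan), [-1, 0, 1], [-1, 0, 1])
        assert np.isnan(nt.kernel_weighted_extract(_point(0, 0, 1.4, 1.4), g))
        g2 = _grid(np.ones((3, 3)), [-1, 0, 1], [-1, 0, 1])
        assert np.isnan(nt.kernel_weighted_extract(_point(10.0, 10.0, 0.2, 0.2), g2))

    def test_invariant_to_cell_enumeration_order(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 6))
        lons = np.linspace(-2, 2, 6)
        lats = np.linspace(-2, 2, 6)
        g = _grid(vals, lons, lats)
        # flipping the latitude axis reverses enumeration; same cells
        gf = _grid(vals[::-1], lons, lats[::-1]).sortby("lat")
        p = _point(0.1, 0.2, 1.5, 1.5)
        assert nt.kernel_weighted_extract(p, g) == pytest.approx(
            nt.kernel_weighted_extract(p, gf), rel=1e-12)

    def test_time_resolved_nearest_slice_and_out_of_window(self):
        times = pd.date_range("2001-08-01", periods=3, freq="8D")
        vals = np.stack([np.full((3, 3), k) for k in (1.0, 2.0, 3.0)])
        g = xr.DataArray(vals, coords={"time": times, "lat": [-1, 0, 1],
                                       "lon": [-1, 0, 1]},
                         dims=("time", "lat", "lon"))
        v = nt.kernel_weighted_extract(_point(0, 0, 1.4, 1.4,
                                              date="2001-08-10"), g)
        assert v == pytest.approx(2.0)
        far = nt.kernel_weighted_extract(_point(0, 0, 1.4, 1.4,
                                                date="2002-03-01"), g)
        assert np.isnan(far)


class TestDetrend:
    def test_linear_trend_removed_exactly(self):
        lats = np.linspace(30, 48, 200)
        vals = 22.0 - 0.5 * lats
        anom = nt.detrend_latitude(vals, lats)
        assert np.abs(anom).max() < 1e-8 * np.abs(vals).max()

    def test_constant_values_give_zero_anomaly(self):
        lats = np.linspace(30, 48, 50)
        anom = nt.detrend_latitude(np.full(50, 4.2), lats)
        assert np.abs(anom).max() < 1e-10

    def test_noise_leaves_no_latitude_correlation(self):
        rng = np.random.default_rng(4)
        lats = rng.uniform(30, 48, 1000)
        vals = 10.0 - 0.4 * lats + rng.normal(0, 1.0, 1000)
        anom = nt.detrend_latitude(vals, lats)
        r = np.corrcoef(anom, lats)[0, 1]
        assert abs(r) < 0.05

    def test_nearly_idempotent_on_trend_plus_noise(self):
        # a loess smoother is not a projection, so exact idempotency is
        # impossible; for trend-plus-noise data the second pass must leave
        # the anomalies essentially unchanged
        rng = np.random.default_rng(5)
        lats = rng.uniform(30, 48, 1000)
        vals = 10.0 - 0.4 * lats + rng.normal(0, 1.0, 1000)
        a1 = nt.detrend_latitude(vals, lats)
        a2 = nt.detrend_latitude(a1, lats)
        assert np.abs(a2 - a1).max() < 0.05 * a1.std()

    def test_preserves_missing_and_requires_enough_pairs(self):
        lats = np.linspace(30, 48, 20)
        vals = lats * 0.3
        vals[3] = np.nan
        anom = nt.detrend_latitude(vals, lats)
        assert np.isnan(anom[3]) and np.isfinite(anom).sum() == 19
        with pytest.raises(ValueError):
            nt.detrend_latitude([1.0] * 5, [30, 31, 32, 33, 34])
        with pytest.raises(ValueError):
            nt.detrend_latitude([np.nan] * 12, np.linspace(30, 40, 12))


class TestCollinearityScreen:
    def test_duplicated_predictor_keeps_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, report = nt.collinearity_screen(t, ["a", "b", "c"],
                                              {"a": 2.0, "b": 1.0, "c": 0.5})
        assert kept == ["a", "c"]
        assert report["flagged_pairs"][0]["dropped"] == "b"

    def test_independent_predictors_all_retained(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame({k: rng.normal(size=200) for k in "abcd"})
        kept, _ = nt.collinearity_screen(t, list("abcd"),
                                         {k: 1.0 for k in "abcd"})
        assert kept == list("abcd")

    def test_correlated_pair_drops_lower_scoring_member(self):
        # the published screen: r = 0.86 between a variable and its
        # detrended version; the lower single-predictor logB member goes
        rng = np.random.default_rng(8)
        n = 500
        ssh = rng.normal(size=n)
        dt_ssh = 0.86 * ssh + np.sqrt(1 - 0.86 ** 2) * rng.normal(size=n)
        t = pd.DataFrame({"SSH": ssh, "dtSSH": dt_ssh})
        kept, report = nt.collinearity_screen(
            t, ["SSH", "dtSSH"], {"SSH": 1.1, "dtSSH": 3.0})
        assert kept == ["dtSSH"]
        assert report["flagged_pairs"][0]["abs_r"] >= 0.7

    def test_zero_variance_predictor_dropped_as_degenerate(self):
        t = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        kept, report = nt.collinearity_screen(t, ["a", "b"], {"a": 9.9, "b": 0.1})
        assert kept == ["b"]
        assert report["dropped"][0]["reason"] == "degenerate"


class TestTableHelpers:
    def test_extract_table_and_detrended_columns(self, sim_small):
        _, fields, tracks, _ = sim_small
        sub = tracks.head(40)
        table = extract_table(sub, fields, predictors=["SST", "DEPTH"])
        assert {"SST", "DEPTH"} <= set(table.columns)
        table = add_detrended(table, ["SST"])
        ok = table["SST"].notna()
        assert (table["dtSST"].notna() == ok).all()
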