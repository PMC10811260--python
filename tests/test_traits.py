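"""Trait extractors (CC, CH, CWSI) and the cumulative water deficit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cloverpheno.simulate import generate_plot_raster
from cloverpheno.traits import (
    PlotRaster,
    ThermalScene,
    compute_canopy_cover,
    compute_canopy_height,
    compute_cwd,
    compute_cwsi,
    read_height_tiff,
)


def _raster(heights, mask):
    return PlotRaster("P1", np.asarray(heights, float), np.asarray(mask, bool))


class TestCanopyCover:
    def test_full_and_bare(self):
        ones = np.ones((5, 4))
        assert compute_canopy_cover(_raster(ones, np.ones((5, 4)))) == 100.0
        assert compute_canopy_cover(_raster(ones, np.zeros((5, 4)))) == 0.0

    def test_pixel_count_oracle(self):
        """37 vegetation pixels of 100 -> 37.0%."""
        mask = np.zeros(100, bool)
        mask[:37] = True
        assert compute_canopy_cover(_raster(np.ones(100).reshape(10, 10), mask.reshape(10, 10))) == 37.0

    def test_zero_pixel_polygon_rejected(self):
        with pytest.raises(ValueError, match="zero-pixel"):
            compute_canopy_cover(_raster(np.empty((0, 0)), np.empty((0, 0))))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_pixel_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random(60) < 0.5
        h = rng.uniform(0, 50, 60)
        perm = rng.permutation(60)
        a = _raster(h.reshape(6, 10), mask.reshape(6, 10))
        b = _raster(h[perm].reshape(6, 10), mask[perm].reshape(6, 10))
        assert compute_canopy_cover(a) == compute_canopy_cover(b)
        if mask.any():
            assert compute_canopy_height(a) == pytest.approx(compute_canopy_height(b))


class TestCanopyHeight:
    def test_constant_field(self):
        assert compute_canopy_height(_raster(np.full((3, 3), 23.5), np.ones((3, 3)))) == 23.5

    def test_linear_interpolation_oracle(self):
        """Q90 of 10..100 by the sort-based interpolation rule: 90 + 0.1*(100-90)."""
        h = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100], float)
        # independent oracle: position q*(n-1) between order statistics
        srt = np.sort(h)
        pos = 0.9 * (len(h) - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        expected = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        got = compute_canopy_height(_raster(h.reshape(2, 5), np.ones((2, 5))))
        assert got == pytest.approx(expected)
        assert expected == pytest.approx(91.0)

    def test_empty_mask_is_missing(self):
        assert np.isnan(compute_canopy_height(_raster(np.ones((2, 2)), np.zeros((2, 2)))))

    def test_quantile_only_over_vegetation(self):
        h = np.array([[100.0, 1.0], [1.0, 1.0]])
        mask = np.array([[True, False], [False, False]])
        assert compute_canopy_height(_raster(h, mask)) == 100.0


class TestCWSI:
    def test_bounds_exact(self):
        scene = ThermalScene(pd.Series({"a": 25.0, "b": 35.0}), twet=25.0, tdry=35.0)
        out = compute_cwsi(scene)
        assert out["a"] == 0.0 and out["b"] == 1.0

    def test_midpoint(self):
        scene = ThermalScene(pd.Series({"a": 30.0}), twet=25.0, tdry=35.0)
        assert compute_cwsi(scene)["a"] == 0.5

    def test_monotone_in_tc(self):
        tc = pd.Series(np.linspace(25, 35, 21))
        out = compute_cwsi(ThermalScene(tc, twet=25.0, tdry=35.0))
        assert (np.diff(out) > 0).all()

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            ThermalScene(pd.Series({"a": 30.0}), twet=35.0, tdry=35.0)

    def test_out_of_range_clamped_with_warning(self):
        scene = ThermalScene(pd.Series({"a": 20.0, "b": 40.0}), twet=25.0, tdry=35.0)
        with pytest.warns(RuntimeWarning, match="clamped 2"):
            out = compute_cwsi(scene)
        assert out["a"] == 0.0 and out["b"] == 1.0

    def test_percentile_references(self):
        tc = pd.Series(np.linspace(20, 40, 101))
        scene = ThermalScene.from_temperatures(tc)
        assert scene.twet == pytest.approx(20.2)
        assert scene.tdry == pytest.approx(39.8)


class TestCWD:
    def test_balanced_budget_is_zero(self):
        w = pd.DataFrame({"doy": range(1, 6), "et0": 3.0, "precipitation": 3.0})
        assert (compute_cwd(w).table["cwd"] == 0).all()

    def test_five_day_hand_oracle(self):
        """ET0 {4,4,4,4,4}, P {0,10,0,0,0}, I {0,0,5,0,0} -> CWD {4,-2,-3,1,5}."""
        w = pd.DataFrame(
            {"doy": [1, 2, 3, 4, 5], "et0": [4.0] * 5, "precipitation": [0, 10, 0, 0, 0]}
        )
        wb = compute_cwd(w, irrigation=[(3, 5.0)])
        assert list(wb.table["cwd"]) == [4.0, -2.0, -3.0, 1.0, 5.0]

    def test_shelter_excludes_all_rain(self):
        w = pd.DataFrame({"doy": range(1, 6), "et0": [2.0] * 5, "precipitation": [9.0] * 5})
        wb = compute_cwd(w, irrigation=[(2, 1.0)], shelter_windows=[(1, 5)])
        expected = np.cumsum([2.0, 1.0, 2.0, 2.0, 2.0])
        np.testing.assert_allclose(wb.table["cwd"], expected)

    def test_daily_increment_identity(self):
        rng = np.random.default_rng(0)
        w = pd.DataFrame(
            {"doy": range(1, 31), "et0": rng.uniform(0, 5, 30), "precipitation": rng.uniform(0, 8, 30)}
        )
        wb = compute_cwd(w, irrigation=[(10, 4.0)], shelter_windows=[(5, 12)])
        t = wb.table
        inc = t["cwd"].diff().dropna()
        expected = (t["et0"] - t["precipitation_effective"] - t["irrigation"]).iloc[1:]
        np.testing.assert_allclose(inc, expected)

    def test_nondecreasing_when_demand_dominates(self):
        w = pd.DataFrame({"doy": range(1, 11), "et0": [4.0] * 10, "precipitation": [1.0] * 10})
        assert (compute_cwd(w).table["cwd"].diff().dropna() >= 0).all()

    def test_irrigation_outside_range_rejected(self):
        w = pd.DataFrame({"doy": [1, 2], "et0": [1.0, 1.0], "precipitation": [0.0, 0.0]})
        with pytest.raises(ValueError, match="DOY 9"):
            compute_cwd(w, irrigation=[(9, 5.0)])


class TestRasterIO:
    def test_generated_raster_round_trips_traits(self):
        r = generate_plot_raster("P9", cc_percent=40.0, ch_cm=30.0, shape=(20, 50), seed=1)
        assert compute_canopy_cover(r) == pytest.approx(40.0)
        assert compute_canopy_height(r) == pytest.approx(30.0, rel=1e-6)

    def test_tiff_round_trip(self, tmp_path):
        import tifffile

        r = generate_plot_raster("P2", cc_percent=55.0, ch_cm=25.0, seed=2)
        path = tmp_path / "plot.tif"
        tifffile.imwrite(path, r.height_grid.astype(np.float32))
        loaded = read_height_tiff(path, "P2", mask=r.vegetation_mask)
        assert compute_canopy_cover(loaded) == pytest.approx(compute_canopy_cover(r))
        assert compute_canopy_height(loaded) == pytest.approx(compute_canopy_height(r), rel=1e-5)
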