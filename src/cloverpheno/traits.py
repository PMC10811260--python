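"""Plot-level trait extraction and the field water balance.

Traits mirror standard UAV phenotyping practice for forage swards:

* **CC** (canopy cover, %) — share of the plot polygon's pixels classified as
  vegetation.
* **CH** (canopy height, cm) — the 90th percentile (Q90) of per-pixel height
  above the soil over vegetation pixels, robust to single tall flowering
  stems.
* **CWSI** (crop water stress index) — normalized canopy temperature
  ``(Tc − Twet)/(Tdry − Twet)``; 0 = fully transpiring, 1 = non-transpiring.
* **CWD** (cumulative water deficit, mm) — running sum of reference
  evapotranspiration minus effective precipitation and irrigation; positive
  means drier (drought severity convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotRaster",
    "ThermalScene",
    "WaterBalanceSeries",
    "compute_canopy_cover",
    "compute_canopy_height",
    "compute_cwsi",
    "compute_cwd",
    "excess_green_mask",
    "polygon_mask",
    "read_height_tiff",
]


@dataclass
class PlotRaster:
    """Height map of one plot with its vegetation mask.

    ``height_grid`` holds canopy height above soil (cm) per pixel;
    ``vegetation_mask`` flags the pixels that belong to the canopy. Shapes
    must agree and heights must be finite wherever the mask is true.
    """

    plot_id: str
    height_grid: np.ndarray
    vegetation_mask: np.ndarray

    def __post_init__(self) -> None:
        self.height_grid = np.asarray(self.height_grid, dtype=float)
        self.vegetation_mask = np.asarray(self.vegetation_mask, dtype=bool)
        if self.height_grid.shape != self.vegetation_mask.shape:
            raise ValueError(
                f"plot {self.plot_id}: height grid {self.height_grid.shape} and "
                f"mask {self.vegetation_mask.shape} shapes differ"
            )
        if not np.isfinite(self.height_grid[self.vegetation_mask]).all():
            raise ValueError(f"plot {self.plot_id}: non-finite heights under the vegetation mask")


@dataclass
class ThermalScene:
    """Per-plot canopy temperatures with wet/dry references for one flight."""

    tc: pd.Series  # canopy temperature per plot_id, °C
    twet: float  # fully transpiring reference, °C
    tdry: float  # non-transpiring reference, °C
    doy: int = 0
    year: int = 0

    def __post_init__(self) -> None:
        if not self.tdry > self.twet:
            raise ValueError(f"Tdry ({self.tdry}) must exceed Twet ({self.twet})")

    @classmethod
    def from_temperatures(
        cls,
        tc: Mapping[str, float] | pd.Series,
        twet: float | None = None,
        tdry: float | None = None,
        doy: int = 0,
        year: int = 0,
        percentiles: tuple[float, float] = (1.0, 99.0),
    ) -> "ThermalScene":
        """Build a scene, defaulting missing references to scene percentiles.

        When no measured wet/dry reference panels are available, the 1st/99th
        percentiles of the scene temperature distribution stand in for
        Twet/Tdry.
        """
        tc = pd.Series(tc, dtype=float)
        lo, hi = np.percentile(tc.to_numpy(), percentiles)
        return cls(
            tc=tc,
            twet=float(twet if twet is not None else lo),
            tdry=float(tdry if tdry is not None else hi),
            doy=doy,
            year=year,
        )


@dataclass
class WaterBalanceSeries:
    """Daily water balance of one field over a season."""

    field: str
    year: int
    table: pd.DataFrame  # doy, et0, precipitation_effective, irrigation, cwd

    @property
    def cwd(self) -> pd.Series:
        return self.table.set_index("doy")["cwd"]


def compute_canopy_cover(raster: PlotRaster) -> float:
    """Canopy cover: percentage of the plot polygon covered by vegetation.

    ``CC = 100 · (#vegetation pixels) / (#pixels)``, in [0, 100].
    """
    n = raster.vegetation_mask.size
    if n == 0:
        raise ValueError(f"plot {raster.plot_id}: zero-pixel polygon")
    return 100.0 * float(raster.vegetation_mask.sum()) / float(n)


def compute_canopy_height(raster: PlotRaster, q: float = 0.90) -> float:
    """Canopy height as the Q90 of heights over vegetation pixels (cm).

    Uses the linear-interpolation quantile convention (numpy's default);
    quantile conventions differ between tools, so the choice is fixed here.
    Returns NaN for an empty vegetation mask (no canopy to measure).
    """
    heights = raster.height_grid[raster.vegetation_mask]
    if heights.size == 0:
        return float("nan")
    return float(np.quantile(heights, q))


def compute_cwsi(
    scene: ThermalScene, clamp: bool = True
) -> pd.Series:
    """Crop water stress index per plot from a thermal scene.

    ``CWSI = (Tc − Twet)/(Tdry − Twet)``. Values outside [0, 1] (canopy
    cooler than the wet or hotter than the dry reference) are clamped with a
    warning reporting how many pixels fell outside.
    """
    cwsi = (scene.tc - scene.twet) / (scene.tdry - scene.twet)
    out_of_range = int(((cwsi < 0) | (cwsi > 1)).sum())
    if clamp and out_of_range:
        warnings.warn(
            f"CWSI: clamped {out_of_range} plot(s) outside [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
        cwsi = cwsi.clip(0.0, 1.0)
    cwsi.name = "CWSI"
    return cwsi


def compute_cwd(
    weather: pd.DataFrame,
    irrigation: Iterable[tuple[int, float]] = (),
    shelter_windows: Iterable[tuple[int, int]] = (),
    start_doy: int | None = None,
    end_doy: int | None = None,
    field: str = "",
    year: int = 0,
) -> WaterBalanceSeries:
    """Cumulative water deficit from daily weather, irrigation and shelters.

    Each day contributes ``ET0 − effective precipitation − irrigation`` to the
    running deficit. Inside a rain-out-shelter window the effective
    precipitation is zero (the shelters exclude rain but not evaporative
    demand). Deficit is signed positive-when-dry.

    Parameters
    ----------
    weather
        DataFrame with ``doy``, ``et0`` and ``precipitation`` columns (mm).
    irrigation
        (doy, mm) events; an event outside the weather's DOY range is an
        error.
    shelter_windows
        Closed DOY intervals during which precipitation is excluded.
    start_doy, end_doy
        Accumulation range; defaults to the weather table's extent. The
        accumulation origin is configurable because reporting conventions
        differ.
    """
    w = weather.sort_values("doy").reset_index(drop=True)
    doys = w["doy"].to_numpy()
    lo = int(doys.min() if start_doy is None else start_doy)
    hi = int(doys.max() if end_doy is None else end_doy)
    sel = (doys >= lo) & (doys <= hi)
    w = w.loc[sel].reset_index(drop=True)
    doys = w["doy"].to_numpy()
    if w.empty:
        raise ValueError("weather covers no days in the requested range")

    irr = np.zeros(len(w))
    for doy, mm in irrigation:
        if doy < lo or doy > hi or doy not in doys:
            raise ValueError(f"irrigation event on DOY {doy} outside weather range {lo}..{hi}")
        if mm < 0:
            raise ValueError(f"negative irrigation amount on DOY {doy}")
        irr[np.searchsorted(doys, doy)] += mm

    precip_eff = w["precipitation"].to_numpy(dtype=float).copy()
    for a, b in shelter_windows:
        precip_eff[(doys >= a) & (doys <= b)] = 0.0

    daily = w["et0"].to_numpy(dtype=float) - precip_eff - irr
    table = pd.DataFrame(
        {
            "doy": doys,
            "et0": w["et0"].to_numpy(dtype=float),
            "precipitation_effective": precip_eff,
            "irrigation": irr,
            "cwd": np.cumsum(daily),
        }
    )
    return WaterBalanceSeries(field=field, year=year, table=table)


# ---------------------------------------------------------------------------
# raster helpers (inputs for the extractors; not part of the validated core)

def excess_green_mask(rgb: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Vegetation mask from an RGB raster via the excess-green index.

    ExG = 2g − r − b on chromatic coordinates; pixels above ``threshold``
    count as vegetation. Convenience helper only — the validated extraction
    takes the mask as an input.
    """
    rgb = np.asarray(rgb, dtype=float)
    total = rgb.sum(axis=-1)
    total[total == 0] = 1.0
    chrom = rgb / total[..., None]
    exg = 2 * chrom[..., 1] - chrom[..., 0] - chrom[..., 2]
    return exg > threshold


def polygon_mask(shape: tuple[int, int], polygon: Sequence[Sequence[float]]) -> np.ndarray:
    """Rasterize a (row, col) polygon onto a grid of ``shape``."""
    from skimage.draw import polygon as _poly

    poly = np.asarray(polygon, dtype=float)
    rr, cc = _poly(poly[:, 0], poly[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def read_height_tiff(path, plot_id: str, polygon=None, mask=None) -> PlotRaster:
    """Load a height-map TIFF as a :class:`PlotRaster`.

    ``polygon`` (pixel coordinates, GeoJSON-style ring) or an explicit
    boolean ``mask`` selects vegetation pixels; with neither, every finite
    pixel above zero counts as vegetation.
    """
    import tifffile

    grid = np.asarray(tifffile.imread(str(path)), dtype=float)
    if mask is None:
        if polygon is not None:
            mask = polygon_mask(grid.shape, polygon)
        else:
            mask = np.isfinite(grid) & (grid > 0)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(grid)
    return PlotRaster(plot_id=plot_id, height_grid=np.nan_to_num(grid), vegetation_mask=mask)


def load_plot_polygons(path) -> dict[str, list]:
    """Read plot polygons from a GeoJSON FeatureCollection keyed by plot_id."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj.get("features", []):
        pid = feat.get("properties", {}).get("plot_id")
        if pid is not None:
            out[str(pid)] = feat["geometry"]["coordinates"][0]
    return out
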