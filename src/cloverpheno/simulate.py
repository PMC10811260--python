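"""Synthetic two-field drought trials with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — independent Gaussian accession, block, column and row effects plus
residual noise — together with the field-trial features that make the
analysis non-trivial: a time-varying proportional drought effect with
per-accession sensitivity (G×E), maturity-driven bimodality in canopy height
(early accessions push flowering stems), canopy cover bounded in [0, 100],
thermal scenes for CWSI, and a configurable rate of faulty plots. Every
realized effect is recorded in a :class:`TruthRecord` so parameter-recovery
tests can compare estimates against the generating truth.

Model per observation (plot of accession *i* in block *b*, column *c*,
row *r*, at DOY *t*):

* identity-link traits (CH, CH_rpm): the systematic part
  ``m = μ(t) + boost_i(t) + g_i + u_b + u_c + u_r`` is multiplied in the
  drought field by ``(1 − δ(t))^(1 + s_i)`` and Gaussian noise is added, so
  the treatment is exactly proportional and the expected relative index is
  δ(t) when G×E is off;
* CC: the same linear predictor lives on a logit scale mapped to [0, 100],
  with the drought term ``log(1 − δ(t))·(1 + s_i)`` shifting the link (odds
  multiplied by (1 − δ)^(1+s)); noise is added on the link scale so values
  stay inside the bounds;
* CWSI: drought *raises* the index: ``base(t) + gain·δ(t)·(1 + s_i)`` plus
  effects and noise, clipped to [0, 1].

The generator is statistical, not mechanistic: no soil water dynamics, no
light interception, no plant mortality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import Field, Maturity, TrialDesign
from .timeline import Timeline, YEAR1_TIMELINE
from .traits import PlotRaster, ThermalScene

__all__ = [
    "VarComponents",
    "SimulationParams",
    "TruthRecord",
    "WeatherParams",
    "simulate_weather",
    "simulate_trial",
    "SimulatedTrial",
    "inject_faults",
    "generate_plot_raster",
]

_SUBSTREAMS = ("layout", "effects", "noise", "faults", "weather")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the shared seed, so components vary independently."""
    idx = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


@dataclass(frozen=True)
class VarComponents:
    """Generating variances for one trait (link-scale units² where relevant)."""

    V_G: float
    V_R: float
    V_block: float = 0.0
    V_column: float = 0.0
    V_row: float = 0.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def _default_variances() -> dict[str, VarComponents]:
    return {
        # CH in cm²: accession SD 5 cm, residual 4 cm, mild spatial trends
        "CH": VarComponents(V_G=25.0, V_R=16.0, V_block=2.0, V_column=1.0, V_row=1.0),
        "CH_rpm": VarComponents(V_G=25.0, V_R=9.0, V_block=2.0, V_column=1.0, V_row=1.0),
        # CC on the logit scale
        "CC": VarComponents(V_G=0.25, V_R=0.16, V_block=0.02, V_column=0.01, V_row=0.01),
        # CWSI on its native 0–1 scale
        "CWSI": VarComponents(V_G=0.004, V_R=0.006, V_block=0.0005, V_column=0.0, V_row=0.0),
    }


def _default_obs_doys() -> dict[str, tuple[int, ...]]:
    # UAV flights through the season; ground RPM campaigns a few days off the
    # nearest flight; one thermal flight shortly after drought relief
    return {
        "CC": (149, 165, 178, 205, 225, 256, 273),
        "CH": (149, 165, 178, 205, 225, 256, 273),
        "CH_rpm": (150, 167, 204, 257),
        "CWSI": (206,),
    }


def smoothstep(x: np.ndarray | float) -> np.ndarray | float:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class SimulationParams:
    """Everything that defines the synthetic study conditions.

    Defaults reproduce a trial of the reference scale: 395 accessions, a
    3 × 5 × 53 grid per field, two replicates (the control cultivar seven),
    a drought effect ramping to a 40% reduction by shelter removal and fading
    over the recovery phase, and moderate accession-specific drought
    sensitivity.
    """

    panel_size: int = 395
    geometry: tuple[int, int, int] = (3, 5, 53)
    reps: int = 2
    control_reps: int = 7
    variance_components: dict[str, VarComponents] = dc_field(default_factory=_default_variances)
    obs_doys: dict[str, tuple[int, ...]] = dc_field(default_factory=_default_obs_doys)
    delta_max: float = 0.4  # peak proportional reduction at the end of the window
    recovery_days: int = 60  # days for δ to fade after shelter removal
    gxe_sd: float = 0.2  # SD of per-accession drought sensitivity s_i
    early_fraction: float = 0.5  # share of early-flowering (double-cut) accessions
    flowering_ch_boost: float = 10.0  # cm added to CH of early accessions when flowering
    fault_rate: float = 0.0
    outlier_offset: float = 50.0
    cwsi_base: float = 0.2
    cwsi_gain: float = 0.5  # CWSI increase per unit δ
    ch_range: tuple[float, float] = (7.0, 45.0)  # cm, post-cut to pre-cut
    cc_range: tuple[float, float] = (30.0, 95.0)  # %, post-cut to pre-cut
    fld_mean: float = 160.0
    fld_sd: float = 8.0
    flowering_prob: float = 0.9  # per-plot flowering probability, early accessions
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.delta_max <= 1.0:
            raise ValueError("delta_max must lie in [0, 1]")
        if not 0.0 <= self.early_fraction <= 1.0:
            raise ValueError("early_fraction must lie in [0, 1]")
        if not 0.0 <= self.fault_rate < 1.0:
            raise ValueError("fault_rate must lie in [0, 1)")
        if self.gxe_sd < 0:
            raise ValueError("gxe_sd must be >= 0")

    # -- deterministic trait trajectories ---------------------------------

    def delta(self, doy: float, timeline: Timeline) -> float:
        """Proportional drought reduction δ(t) ∈ [0, 1].

        Ramps linearly from 0 at shelter installation to ``delta_max`` at
        removal, then fades linearly to 0 over ``recovery_days`` (the legacy
        effect of drought on regrowth).
        """
        a, b = timeline.drought_window
        if doy <= a:
            return 0.0
        if doy <= b:
            return self.delta_max * (doy - a) / (b - a)
        return max(0.0, self.delta_max * (1.0 - (doy - b) / self.recovery_days))

    def baseline(self, variable: str, doy: float, timeline: Timeline) -> float:
        """Mean control-field trajectory of a trait over the season.

        Within each growth period the canopy regrows from its post-cut floor
        to its pre-cut ceiling (smoothstep); CC saturates near its ceiling
        well before the cut, as swards close early.
        """
        frac = 0.0
        for lo, hi in timeline.growth_periods():
            if lo < doy <= hi:
                frac = (doy - lo) / (hi - lo)
                break
        if variable in ("CH", "CH_rpm"):
            lo_v, hi_v = self.ch_range
            return lo_v + (hi_v - lo_v) * float(smoothstep(frac))
        if variable == "CC":
            lo_v, hi_v = self.cc_range
            # swards close faster than they grow tall
            return lo_v + (hi_v - lo_v) * float(smoothstep(min(1.0, 1.6 * frac)))
        if variable == "CWSI":
            return self.cwsi_base
        raise ValueError(f"no baseline for variable {variable!r}")

    def flowering_windows(self, timeline: Timeline) -> list[tuple[int, int]]:
        """DOY windows in which early accessions carry flowering stems."""
        cuts = timeline.cut_doys
        wins = []
        if len(cuts) >= 2:
            wins.append((cuts[0] + 15, cuts[1]))
        if len(cuts) >= 3:
            wins.append((cuts[1] + 20, cuts[2]))
        return wins


@dataclass
class TruthRecord:
    """Realized generating quantities of one synthetic trial."""

    genetic_effects: pd.DataFrame  # accessions × variables, link scale
    sensitivity: pd.Series  # per-accession drought sensitivity s_i
    maturity: pd.Series  # per-accession early/late
    spatial_effects: dict  # (field, variable) -> {term: {level: effect}}
    delta_by_doy: dict  # doy -> δ used
    params: SimulationParams
    fault_flags: pd.DataFrame | None = None  # filled by inject_faults

    def to_json(self, path) -> None:
        payload = {
            "genetic_effects": self.genetic_effects.to_dict(),
            "sensitivity": self.sensitivity.to_dict(),
            "maturity": self.maturity.to_dict(),
            "spatial_effects": {
                f"{f}/{v}": {t: {str(k): val for k, val in d.items()} for t, d in terms.items()}
                for (f, v), terms in self.spatial_effects.items()
            },
            "delta_by_doy": self.delta_by_doy,
            "params": {
                k: (v if not isinstance(v, dict) else {kk: asdict(vv) if hasattr(vv, "__dataclass_fields__") else vv for kk, vv in v.items()})
                for k, v in asdict(self.params).items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=str, indent=1)


@dataclass
class SimulatedTrial:
    phenotypes: pd.DataFrame  # long format
    weather: pd.DataFrame
    thermal_scenes: list[ThermalScene]
    truth: TruthRecord
    timeline: Timeline


# ---------------------------------------------------------------------------
# weather


@dataclass(frozen=True)
class WeatherParams:
    """Seasonal shape + noise of the synthetic daily weather.

    Defaults are calibrated to a temperate maritime site: ~850 mm annual
    precipitation, midsummer reference evapotranspiration near 3.5 mm/day.
    """

    rain_prob: float = 0.45
    rain_mean_mm: float = 5.2
    et0_winter: float = 0.4  # mm/day
    et0_summer: float = 3.5  # mm/day
    et0_cv: float = 0.3
    tmean_winter: float = 3.0  # °C
    tmean_summer: float = 18.0
    rad_winter: float = 2.0  # MJ m⁻² day⁻¹
    rad_summer: float = 20.0

    def seasonal(self, doy: np.ndarray, lo: float, hi: float) -> np.ndarray:
        # sinusoid peaking around DOY 196 (mid-July)
        return lo + (hi - lo) * 0.5 * (1.0 - np.cos(2.0 * np.pi * (doy - 15) / 365.0))

    def et0_mean(self, doy: np.ndarray | int) -> np.ndarray:
        return self.seasonal(np.asarray(doy, dtype=float), self.et0_winter, self.et0_summer)


def simulate_weather(
    year: int = 1,
    params: WeatherParams = WeatherParams(),
    n_days: int = 365,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily weather series: DOY, tmean, precipitation, ET0, radiation.

    Reproducible for a fixed seed; precipitation and ET0 are non-negative by
    construction (Bernoulli wet days × exponential amounts; gamma-distributed
    ET0 around the seasonal mean).
    """
    if n_days < 1:
        raise ValueError("need at least one day")
    rng = _substream(seed, "weather")
    doy = np.arange(1, n_days + 1)
    et0_m = params.et0_mean(doy)
    if params.et0_cv > 0:
        shape = 1.0 / params.et0_cv**2
        et0 = rng.gamma(shape, et0_m / shape)
    else:
        et0 = et0_m.copy()
    wet = rng.random(n_days) < params.rain_prob
    precip = np.where(wet, rng.exponential(params.rain_mean_mm, n_days), 0.0)
    tmean = params.seasonal(doy, params.tmean_winter, params.tmean_summer) + rng.normal(0, 2.5, n_days)
    rad = np.clip(
        params.seasonal(doy, params.rad_winter, params.rad_summer) + rng.normal(0, 3.0, n_days),
        0.1,
        None,
    )
    return pd.DataFrame(
        {
            "year": year,
            "doy": doy,
            "tmean": tmean,
            "precipitation": precip,
            "et0": et0,
            "radiation": rad,
        }
    )


# ---------------------------------------------------------------------------
# the trial itself


def _draw_effects(design: TrialDesign, params: SimulationParams, rng: np.random.Generator):
    acc_ids = design.accession_ids
    variables = list(params.variance_components)
    g = pd.DataFrame(
        {
            v: rng.normal(0.0, np.sqrt(params.variance_components[v].V_G), len(acc_ids))
            for v in variables
        },
        index=pd.Index(acc_ids, name="accession_id"),
    )
    s = pd.Series(rng.normal(0.0, params.gxe_sd, len(acc_ids)), index=g.index, name="sensitivity")
    n_early = int(round(params.early_fraction * len(acc_ids)))
    early_mask = np.zeros(len(acc_ids), dtype=bool)
    early_mask[rng.choice(len(acc_ids), size=n_early, replace=False)] = True
    maturity = pd.Series(
        np.where(early_mask, Maturity.early.value, Maturity.late.value),
        index=g.index,
        name="maturity",
    )
    blocks, columns, rows = design.geometry.blocks, design.geometry.columns, design.geometry.rows
    spatial: dict = {}
    for field in (Field.control, Field.drought):
        for v in variables:
            vc = params.variance_components[v]
            spatial[(field.value, v)] = {
                "Block": {
                    b + 1: rng.normal(0, np.sqrt(vc.V_block)) for b in range(blocks)
                },
                "Column": {
                    (b + 1, c + 1): rng.normal(0, np.sqrt(vc.V_column))
                    for b in range(blocks)
                    for c in range(columns)
                },
                "Row": {r + 1: rng.normal(0, np.sqrt(vc.V_row)) for r in range(rows)},
            }
    return g, s, maturity, spatial


def simulate_trial(
    design: TrialDesign,
    params: SimulationParams | None = None,
    timeline: Timeline = YEAR1_TIMELINE,
    year: int | None = None,
) -> SimulatedTrial:
    """Generate one production year of observations for a trial design.

    Returns the long-format phenotype table (CC/CH/CH_rpm/FLD rows, plus CWSI
    derived from the emitted thermal scenes by the caller or pipeline), the
    daily weather, the thermal scenes, and the :class:`TruthRecord` of all
    realized effects. Faults are injected afterwards with
    :func:`inject_faults` when ``params.fault_rate`` > 0.
    """
    params = params or SimulationParams()
    from .design import validate_design

    problems = validate_design(design)
    if problems:
        raise ValueError("invalid design: " + "; ".join(problems[:5]))
    year = timeline.year if year is None else year

    eff_rng = _substream(params.seed, "effects")
    noise_rng = _substream(params.seed, "noise")
    g, s, maturity, spatial = _draw_effects(design, params, eff_rng)

    rows = []
    delta_by_doy: dict[int, float] = {}
    flower_wins = params.flowering_windows(timeline)
    for field in (Field.control, Field.drought):
        plots = design.field_plots(field)
        acc = np.array([p.accession_id for p in plots])
        g_idx = g.index.get_indexer(acc)
        blk = np.array([p.block for p in plots])
        col_pairs = [(p.block, p.column) for p in plots]
        colidx = np.array([p.column for p in plots])
        rowi = np.array([p.row for p in plots])
        pid = np.array([p.plot_id for p in plots])
        s_p = s.to_numpy()[g_idx]
        early_p = (maturity.to_numpy()[g_idx] == Maturity.early.value)
        for variable, vc in params.variance_components.items():
            if variable == "CWSI":
                continue  # CWSI arrives via thermal scenes
            # CH_rpm is the same canopy as CH measured by another instrument:
            # it shares CH's genetic and spatial reality, with its own noise
            src = "CH" if variable == "CH_rpm" and "CH" in params.variance_components else variable
            sp = spatial[(field.value, src)]
            u_b = np.array([sp["Block"][b] for b in blk])
            u_c = np.array([sp["Column"][cp] for cp in col_pairs])
            u_r = np.array([sp["Row"][r] for r in rowi])
            g_p = g[src].to_numpy()[g_idx]
            for doy in params.obs_doys.get(variable, ()):
                d = params.delta(doy, timeline) if field is Field.drought else 0.0
                delta_by_doy[int(doy)] = params.delta(doy, timeline)
                eps = noise_rng.normal(0.0, np.sqrt(vc.V_R), len(plots))
                if variable == "CC":
                    mu = params.baseline("CC", doy, timeline)
                    eta = logit(np.clip(mu / 100.0, 1e-6, 1 - 1e-6)) + g_p + u_b + u_c + u_r
                    if d > 0:
                        eta = eta + np.log1p(-d) * (1.0 + s_p)
                    value = 100.0 * expit(eta + eps)
                else:  # CH, CH_rpm — identity link, proportional treatment
                    boost = np.where(
                        early_p & any(a <= doy <= b for a, b in flower_wins),
                        params.flowering_ch_boost,
                        0.0,
                    )
                    m = params.baseline(variable, doy, timeline) + boost + g_p + u_b + u_c + u_r
                    if d > 0:
                        m = m * np.power(1.0 - d, 1.0 + s_p)
                    value = m + eps
                rows.append(
                    pd.DataFrame(
                        {
                            "plot_id": pid,
                            "field": field.value,
                            "block": blk,
                            "column": colidx,
                            "row": rowi,
                            "accession_id": acc,
                            "variable": variable,
                            "year": year,
                            "doy": int(doy),
                            "value": value,
                            "flag": "ok",
                        }
                    )
                )
        # flowering (year 1 scoring): FLD per plot
        if year == 1:
            flower = noise_rng.random(len(plots)) < params.flowering_prob
            fld = np.where(
                early_p & flower,
                np.clip(noise_rng.normal(params.fld_mean, params.fld_sd, len(plots)), 120, 200).round(),
                222.0,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "plot_id": pid,
                        "field": field.value,
                        "block": blk,
                        "column": colidx,
                        "row": rowi,
                        "accession_id": acc,
                        "variable": "FLD",
                        "year": year,
                        "doy": int(timeline.cut_doys[0]),
                        "value": fld,
                        "flag": "ok",
                    }
                )
            )

    phenotypes = pd.concat(rows, ignore_index=True)

    # thermal scenes: canopy temperature encodes the true CWSI field
    scenes: list[ThermalScene] = []
    vc = params.variance_components.get("CWSI")
    if vc is not None:
        twet, tdry = 24.0, 42.0
        for doy in params.obs_doys.get("CWSI", ()):
            for field in (Field.control, Field.drought):
                plots = design.field_plots(field)
                acc = np.array([p.accession_id for p in plots])
                g_idx = g.index.get_indexer(acc)
                sp = spatial[(field.value, "CWSI")]
                u = (
                    np.array([sp["Block"][p.block] for p in plots])
                    + np.array([sp["Column"][(p.block, p.column)] for p in plots])
                    + np.array([sp["Row"][p.row] for p in plots])
                )
                d = params.delta(doy, timeline) if field is Field.drought else 0.0
                cwsi = (
                    params.cwsi_base
                    + params.cwsi_gain * d * (1.0 + s.to_numpy()[g_idx])
                    + g["CWSI"].to_numpy()[g_idx]
                    + u
                    + noise_rng.normal(0, np.sqrt(vc.V_R), len(plots))
                )
                cwsi = np.clip(cwsi, 0.0, 1.0)
                tc = pd.Series(
                    twet + cwsi * (tdry - twet),
                    index=pd.Index([p.plot_id for p in plots], name="plot_id"),
                )
                scenes.append(ThermalScene(tc=tc, twet=twet, tdry=tdry, doy=int(doy), year=year))

    weather = simulate_weather(year=year, seed=params.seed)
    truth = TruthRecord(
        genetic_effects=g,
        sensitivity=s,
        maturity=maturity,
        spatial_effects=spatial,
        delta_by_doy=delta_by_doy,
        params=params,
    )
    trial = SimulatedTrial(
        phenotypes=phenotypes,
        weather=weather,
        thermal_scenes=scenes,
        truth=truth,
        timeline=timeline,
    )
    if params.fault_rate > 0:
        trial.phenotypes = inject_faults(
            trial.phenotypes, params.fault_rate, seed=params.seed,
            outlier_offset=params.outlier_offset, truth=truth,
        )
    return trial


def scene_observations(scene: ThermalScene, design: TrialDesign) -> pd.DataFrame:
    """CWSI observations (long format) extracted from a thermal scene."""
    from .traits import compute_cwsi

    cwsi = compute_cwsi(scene)
    lookup = {p.plot_id: p for f in (Field.control, Field.drought) for p in design.field_plots(f)}
    recs = []
    for pid, val in cwsi.items():
        p = lookup[pid]
        recs.append(
            {
                "plot_id": pid,
                "field": p.field.value,
                "block": p.block,
                "column": p.column,
                "row": p.row,
                "accession_id": p.accession_id,
                "variable": "CWSI",
                "year": scene.year,
                "doy": scene.doy,
                "value": float(val),
                "flag": "ok",
            }
        )
    return pd.DataFrame(recs)


def inject_faults(
    table: pd.DataFrame,
    fault_rate: float,
    seed: int = 0,
    outlier_offset: float = 50.0,
    truth: TruthRecord | None = None,
) -> pd.DataFrame:
    """Flag a random fraction of observations as faulty.

    Each observation row is independently faulty with probability
    ``fault_rate``; faulty rows get a flag drawn from {outlier: 0.5,
    damaged: 0.25, not_established: 0.25}. ``outlier`` rows additionally have
    their value displaced by ``outlier_offset`` (sign alternating), the other
    flags leave the stored value untouched. With rate 0 the table is returned
    unchanged (bit-identical values).
    """
    if not 0.0 <= fault_rate < 1.0:
        raise ValueError("fault_rate must lie in [0, 1)")
    if fault_rate == 0.0:
        return table
    rng = _substream(seed, "faults")
    t = table.copy()
    hit = rng.random(len(t)) < fault_rate
    kinds = rng.choice(
        ["outlier", "damaged", "not_established"], size=len(t), p=[0.5, 0.25, 0.25]
    )
    signs = rng.choice([-1.0, 1.0], size=len(t))
    t.loc[hit, "flag"] = kinds[hit]
    is_out = hit & (kinds == "outlier")
    t.loc[is_out, "value"] = t.loc[is_out, "value"] + signs[is_out] * outlier_offset
    if truth is not None:
        truth.fault_flags = t.loc[hit, ["plot_id", "variable", "year", "doy", "flag"]].reset_index(
            drop=True
        )
    return t


def generate_plot_raster(
    plot_id: str,
    cc_percent: float,
    ch_cm: float,
    shape: tuple[int, int] = (20, 50),
    seed: int = 0,
) -> PlotRaster:
    """Render one plot's height grid and vegetation mask.

    The mask covers ``cc_percent`` of the pixels (exact count); vegetated
    heights are drawn so that their Q90 sits near ``ch_cm``. Used to exercise
    the raster trait extractors against known plot values.
    """
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    n_veg = int(round(cc_percent / 100.0 * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_veg, replace=False)] = True
    # heights: beta-shaped canopy with Q90 at ch_cm
    h = np.zeros(n)
    if n_veg:
        raw = rng.beta(4.0, 2.0, n_veg)
        raw = raw / np.quantile(raw, 0.90) * ch_cm
        h[mask] = raw
    return PlotRaster(
        plot_id=plot_id,
        height_grid=h.reshape(shape),
        vegetation_mask=mask.reshape(shape),
    )
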