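"""End-to-end pipeline: simulate → QC → fit → Yr → PCA → ranking.

One config object drives the whole analysis for a single production year
(the two trial years are deliberately independent invocations sharing a
design — a perennial crop's second year is not a replicate of its first).
Every stage writes CSV outputs plus a manifest with checksums so reruns can
be verified bit-for-bit for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import Geometry, build_design, classify_maturity, validate_design
from .qc import QCRules, filter_observations, name_variable, correlate_ground_uav
from .response import compute_yr, yr_time_series
from .multivariate import (
    overlap,
    reduce_variables,
    run_pca,
    select_top_set,
    top_quartile_counts,
)
from .simulate import SimulationParams, VarComponents, simulate_trial, scene_observations
from .timeline import Timeline, YEAR1_TIMELINE, drought_duration_days
from .traits import compute_cwd
from .vcmodels import compute_blups, compute_heritability, fit_variable

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Design geometry, season timeline and per-stage options."""

    panel_size: int = 80
    geometry: tuple[int, int, int] = (3, 5, 11)
    reps: int = 2
    control_id: str = "Lemmon"
    control_reps: int = 7
    seed: int = 0
    timeline: Timeline = dc_field(default_factory=lambda: YEAR1_TIMELINE)
    sim: SimulationParams | None = None  # defaults derived from the fields above
    qc_rules: QCRules = dc_field(default_factory=QCRules)
    fit_variables: tuple[str, ...] = ("CC", "CH", "CWSI")
    yr_variables: tuple[str, ...] = ("CC", "CH", "CWSI")
    pca_selection: tuple[str, ...] | None = None  # VAR_DOY names; None = all fitted
    ranking_variables: tuple[str, ...] = ("CC", "CH")
    ranking_target_size: int = 25

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimulationParams(
                panel_size=self.panel_size,
                geometry=tuple(self.geometry),
                reps=self.reps,
                control_reps=self.control_reps,
                seed=self.seed,
                obs_doys={
                    "CC": (149, 165, 178, 205, 256),
                    "CH": (149, 165, 178, 205, 256),
                    "CH_rpm": (150, 207),
                    "CWSI": (206,),
                },
                fault_rate=0.02,
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "timeline" in raw and isinstance(raw["timeline"], dict):
            t = dict(raw["timeline"])
            t["cut_doys"] = tuple(t.get("cut_doys", YEAR1_TIMELINE.cut_doys))
            t["drought_window"] = tuple(t.get("drought_window", YEAR1_TIMELINE.drought_window))
            if "irrigation" in t:
                t["irrigation"] = {
                    f: tuple((int(d), float(mm)) for d, mm in events)
                    for f, events in t["irrigation"].items()
                }
            raw["timeline"] = Timeline(**t)
        if "qc_rules" in raw and isinstance(raw["qc_rules"], dict):
            raw["qc_rules"] = QCRules(**raw["qc_rules"])
        if "sim" in raw and isinstance(raw["sim"], dict):
            s = dict(raw["sim"])
            if "variance_components" in s:
                s["variance_components"] = {
                    k: VarComponents(**v) for k, v in s["variance_components"].items()
                }
            if "obs_doys" in s:
                s["obs_doys"] = {k: tuple(v) for k, v in s["obs_doys"].items()}
            raw["sim"] = SimulationParams(**s)
        for key in ("geometry", "fit_variables", "yr_variables", "ranking_variables", "pca_selection"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def validate_config(config: PipelineConfig) -> list[str]:
    """All config invariant violations, empty when the config is usable."""
    problems = list(config.timeline.validate())
    g = Geometry(*config.geometry)
    required = (config.panel_size - 1) * config.reps + config.control_reps
    if required != g.plots_per_field:
        problems.append(
            f"geometry {config.geometry} holds {g.plots_per_field} plots but the panel "
            f"needs {required}"
        )
    if config.ranking_target_size > config.panel_size:
        problems.append("ranking target size exceeds the panel size")
    if config.sim is not None and config.sim.seed != config.seed:
        problems.append("simulation seed differs from the pipeline seed")
    return problems


@dataclass
class PipelineResult:
    outdir: Path
    design: object
    blups: dict[str, pd.DataFrame]  # field -> accession × VAR_DOY matrix
    fit_summary: pd.DataFrame
    yr_matrix: pd.DataFrame
    yr_trajectory: pd.DataFrame
    pca: object
    ranking: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g", **kwargs)
    manifest.setdefault(stage, {})[path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run every stage on a freshly simulated trial and write all outputs.

    Stage order: design → simulate → QC → water balance → per-field model
    fits (BLUPs, H²) → Yr indices and trajectory → PCA → top-quartile
    ranking. Any stage failure aborts with the stage name attached.
    Rerunning with the same config reproduces identical files.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    stage = "design"
    try:
        panel = [config.control_id] + [
            f"ACC{i:04d}" for i in range(1, config.panel_size)
        ]
        design = build_design(
            panel,
            geometry=Geometry(*config.geometry),
            reps=config.reps,
            control_id=config.control_id,
            control_reps=config.control_reps,
            seed=config.seed,
        )
        assert not validate_design(design)
        _write(design.to_frame(), outdir / "design.csv", manifest, stage, index=False)

        stage = "simulate"
        trial = simulate_trial(design, config.sim, timeline=config.timeline)
        pheno = trial.phenotypes
        for scene in trial.thermal_scenes:
            pheno = pd.concat([pheno, scene_observations(scene, design)], ignore_index=True)
        _write(pheno, outdir / "observations.csv", manifest, stage, index=False)
        _write(trial.weather, outdir / "weather.csv", manifest, stage, index=False)
        trial.truth.to_json(outdir / "truth.json")
        manifest[stage]["truth.json"] = _sha256(outdir / "truth.json")

        stage = "qc"
        filtered = filter_observations(pheno, config.qc_rules)
        _write(filtered.table, outdir / "filtered.csv", manifest, stage, index=False)
        _write(filtered.report, outdir / "qc_report.csv", manifest, stage, index=False)
        if (filtered.table["variable"] == "CH_rpm").any():
            corr = correlate_ground_uav(filtered.table)
            _write(corr.pairs, outdir / "ground_uav_correlation.csv", manifest, stage, index=False)

        stage = "maturity"
        fld = filtered.table[filtered.table["variable"] == "FLD"]
        maturity = classify_maturity(fld) if len(fld) else None
        if maturity is not None:
            _write(maturity, outdir / "maturity.csv", manifest, stage)

        stage = "water_balance"
        for field in ("control", "drought"):
            shelter = [config.timeline.drought_window] if field == "drought" else []
            wb = compute_cwd(
                trial.weather,
                irrigation=config.timeline.irrigation.get(field, ()),
                shelter_windows=shelter,
                start_doy=config.timeline.season_start,
                end_doy=config.timeline.season_end,
                field=field,
                year=config.timeline.year,
            )
            _write(wb.table, outdir / f"cwd_{field}.csv", manifest, stage, index=False)

        stage = "fit"
        blups: dict[str, pd.DataFrame] = {}
        summary_rows = []
        for field in ("control", "drought"):
            sub = filtered.table[filtered.table["field"] == field]
            cols = {}
            for (var, doy), obs in sub.groupby(["variable", "doy"]):
                if var not in config.fit_variables:
                    continue
                vname = name_variable(var, int(doy))
                best, _ = fit_variable(obs, variable=vname)
                h2 = compute_heritability(best)
                cols[vname] = compute_blups(best)
                summary_rows.append(
                    {
                        "field": field,
                        "variable": vname,
                        "structure_id": best.spec.structure_id,
                        "structure": best.spec.label,
                        "intercept": best.intercept,
                        **best.components.as_dict(),
                        "loglik": best.loglik,
                        "aic": best.aic,
                        "n_obs": best.n_obs,
                        "H2": h2.H2,
                    }
                )
            blups[field] = pd.DataFrame(cols)
            blups[field].index.name = "accession_id"
            _write(blups[field], outdir / f"blups_{field}.csv", manifest, stage)
        fit_summary = pd.DataFrame(summary_rows)
        _write(fit_summary, outdir / "fit_summary.csv", manifest, stage, index=False)

        stage = "yr"
        yr_cols = {}
        common = [
            c
            for c in blups["control"].columns
            if c in blups["drought"].columns and c.split("_")[0] in config.yr_variables
        ]
        for c in common:
            yr_cols[f"Yr_{c}"] = compute_yr(blups["control"][c], blups["drought"][c])
        yr_matrix = pd.DataFrame(yr_cols)
        yr_matrix.index.name = "accession_id"
        _write(yr_matrix, outdir / "yr_matrix.csv", manifest, stage)
        trajectory = yr_time_series(
            yr_matrix,
            year=config.timeline.year,
            drought_window=config.timeline.drought_window,
            cut_doys=config.timeline.cut_doys,
        )
        _write(trajectory, outdir / "yr_trajectory.csv", manifest, stage, index=False)

        stage = "pca"
        control_matrix = blups["control"]
        if config.pca_selection:
            control_matrix = reduce_variables(control_matrix, selection=list(config.pca_selection))
        groups = None
        if maturity is not None:
            groups = {"maturity": maturity["maturity"].to_dict()}
        pca = run_pca(control_matrix, standardize=True, groups=groups)
        _write(pca.loadings, outdir / "pca_loadings.csv", manifest, stage)
        _write(pca.scores, outdir / "pca_scores.csv", manifest, stage)
        _write(
            pd.DataFrame(
                {"component": [f"PC{i+1}" for i in range(len(pca.explained))],
                 "explained_fraction": pca.explained}
            ),
            outdir / "pca_explained.csv",
            manifest,
            stage,
            index=False,
        )

        stage = "ranking"
        rank_rows = []
        for var in config.ranking_variables:
            sets = {}
            for field in ("control", "drought"):
                cols = [c for c in blups[field].columns if c.startswith(f"{var}_")]
                if not cols:
                    continue
                counts = top_quartile_counts(blups[field][cols])
                sets[field] = select_top_set(counts, config.ranking_target_size)
            if len(sets) == 2:
                ov = overlap(sets["control"], sets["drought"])
                rank_rows.append({"year": config.timeline.year, "variable": var, **ov})
        ranking = pd.DataFrame(rank_rows)
        _write(ranking, outdir / "ranking_overlap.csv", manifest, stage, index=False)

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["meta"] = {
        "package_version": __version__,
        "seed": config.seed,
        "year": config.timeline.year,
        "drought_duration_days": drought_duration_days(config.timeline),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        outdir=outdir,
        design=design,
        blups=blups,
        fit_summary=fit_summary,
        yr_matrix=yr_matrix,
        yr_trajectory=trajectory,
        pca=pca,
        ranking=ranking,
        manifest=manifest,
    )
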