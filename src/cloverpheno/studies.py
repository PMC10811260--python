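"""Parameter-recovery and calibration studies on synthetic trials.

Because the original field data are not public, the pipeline's correctness is
established against simulations with known generating truth: REML against
the balanced-ANOVA closed form, heritability and drought-index recovery
against the generator's parameters, type-I-error calibration of the Z-test,
and the null behaviour of the top-set overlap statistic. Each study is a
plain function returning a summary the tests and the acceptance report can
assert against.

The recovery studies use a single identity-link trait with the variance
components under study, no maturity boost and no faults: those features are
deliberate confounders exercised by their own tests, and leaving them on
would change the generating truth the study is asked to recover.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .design import Geometry, build_design
from .multivariate import overlap, select_top_set, top_quartile_counts
from .response import compute_yr, ztest_mean_vs_zero
from .simulate import SimulationParams, VarComponents, simulate_trial
from .timeline import YEAR1_TIMELINE, Timeline
from .vcmodels import (
    CANDIDATE_SPECS,
    ModelSpec,
    compute_blups,
    compute_heritability,
    fit_vc_model,
)

__all__ = [
    "balanced_anova_components",
    "reml_anova_agreement",
    "h2_recovery",
    "yr_recovery",
    "ztest_type1_error",
    "null_overlap",
    "overlap_vs_genetic_correlation",
]

#: 200-accession panel on a 3 × 5 × 27 grid: (200−1)·2 + 7 = 405 plots/field
RECOVERY_PANEL = 200
RECOVERY_GEOMETRY = Geometry(3, 5, 27)


def balanced_anova_components(data: pd.DataFrame) -> tuple[float, float]:
    """Method-of-moments (V_G, V_R) for a balanced one-way layout.

    Classical ANOVA identity: V_R = within-accession mean square, V_G =
    (between MS − within MS)/n_reps. Valid as a REML oracle when the V_G
    estimate is interior (non-negative).
    """
    groups = data.groupby("accession_id")["value"]
    nrep = int(groups.size().iloc[0])
    if not (groups.size() == nrep).all():
        raise ValueError("layout is not balanced")
    ms_within = float(groups.var(ddof=1).mean())
    ms_between = nrep * float(groups.mean().var(ddof=1))
    return (ms_between - ms_within) / nrep, ms_within


def _one_way_toy(rng: np.random.Generator) -> pd.DataFrame:
    """Random balanced one-way layout with an interior moment estimate."""
    for _ in range(100):
        a = int(rng.integers(8, 30))
        nrep = int(rng.integers(3, 7))
        vg = float(rng.uniform(0.5, 5.0))
        vr = float(rng.uniform(0.2, 2.0))
        g = rng.normal(0, np.sqrt(vg), a)
        y = (rng.uniform(-10, 10) + g[:, None] + rng.normal(0, np.sqrt(vr), (a, nrep))).ravel()
        df = pd.DataFrame(
            {
                "accession_id": np.repeat([f"A{i:03d}" for i in range(a)], nrep),
                "block": 1,
                "column": 1,
                "row": 1,
                "value": y,
            }
        )
        if balanced_anova_components(df)[0] > 0:
            return df
    raise RuntimeError("could not draw an interior toy")


def reml_anova_agreement(n_toys: int = 50, seed: int = 0) -> dict:
    """Max relative (V_G, V_R) disagreement REML vs ANOVA over random toys."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_toys):
        df = _one_way_toy(rng)
        vg_a, vr_a = balanced_anova_components(df)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        worst = max(
            worst,
            abs(fit.components.V_G - vg_a) / vg_a,
            abs(fit.components.V_R - vr_a) / vr_a,
        )
    return {"max_rel_err": worst, "n_toys": n_toys}


def _recovery_params(
    vc: VarComponents,
    seed: int,
    obs_doys: tuple[int, ...],
    delta_max: float = 0.0,
    gxe_sd: float = 0.0,
) -> SimulationParams:
    return SimulationParams(
        panel_size=RECOVERY_PANEL,
        geometry=(RECOVERY_GEOMETRY.blocks, RECOVERY_GEOMETRY.columns, RECOVERY_GEOMETRY.rows),
        variance_components={"CH": vc},
        obs_doys={"CH": obs_doys},
        delta_max=delta_max,
        gxe_sd=gxe_sd,
        early_fraction=0.0,  # no maturity boost in recovery studies
        fault_rate=0.0,
        seed=seed,
    )


def _recovery_design(seed: int):
    panel = ["Lemmon"] + [f"ACC{i:04d}" for i in range(1, RECOVERY_PANEL)]
    return build_design(panel, RECOVERY_GEOMETRY, reps=2, control_reps=7, seed=seed)


def h2_recovery(
    true_h2: float,
    n_seeds: int = 20,
    seed: int = 0,
    timeline: Timeline = YEAR1_TIMELINE,
) -> dict:
    """Mean estimated H² over simulated trials with known heritability.

    V_R is fixed at 1 and V_G = H²/(1 − H²); 200 accessions × 2 replicates
    in the control field, accession-only structure (the generating one).
    """
    vg = true_h2 / (1.0 - true_h2)
    vc = VarComponents(V_G=vg, V_R=1.0)
    doy = 256  # outside every flowering window
    estimates = []
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32) >> 1
    for s in base:
        design = _recovery_design(int(s))
        trial = simulate_trial(design, _recovery_params(vc, int(s), (doy,)), timeline)
        obs = trial.phenotypes
        obs = obs[(obs["field"] == "control") & (obs["variable"] == "CH")]
        fit = fit_vc_model(obs, CANDIDATE_SPECS[0], variable="CH_256")
        estimates.append(compute_heritability(fit).H2)
    estimates = np.asarray(estimates)
    return {
        "true_h2": true_h2,
        "mean_h2": float(estimates.mean()),
        "bias": float(estimates.mean() - true_h2),
        "n_seeds": n_seeds,
        "n_obs": RECOVERY_GEOMETRY.plots_per_field,
    }


def yr_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    obs_doys: tuple[int, ...] = (165, 178, 205),
    delta_max: float = 0.4,
    timeline: Timeline = YEAR1_TIMELINE,
) -> dict:
    """Mean BLUP-based Yr per DOY vs the generating drought effect δ(t).

    No G×E (gxe_sd = 0), so every accession's true relative reduction at DOY
    t is exactly δ(t); the study measures how well the full
    fit-BLUPs-then-index pipeline recovers it.
    """
    vc = VarComponents(V_G=25.0, V_R=16.0)
    params0 = _recovery_params(vc, 0, tuple(obs_doys), delta_max=delta_max)
    truth_delta = {d: params0.delta(d, timeline) for d in obs_doys}
    sums = {d: 0.0 for d in obs_doys}
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32) >> 1
    for s in base:
        design = _recovery_design(int(s))
        trial = simulate_trial(
            design, _recovery_params(vc, int(s), tuple(obs_doys), delta_max=delta_max), timeline
        )
        obs = trial.phenotypes
        for d in obs_doys:
            blups = {}
            for field in ("control", "drought"):
                sub = obs[
                    (obs["field"] == field) & (obs["variable"] == "CH") & (obs["doy"] == d)
                ]
                fit = fit_vc_model(sub, CANDIDATE_SPECS[0])
                blups[field] = compute_blups(fit)
            yr = compute_yr(blups["control"], blups["drought"])
            sums[d] += float(yr.mean())
    mean_yr = {d: sums[d] / n_seeds for d in obs_doys}
    errors = {d: mean_yr[d] - truth_delta[d] for d in obs_doys}
    return {
        "mean_yr_by_doy": mean_yr,
        "delta_by_doy": truth_delta,
        "max_abs_err": max(abs(e) for e in errors.values()),
        "n_seeds": n_seeds,
    }


def ztest_type1_error(
    n: int = 395, n_sims: int = 10000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical rejection rate of the Yr Z-test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        res = ztest_mean_vs_zero(rng.normal(0.0, 1.0, n))
        if res.p < alpha:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims, "n": n}


def null_overlap(
    n_accessions: int = 395, top_size: int = 50, n_draws: int = 10000, seed: int = 0
) -> dict:
    """Overlap of two independent top-`s` sets out of A accessions.

    Under independence the expected overlap is s²/A (hypergeometric mean).
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"A{i}" for i in range(n_accessions)])
    total = 0
    for _ in range(n_draws):
        a = select_top_set(pd.Series(rng.permutation(n_accessions), index=idx), top_size)
        b = select_top_set(pd.Series(rng.permutation(n_accessions), index=idx), top_size)
        total += overlap(a, b)["n_both"]
    return {
        "mean_overlap": total / n_draws,
        "expected": top_size**2 / n_accessions,
        "n_draws": n_draws,
    }


def overlap_vs_genetic_correlation(
    rhos: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_accessions: int = 395,
    top_size: int = 50,
    n_variables: int = 6,
    noise_sd: float = 0.7,
    n_reps: int = 100,
    seed: int = 0,
) -> dict:
    """Mean top-set overlap fraction across between-field genetic correlations.

    Per replicate, each field's accession values share a genetic component
    with correlation ρ between fields, plus independent per-variable noise;
    the breeder's top-quartile ranking is applied per field and the overlap
    fraction recorded. The fraction should be non-decreasing in ρ.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"A{i}" for i in range(n_accessions)])
    means = {}
    for rho in rhos:
        acc = 0.0
        for _ in range(n_reps):
            g_c = rng.normal(0, 1, n_accessions)
            g_d = rho * g_c + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, 1, n_accessions)
            fields = {}
            for name, g in (("control", g_c), ("drought", g_d)):
                mat = pd.DataFrame(
                    g[:, None] + rng.normal(0, noise_sd, (n_accessions, n_variables)),
                    index=idx,
                    columns=[f"V{j}" for j in range(n_variables)],
                )
                fields[name] = select_top_set(top_quartile_counts(mat), top_size)
            acc += overlap(fields["control"], fields["drought"])["fraction_of_control"]
        means[rho] = acc / n_reps
    return {"fraction_by_rho": means, "n_reps": n_reps}
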