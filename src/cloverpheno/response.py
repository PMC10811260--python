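"""Relative drought-performance indices (Yr) and their significance tests.

For each accession and dated variable, the index

    Yr = (Control − Drought) / Control

compares the accession's value in the irrigated control field with its value
in the rain-out-shelter drought field. Positive Yr means the trait was lower
under drought (growth reduced); negative means the drought field exceeded the
control (e.g. canopy temperature stress indices). Accession values default to
BLUPs from the per-field variance-component fits so spatial noise is removed
before fields are compared.

A two-sided Z-test per variable and date asks whether the panel-average Yr
differs from zero, with the conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import parse_variable

__all__ = [
    "compute_yr",
    "ZTestResult",
    "ztest_mean_vs_zero",
    "significance_stars",
    "yr_time_series",
]

#: |control| below this fraction of the median absolute control value makes
#: Yr undefined (explosive denominator guard)
DENOMINATOR_GUARD = 0.01


def compute_yr(
    control_values: pd.Series,
    drought_values: pd.Series,
    guard: float = DENOMINATOR_GUARD,
) -> pd.Series:
    """Per-accession relative performance index Yr = (C − D)/C.

    The two series are aligned on their (accession) index; accessions missing
    from either field, or whose control value is below ``guard`` times the
    median absolute control value, come back as NaN. No clamping is applied
    above the guard — large negative indices are legitimate (drought value
    far above control).

    Scale-invariant: multiplying both fields by c > 0 leaves Yr unchanged.
    """
    c, d = control_values.align(drought_values, join="outer")
    c = c.astype(float)
    d = d.astype(float)
    ref = np.nanmedian(np.abs(c.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        yr = (c - d) / c
    bad = np.abs(c) < guard * ref
    yr[bad] = np.nan
    yr.name = "Yr"
    return yr


def significance_stars(p: float) -> str:
    """Stars at the conventional thresholds: * 0.05, ** 0.01, *** 0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ZTestResult:
    variable: str
    n: int
    mean: float
    sd: float
    z: float
    p: float
    stars: str
    defined: bool = True
    note: str = ""


def ztest_mean_vs_zero(values, variable: str = "") -> ZTestResult:
    """Two-sided Z-test of mean(values) against zero.

    Uses the sample standard deviation (large-panel normal approximation):
    z = mean/(sd/√n), p from the standard normal. With zero spread the test
    is undefined and flagged rather than raising.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = v.size
    if n < 3:
        raise ValueError(f"Z-test needs at least 3 values, got {n}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return ZTestResult(
            variable, n, mean, sd, float("nan"), float("nan"), "", defined=False,
            note="zero standard deviation: all Yr values identical",
        )
    z = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ZTestResult(variable, n, mean, sd, float(z), p, significance_stars(p))


def yr_time_series(
    yr_table: pd.DataFrame,
    year: int | None = None,
    drought_window: tuple[int, int] | None = None,
    cut_doys: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Panel-average Yr trajectory over DOY with Z-test annotations.

    ``yr_table`` is accessions × Yr variables (columns named ``Yr_VAR_DOY``).
    Returns one row per (year, variable, DOY) ordered by DOY, mirroring the
    tabular layout used for seasonal Yr summaries: n, mean, sd, z, p, stars,
    plus whether the date lies inside the drought window and whether it is a
    cut date (both from config).
    """
    rows = []
    for col in yr_table.columns:
        name = col[3:] if col.startswith("Yr_") else col
        var, doy = parse_variable(name)
        vals = yr_table[col].dropna()
        if len(vals) >= 3 and vals.std(ddof=1) > 0:
            zt = ztest_mean_vs_zero(vals, variable=col)
        else:
            zt = ZTestResult(
                col, len(vals), float(vals.mean()) if len(vals) else float("nan"),
                float("nan"), float("nan"), float("nan"), "", defined=False,
            )
        rows.append(
            {
                "year": year,
                "variable": var,
                "doy": doy,
                "n": zt.n,
                "mean_yr": zt.mean,
                "sd": zt.sd,
                "z": zt.z,
                "p": zt.p,
                "stars": zt.stars,
                "in_drought_window": (
                    bool(drought_window[0] <= doy <= drought_window[1])
                    if drought_window
                    else False
                ),
                "is_cut_doy": doy in set(cut_doys),
            }
        )
    out = pd.DataFrame(rows).sort_values(["variable", "doy"]).reset_index(drop=True)
    return out
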