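"""Observation naming, quality filtering, and ground-vs-UAV validation.

Observations live in a long-format table, one row per
(plot, variable, year, DOY). Variables follow the trial's naming rule: the
variable abbreviation followed by the day of year, e.g. ``CC_178`` for
canopy cover measured on DOY 178.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VARIABLES",
    "FLAGS",
    "name_variable",
    "parse_variable",
    "validate_table",
    "QCRules",
    "filter_observations",
    "FilterResult",
    "correlate_ground_uav",
    "CorrelationResult",
]

#: variable code -> unit
VARIABLES = {
    "CC": "%",
    "CH": "cm",
    "CH_rpm": "cm",
    "CWSI": "",
    "FLD": "DOY",
}

FLAGS = ("ok", "not_established", "damaged", "outlier", "missing")

_NAME_RE = re.compile(r"^(?P<var>[A-Za-z]+(?:_rpm)?)_(?P<doy>\d{1,3})$")


def name_variable(variable: str, doy: int) -> str:
    """Compose the dated variable name, e.g. ``("CC", 178) -> "CC_178"``."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {sorted(VARIABLES)}")
    doy = int(doy)
    if not 1 <= doy <= 366:
        raise ValueError(f"DOY {doy} outside 1..366")
    return f"{variable}_{doy}"


def parse_variable(name: str) -> tuple[str, int]:
    """Invert :func:`name_variable`: ``"CH_165" -> ("CH", 165)``."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse dated variable name {name!r}")
    var, doy = m.group("var"), int(m.group("doy"))
    if var not in VARIABLES:
        raise ValueError(f"unknown variable {var!r} in {name!r}")
    if not 1 <= doy <= 366:
        raise ValueError(f"DOY {doy} outside 1..366 in {name!r}")
    return var, doy


def validate_table(table: pd.DataFrame) -> list[str]:
    """Check long-table invariants; return one message per violation."""
    problems = []
    required = {"plot_id", "field", "accession_id", "variable", "year", "doy", "value", "flag"}
    missing = required - set(table.columns)
    if missing:
        problems.append(f"missing columns: {sorted(missing)}")
        return problems
    dup = table.duplicated(["plot_id", "variable", "year", "doy"]).sum()
    if dup:
        problems.append(f"{dup} duplicated (plot_id, variable, year, doy) rows")
    ok = table["flag"] == "ok"
    cc = table.loc[ok & (table["variable"] == "CC"), "value"]
    if ((cc < 0) | (cc > 100)).any():
        problems.append("CC values outside [0, 100]")
    fld = table.loc[ok & (table["variable"] == "FLD"), "value"]
    if ((fld < 1) | (fld > 222)).any():
        problems.append("FLD values outside [1, 222]")
    if ((table["doy"] < 1) | (table["doy"] > 366)).any():
        problems.append("DOY outside 1..366")
    bad_flags = set(table["flag"].unique()) - set(FLAGS)
    if bad_flags:
        problems.append(f"unknown flags: {sorted(bad_flags)}")
    return problems


@dataclass(frozen=True)
class QCRules:
    """Configuration of the faulty-plot filter.

    ``outlier_multiplier`` sets the statistical-outlier fence: within each
    variable × field × DOY cell, values outside median ± multiplier·IQR are
    excluded. 3·IQR is deliberately conservative so genuine genetic tails are
    kept. ``plot_level_flags`` are faults that discard a plot for every
    variable (crop never established, herbivore damage), not just the flagged
    cell.
    """

    outlier_multiplier: float = 3.0
    plot_level_flags: tuple[str, ...] = ("not_established", "damaged")


@dataclass
class FilterResult:
    table: pd.DataFrame
    report: pd.DataFrame  # variable, n_retained, n_excluded, per-reason counts


def _stat_outlier_pass(values: pd.Series, mult: float) -> pd.Series:
    """Boolean mask of statistical outliers under the median ± mult·IQR fence."""
    v = values.to_numpy(dtype=float)
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return pd.Series((v < med - mult * iqr) | (v > med + mult * iqr), index=values.index)


def filter_observations(
    table: pd.DataFrame, rules: QCRules = QCRules()
) -> FilterResult:
    """Drop faulty plots per variable and statistical outliers.

    Three exclusion classes, mirroring field practice:

    1. plot-level faults (``not_established``, ``damaged``): every
       observation of the plot is dropped for all variables;
    2. cell-level flags (``outlier``, ``missing``) drop the flagged cell;
    3. statistical outliers among unflagged values, per
       variable × field × DOY, outside median ± multiplier·IQR. This fence is
       re-applied until no further value falls outside it, so the filter is
       idempotent by construction (filter∘filter = filter).

    Returns the retained table and an exclusion report with per-variable
    retained/excluded counts by reason.
    """
    t = table.copy()
    reason = pd.Series("", index=t.index, dtype=object)

    bad_plots = set(t.loc[t["flag"].isin(rules.plot_level_flags), "plot_id"])
    in_bad_plot = t["plot_id"].isin(bad_plots)
    reason[in_bad_plot] = "plot_fault"
    flagged = (~in_bad_plot) & (t["flag"] != "ok")
    reason[flagged] = "flagged_" + t.loc[flagged, "flag"].astype(str)

    keep = reason == ""
    if rules.outlier_multiplier is not None and np.isfinite(rules.outlier_multiplier):
        changed = True
        while changed:
            changed = False
            live = t.loc[keep]
            for _, idx in live.groupby(["variable", "field", "year", "doy"]).groups.items():
                vals = t.loc[idx, "value"].dropna()
                if len(vals) < 4:
                    continue
                out = _stat_outlier_pass(vals, rules.outlier_multiplier)
                hit = out.index[out]
                if len(hit):
                    reason[hit] = "stat_outlier"
                    keep[hit] = False
                    changed = True

    kept = t.loc[keep].reset_index(drop=True)
    rep_rows = []
    for var, sub in t.groupby("variable"):
        sub_reason = reason[sub.index]
        counts = sub_reason[sub_reason != ""].value_counts().to_dict()
        rep_rows.append(
            {
                "variable": var,
                "n_retained": int((sub_reason == "").sum()),
                "n_excluded": int((sub_reason != "").sum()),
                **counts,
            }
        )
    report = pd.DataFrame(rep_rows).fillna(0)
    return FilterResult(table=kept, report=report)


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame  # field, year, doy_ground, doy_uav, gap_days, n, r
    skipped: pd.DataFrame  # ground dates with no UAV date within the gap
    mean_r: float


def correlate_ground_uav(
    table: pd.DataFrame,
    ground_var: str = "CH_rpm",
    uav_var: str = "CH",
    max_gap_days: int = 7,
) -> CorrelationResult:
    """Correlate rising-plate-meter and UAV canopy height per time point.

    For each field × year, every ground-measurement date is paired with the
    nearest UAV date at most ``max_gap_days`` away (ties broken toward the
    earlier UAV date) and the per-plot Pearson r is computed over common
    plots. Dates with no UAV partner within the window are listed as skipped;
    pairs with fewer than 3 common plots are reported with r undefined (NaN).
    The operation is symmetric in the two height sources.
    """
    g = table[(table["variable"] == ground_var) & (table["flag"] == "ok")]
    u = table[(table["variable"] == uav_var) & (table["flag"] == "ok")]
    if g.empty or u.empty:
        raise ValueError(f"need observations for both {ground_var} and {uav_var}")

    pair_rows, skip_rows = [], []
    for (field, year), gsub in g.groupby(["field", "year"]):
        usub = u[(u["field"] == field) & (u["year"] == year)]
        uav_doys = np.sort(usub["doy"].unique())
        if uav_doys.size == 0:
            continue
        for doy_g in np.sort(gsub["doy"].unique()):
            gaps = np.abs(uav_doys - doy_g)
            best = gaps.min()
            if best > max_gap_days:
                skip_rows.append(
                    {"field": field, "year": year, "doy_ground": int(doy_g), "nearest_gap": int(best)}
                )
                continue
            # tie toward the earlier UAV date
            candidates = uav_doys[gaps == best]
            doy_u = int(candidates.min())
            gv = gsub[gsub["doy"] == doy_g].set_index("plot_id")["value"]
            uv = usub[usub["doy"] == doy_u].set_index("plot_id")["value"]
            common = gv.index.intersection(uv.index)
            if len(common) < 3:
                r = float("nan")
            else:
                r = float(stats.pearsonr(gv[common], uv[common]).statistic)
            pair_rows.append(
                {
                    "field": field,
                    "year": year,
                    "doy_ground": int(doy_g),
                    "doy_uav": doy_u,
                    "gap_days": int(best),
                    "n": int(len(common)),
                    "r": r,
                }
            )
    pairs = pd.DataFrame(
        pair_rows, columns=["field", "year", "doy_ground", "doy_uav", "gap_days", "n", "r"]
    )
    skipped = pd.DataFrame(skip_rows, columns=["field", "year", "doy_ground", "nearest_gap"])
    mean_r = float(pairs["r"].mean()) if len(pairs) else float("nan")
    return CorrelationResult(pairs=pairs, skipped=skipped, mean_r=mean_r)
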