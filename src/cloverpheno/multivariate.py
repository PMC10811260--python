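"""Variable reduction, PCA overlays, and top-quartile ranking.

Multivariate structure of the accession × trait matrix: redundant dated
variables are first thinned (either to configured mid/end-of-growth-period
dates or by a correlation threshold), PCA summarizes the remainder with
grouping overlays (maturity, geographic origin, variety type), and a simple
breeder's ranking counts how often each accession reaches the top 25% of a
variable, selecting the best set per field and measuring how strongly the
control- and drought-field selections overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "reduce_variables",
    "PCAResult",
    "run_pca",
    "top_quartile_counts",
    "select_top_set",
    "overlap",
]


def reduce_variables(
    matrix: pd.DataFrame,
    selection: Sequence[str] | None = None,
    corr_threshold: float | None = None,
) -> pd.DataFrame:
    """Thin the dated-variable columns of an accession × variable matrix.

    List mode (``selection``): keep exactly the named columns, in the given
    order — typically one mid-growth and one end-of-growth observation per
    growing period. Threshold mode (``corr_threshold``): scan column pairs in
    column order and greedily drop the later column of any pair whose |r|
    exceeds the threshold.
    """
    if selection is not None:
        missing = [c for c in selection if c not in matrix.columns]
        if missing:
            raise KeyError(f"requested variables absent from the matrix: {missing}")
        return matrix.loc[:, list(selection)]
    if corr_threshold is None:
        raise ValueError("give either a selection list or a correlation threshold")
    cols = list(matrix.columns)
    dropped: set[str] = set()
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1 :]:
            if b in dropped:
                continue
            r = matrix[a].corr(matrix[b])
            if np.isfinite(r) and abs(r) > corr_threshold:
                dropped.add(b)
    return matrix.loc[:, [c for c in cols if c not in dropped]]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables × components, orthonormal columns
    scores: pd.DataFrame  # accessions × components
    explained: np.ndarray  # fraction of variance per component
    n_dropped_rows: int
    group_summaries: dict[str, pd.DataFrame] = dc_field(default_factory=dict)

    @property
    def explained_percent(self) -> np.ndarray:
        return 100.0 * self.explained


def run_pca(
    matrix: pd.DataFrame,
    standardize: bool = True,
    groups: Mapping[str, Mapping[str, str]] | pd.DataFrame | None = None,
) -> PCAResult:
    """PCA of an accession × variable matrix.

    Rows with any missing value are dropped (and counted). With
    ``standardize`` (the default — the variables mix %, cm and unitless
    scales) each column is centred and scaled to unit variance; a constant
    column is then an error, named in the message. All components are
    retained, so the explained fractions sum to 1 and are non-increasing.

    ``groups`` maps grouping-name -> (accession -> label); per-group mean
    scores are summarized for overlay plots.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two variable columns")
    clean = matrix.dropna(axis=0, how="any")
    n_dropped = matrix.shape[0] - clean.shape[0]
    X = clean.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [clean.columns[i] for i in flat]
            raise ValueError(f"constant column(s) under standardization: {names}")
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)

    pca = PCA(n_components=min(X.shape[0], X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=clean.columns, columns=comp_names)
    scores_df = pd.DataFrame(scores, index=clean.index, columns=comp_names)
    explained = pca.explained_variance_ratio_

    summaries: dict[str, pd.DataFrame] = {}
    if groups is not None:
        if isinstance(groups, pd.DataFrame):
            groups = {c: groups[c].to_dict() for c in groups.columns}
        for gname, mapping in groups.items():
            labels = scores_df.index.to_series().map(mapping)
            summaries[gname] = scores_df.groupby(labels).mean()
    return PCAResult(
        loadings=loadings,
        scores=scores_df,
        explained=explained,
        n_dropped_rows=n_dropped,
        group_summaries=summaries,
    )


def top_quartile_counts(matrix: pd.DataFrame) -> pd.Series:
    """How many variables place each accession in the top 25%.

    Per variable, the threshold is the 75th percentile (linear interpolation)
    of the observed values; accessions at or above it score one hit — values
    tied with the threshold are included. Missing cells are skipped without
    penalty. Requires at least 4 observed accessions per variable.
    """
    counts = pd.Series(0, index=matrix.index, dtype=int)
    for col in matrix.columns:
        vals = matrix[col].dropna()
        if len(vals) < 4:
            raise ValueError(f"variable {col}: need >= 4 accessions, got {len(vals)}")
        threshold = np.quantile(vals.to_numpy(), 0.75)
        hits = vals.index[vals >= threshold]
        counts[hits] += 1
    counts.name = "top25_hits"
    return counts


def select_top_set(counts: pd.Series, target_size: int = 50) -> set:
    """Accessions with the best top-25% hit counts.

    Returns every accession whose count reaches the ``target_size``-th
    largest count, so ties at the cutoff enlarge the set ("or slightly
    more"). Always at least ``target_size`` members.
    """
    if len(counts) < target_size:
        raise ValueError(f"only {len(counts)} accessions for a top set of {target_size}")
    cutoff = counts.sort_values(ascending=False).iloc[target_size - 1]
    return set(counts.index[counts >= cutoff])


def overlap(set_control: set, set_drought: set) -> dict:
    """Overlap between the two fields' top sets (Table-style schema)."""
    both = set_control & set_drought
    n_control = len(set_control)
    return {
        "n_control": n_control,
        "n_drought": len(set_drought),
        "n_both": len(both),
        "fraction_of_control": (len(both) / n_control) if n_control else float("nan"),
    }
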