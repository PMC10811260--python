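#!/usr/bin/env python
"""Stage 5 — multivariate structure and the breeder's top-set overlap.

Runs PCA on the control-field BLUP matrix (overlaying the maturity classes
recovered from flowering data), then counts top-25% hits per accession for
CC and CH in each field, selects the best set per field, and measures how
strongly the control- and drought-field selections overlap.
"""

import sys
from pathlib import Path

import pandas as pd

from cloverpheno.design import classify_maturity
from cloverpheno.multivariate import overlap, run_pca, select_top_set, top_quartile_counts
from cloverpheno.plots import biplot, yr_trajectory_plot

BASE = Path(__file__).resolve().parent.parent / "results"
TOP_SIZE = 25


def main():
    control = pd.read_csv(BASE / "fits" / "blups_control.csv", index_col=0)
    drought = pd.read_csv(BASE / "fits" / "blups_drought.csv", index_col=0)
    filtered = pd.read_csv(BASE / "qc" / "filtered.csv")
    out = BASE / "multivariate"
    out.mkdir(parents=True, exist_ok=True)

    maturity = classify_maturity(filtered[filtered["variable"] == "FLD"])
    pca = run_pca(control, standardize=True, groups={"maturity": maturity["maturity"].to_dict()})
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pca.scores.to_csv(out / "pca_scores.csv")
    biplot(pca, group_labels=maturity["maturity"]).savefig(out / "pca_biplot.png", dpi=120)

    traj = pd.read_csv(BASE / "response" / "yr_trajectory.csv")
    yr_trajectory_plot(traj, drought_window=(134, 184), cut_doys=(134, 185, 232, 277)).savefig(
        out / "yr_trajectory.png", dpi=120
    )

    rows = []
    for var in ("CC", "CH"):
        sets = {}
        for name, mat in (("control", control), ("drought", drought)):
            cols = [c for c in mat.columns if c.startswith(f"{var}_")]
            sets[name] = select_top_set(top_quartile_counts(mat[cols]), TOP_SIZE)
        rows.append({"variable": var, **overlap(sets["control"], sets["drought"])})
    ranking = pd.DataFrame(rows)
    ranking.to_csv(out / "ranking_overlap.csv", index=False)

    ev = pca.explained_percent
    print(f"PCA: first two components explain {ev[0]:.1f}% + {ev[1]:.1f}% "
          f"= {ev[0] + ev[1]:.1f}% of the variation")
    print(ranking.to_string(index=False))
    for _, r in ranking.iterrows():
        print(f"{r['variable']}: {r['fraction_of_control']:.0%} of the control-field top set "
              "also ranks top under drought")
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
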