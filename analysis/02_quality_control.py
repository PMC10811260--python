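#!/usr/bin/env python
"""Stage 2 — filter faulty plots and validate UAV heights against the ground.

Applies the faulty-plot filter (plot-level faults, flagged cells, and the
median ± 3·IQR statistical fence per variable × field × DOY) and correlates
rising-plate-meter canopy height with the UAV-derived measurement, pairing
observation dates at most 7 days apart.
"""

import sys
from pathlib import Path

import pandas as pd

from cloverpheno.qc import QCRules, correlate_ground_uav, filter_observations

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    obs = pd.read_csv(BASE / "trial" / "observations.csv")
    res = filter_observations(obs, QCRules())
    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / "filtered.csv", index=False)
    res.report.to_csv(out / "qc_report.csv", index=False)

    corr = correlate_ground_uav(res.table, max_gap_days=7)
    corr.pairs.to_csv(out / "ground_uav_correlation.csv", index=False)

    print(f"retained {len(res.table)} of {len(obs)} observations")
    print(res.report.to_string(index=False))
    print(f"ground vs UAV canopy height: mean r = {corr.mean_r:.2f} over "
          f"{len(corr.pairs)} date pairs (gaps ≤ {corr.pairs['gap_days'].max()} days)")
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
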