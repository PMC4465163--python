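#!/usr/bin/env python
"""Feature robustness: how stable is each PET parameter when the VOI
definition changes from a SUV 2.0 to a SUV 2.5 isocontour, and how strongly
does each parameter depend on metabolic tumor volume?

Writes results/tables/stability_table.csv and size_table.csv.
"""

from pathlib import Path

import pandas as pd

from pettex import pearson_table, size_dependency
from pettex.features import PARAMETER_COLUMNS

ROOT = Path(__file__).resolve().parents[1]
TABLE_DIR = ROOT / "results" / "tables"


def main() -> None:
    f20 = pd.read_csv(ROOT / "results" / "cohort" / "features_suv2.0.csv")
    f25 = pd.read_csv(ROOT / "results" / "cohort" / "features_suv2.5.csv")

    stability = pearson_table(f20, f25, columns=list(PARAMETER_COLUMNS))
    size = size_dependency(
        f20, columns=[c for c in PARAMETER_COLUMNS if c != "mtv_ml"])
    TABLE_DIR.mkdir(parents=True, exist_ok=True)
    stability.to_csv(TABLE_DIR / "stability_table.csv", index=False)
    size.to_csv(TABLE_DIR / "size_table.csv", index=False)

    print("stability across VOI definitions (SUV 2.0 vs 2.5):")
    for _, r in stability.iterrows():
        print(f"  {r.feature:<12} r={r.r:.3f}   "
              f"2.0: {r.mean_a:.3g} +/- {r.sd_a:.3g}   "
              f"2.5: {r.mean_b:.3g} +/- {r.sd_b:.3g}")
    print("correlation with MTV:")
    for _, r in size.iterrows():
        sig = " *" if r.p < 0.05 else ""
        print(f"  {r.feature:<12} r={r.r:+.3f}  p={r.p:.3g}{sig}")
    print(f"tables -> {TABLE_DIR}")


if __name__ == "__main__":
    main()
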