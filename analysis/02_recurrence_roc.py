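#!/usr/bin/env python
"""ROC analysis: which PET parameters predict local recurrence, nodal and
distant relapse, and death, in the whole cohort and the T2 subgroup?

Reads the tables written by 01_simulate_cohort.py; writes
results/tables/roc_table.csv.
"""

from pathlib import Path

import pandas as pd

from pettex.pipeline import ENDPOINTS, build_roc_table

ROOT = Path(__file__).resolve().parents[1]
TABLE_DIR = ROOT / "results" / "tables"


def main() -> None:
    features = pd.read_csv(ROOT / "results" / "cohort" / "features_suv2.0.csv")
    outcomes = pd.read_csv(ROOT / "results" / "cohort" / "outcomes.csv")
    roc = build_roc_table(features, outcomes, ENDPOINTS)
    TABLE_DIR.mkdir(parents=True, exist_ok=True)
    roc.to_csv(TABLE_DIR / "roc_table.csv", index=False)

    lr = roc[(roc.endpoint == "LR") & roc.significant].sort_values(
        "auc", ascending=False)
    print("significant LR predictors (whole cohort):")
    for _, r in lr.iterrows():
        print(f"  {r.parameter:<12} AUC {r.auc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})")
    lr_t2 = roc[(roc.endpoint == "LR_T2") & roc.significant]
    print(f"significant LR predictors within T2: "
          f"{', '.join(lr_t2.parameter) or 'none'}")
    for ep in ("LN", "DM"):
        sig = roc[(roc.endpoint == ep) & roc.significant]
        print(f"significant {ep} predictors: {', '.join(sig.parameter) or 'none'}")
    print(f"table -> {TABLE_DIR / 'roc_table.csv'}")


if __name__ == "__main__":
    main()
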