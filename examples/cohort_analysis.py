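"""End-to-end cohort run: classification, report tables, stepwise model.

Draws a synthetic 89-eye cohort (47 responsive, 42 refractory) at the
published group moments, classifies each eye by its treatment course,
and writes the group-comparison table, the ROC/DeLong table and the
backward-stepwise logistic selection trace to a run directory.
"""

import json
from pathlib import Path

import pandas as pd

from faleak import RunConfig, run_pipeline

out = run_pipeline(RunConfig(source="cohort", out_dir="scratch/example-run",
                             seed=11))

summary = json.loads((out / "run_summary.json").read_text())
print(f"cohort: {summary['n_eyes']} eyes, {summary['n_responsive']} responsive "
      f"({summary['responsive_percent']}%), {summary['n_refractory']} refractory")

table2 = pd.read_csv(out / "table2.csv")
print("\nROC table (refractory vs responsive; DeLong p vs pre-treatment CRT):")
print(table2.to_string(index=False))

trace = json.loads((out / "stepwise.json").read_text())
print("\nbackward stepwise logistic regression:")
for r in trace["removed"]:
    print(f"  step {r['step']}: removed {r['variable']} (p = {r['p_at_removal']})")
for var, d in trace["final"].items():
    lo, hi = d["or_ci95"]
    print(f"  retained {var}: OR {d['odds_ratio']:.3f} per unit "
          f"(95% CI {lo:.3f}-{hi:.3f}, p = {d['p']})")
print("\nAn AUC near 0.85 for the perifoveal score vs ~0.65 for CRT means the")
print("quantified leakage separates refractory from responsive eyes far better")
print("than baseline retinal thickness.")
print(f"\nall artefacts written under {Path(out).resolve()}")
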