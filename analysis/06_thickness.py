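#!/usr/bin/env python
"""Correlate ROI cortical thickness with MSNA inhibition: bilateral
rostral-ACC estimate (mean of left+right), insula and Rolandic controls,
Spearman correlations with Bonferroni correction over the three
pre-selected ROIs.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from msna_cortex.morphometry import roi_thickness_report

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    prof_path = ROOT / "results" / "02_msna_profiles.csv"
    if not (cohort_dir / "thickness.csv").exists() or not prof_path.exists():
        raise SystemExit("run 01_simulate.py and 02_msna_profiles.py first")
    table = pd.read_csv(cohort_dir / "thickness.csv").sort_values("subject")
    profiles = pd.read_csv(prof_path).sort_values("subject")
    inh = profiles["inhibition"].to_numpy()

    report = roi_thickness_report(table, inh)
    out = {r.roi: {"spearman_r": round(r.r, 3),
                   "p_raw": round(r.p_raw, 5),
                   "p_bonferroni": round(r.p_adjusted, 5), "n": r.n}
           for r in report}
    res = ROOT / "results"
    (res / "06_thickness.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n")
    for r in report:
        print(f"{r.roi:8s} thickness vs inhibition: r_s = {r.r:+.2f}, "
              f"raw p = {r.p_raw:.4f}, Bonferroni p = {r.p_adjusted:.4f}")


if __name__ == "__main__":
    main()
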