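#!/usr/bin/env python
"""Compare stimulus-locked blood-pressure responses between Inhibitors and
Non-inhibitors: trial-averaged change-from-baseline per beat, Wilcoxon
rank-sum on MAP and DBP at post-stimulus cardiac interval 6, a beat-by-beat
(1-15) screen of heart rate and pulse pressure, and the Spearman
correlation of individual inhibition vs the beat-6 BP change.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from msna_cortex import hemodynamics

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    prof_path = ROOT / "results" / "02_msna_profiles.csv"
    if not (cohort_dir / "bp_beats.csv").exists() or not prof_path.exists():
        raise SystemExit("run 01_simulate.py and 02_msna_profiles.py first")
    profiles = pd.read_csv(prof_path)
    bp = pd.read_csv(cohort_dir / "bp_beats.csv")
    # analysis uses the *measured* groups, not the generator's labels
    bp["group"] = bp["subject"].map(
        profiles.set_index("subject")["group"])

    beats = hemodynamics.align_beats(bp)
    c_map = hemodynamics.compare_groups(beats, beat=6, measure="map")
    c_dbp = hemodynamics.compare_groups(beats, beat=6, measure="dbp")
    screen = hemodynamics.screen_beats(beats)
    inh = profiles.set_index("subject")["inhibition"].to_dict()
    r_s, p_s = hemodynamics.correlate_inhibition_bp(inh, beats)

    out = {
        "beat6_map": {"p": c_map.p_value, "n_groups": list(c_map.n_groups),
                      "method": c_map.method},
        "beat6_dbp": {"p": c_dbp.p_value},
        "screen": [{"beat": c.beat, "measure": c.measure,
                    "p": round(c.p_value, 4)} for c in screen],
        "screen_any_below_05": bool(any(c.p_value < 0.05 for c in screen)),
        "inhibition_bp_spearman": {"r": r_s, "p": p_s},
    }
    res = ROOT / "results"
    (res / "03_bp_results.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n")
    print(f"MAP change at beat 6, Non-inhibitors vs Inhibitors "
          f"(n={c_map.n_groups[0]}+{c_map.n_groups[1]}): "
          f"p = {c_map.p_value:.3f} ({c_map.method} rank-sum)")
    print(f"DBP change at beat 6: p = {c_dbp.p_value:.3f}")
    print(f"HR/pulse-pressure screen beats 1-15: any p<0.05 -> "
          f"{out['screen_any_below_05']}")
    print(f"Spearman inhibition vs beat-6 MAP change: "
          f"r_s = {r_s:.2f}, p = {p_s:.3f}")


if __name__ == "__main__":
    main()
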