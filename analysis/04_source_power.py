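#!/usr/bin/env python
"""Demonstrate the LCMV source-reconstruction chain on sensor projections:
project each subject's ROI source epochs through a toy leadfield, estimate
the combined-condition covariance, beamform every 5 mm grid point,
baseline-contrast source power, apply the 60%-of-peak vertex selection,
and verify the recovered ROI trial series against the generating source.
"""

import json
import sys
from pathlib import Path

import numpy as np

from msna_cortex import source_recon
from msna_cortex.synthetic import (ROI_LABELS, CohortSpec, gen_cohort,
                                   gen_sensor_epochs, make_toy_leadfield)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]
N_DEMO_SUBJECTS = 5


def main() -> None:
    spec = CohortSpec(n_subjects=N_DEMO_SUBJECTS, seed=SEED, n_trials=24,
                      iti_menu=(14.0,))
    cohort = gen_cohort(spec, stages=("source",))
    lead = make_toy_leadfield(n_channels=24, seed=SEED)
    fs = spec.source_fs
    rows = []
    for sub in cohort.subjects:
        sens, active = gen_sensor_epochs(sub.source_epochs, lead, snr=1.0,
                                         seed=SEED * 131 + sub.subject)
        for roi in ROI_LABELS:
            rts = source_recon.beamform_roi(sens, lead, roi, fs)
            rec = rts.series["pulse3"]
            src = sub.source_epochs[roi].epochs["pulse3"]
            r = float(np.corrcoef(rec.ravel(), src.ravel())[0, 1])
            rows.append({"subject": sub.subject, "roi": roi,
                         "n_selected_vertices": int(
                             len(rts.selected_points)),
                         "active_point_selected": bool(
                             active[roi] - np.flatnonzero(
                                 lead.roi_label == roi)[0]
                             in rts.selected_points),
                         "series_corr_with_source": round(abs(r), 3)})
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "04_beamformer.json").write_text(
        json.dumps(rows, indent=2, sort_keys=True) + "\n")
    corr = np.array([x["series_corr_with_source"] for x in rows])
    print(f"{len(rows)} subject x ROI reconstructions at SNR 1.0")
    print(f"median |corr| between recovered ROI series and generating "
          f"source: {np.median(corr):.3f} (min {corr.min():.3f})")


if __name__ == "__main__":
    main()
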