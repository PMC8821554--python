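"""Readers/writers for the cohort artifact formats.

A cohort directory holds per-subject subdirectories (``sub-00`` ...) with
``events.tsv`` (onset_s, trial, pulse, type), ``cardiac.tsv`` (r_time_s),
``neurogram.h5`` (datasets samples, r_times; attr fs) and
``source_epochs.h5`` (one condition-named trials x time dataset per ROI
group; attr fs), plus cohort-level ``bp_beats.csv``, ``thickness.csv``
and ``ground_truth.json``.  Real recordings exported in the same shapes
drop in unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import (CONDITIONS, CardiacSeries, Cohort,
                        NeurogramRecording, SourceEpochSet, StimulusProtocol)


def write_events(protocol: StimulusProtocol, path: Path) -> None:
    rows = []
    for t in range(protocol.n_trials):
        for k in range(protocol.n_pulses):
            rows.append((protocol.pulse_times[t, k], t, k + 1, "pulse"))
    df = pd.DataFrame(rows, columns=["onset_s", "trial", "pulse", "type"])
    df.to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def protocol_from_events(events: pd.DataFrame, r_times: np.ndarray,
                         variant: str = "microneurography",
                         post_r_latency: float = 0.2) -> StimulusProtocol:
    """Rebuild a StimulusProtocol from an events table and R-wave times."""
    ev = events[events["type"] == "pulse"].sort_values(["trial", "pulse"])
    n_trials = ev["trial"].nunique()
    n_pulses = ev["pulse"].nunique()
    times = ev["onset_s"].to_numpy().reshape(n_trials, n_pulses)
    intervals = np.searchsorted(r_times, times - post_r_latency + 1e-9) - 0
    intervals = np.clip(intervals - 1, 0, None)
    return StimulusProtocol(variant=variant, pulse_intervals=intervals,
                            pulse_times=times,
                            iti_seq=np.full(n_trials, np.nan),
                            post_r_latency=post_r_latency)


def write_cardiac(cardiac: CardiacSeries, path: Path) -> None:
    pd.DataFrame({"r_time_s": cardiac.r_times}).to_csv(path, sep="\t",
                                                       index=False)


def read_cardiac(path: Path, duration: float | None = None) -> CardiacSeries:
    r = pd.read_csv(path, sep="\t")["r_time_s"].to_numpy()
    return CardiacSeries(r_times=r,
                         duration=duration if duration else float(r[-1]) + 2.0)


def write_neurogram(neurogram: NeurogramRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=neurogram.samples)
        f.create_dataset("r_times", data=neurogram.r_times)
        f.attrs["fs"] = neurogram.fs


def read_neurogram(path: Path) -> NeurogramRecording:
    with h5py.File(path, "r") as f:
        return NeurogramRecording(samples=f["samples"][:],
                                  fs=float(f.attrs["fs"]),
                                  r_times=f["r_times"][:])


def write_source_epochs(epochs_by_roi: dict, path: Path) -> None:
    with h5py.File(path, "w") as f:
        for roi, es in epochs_by_roi.items():
            grp = f.create_group(roi)
            grp.attrs["fs"] = es.fs
            for cond in CONDITIONS:
                grp.create_dataset(cond, data=es.epochs[cond])


def read_source_epochs(path: Path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for roi in f:
            out[roi] = SourceEpochSet(
                epochs={c: f[roi][c][:] for c in CONDITIONS},
                fs=float(f[roi].attrs["fs"]), roi=roi)
    return out


def save_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        d = out_dir / f"sub-{sub.subject:02d}"
        d.mkdir(exist_ok=True)
        write_cardiac(sub.cardiac, d / "cardiac.tsv")
        write_events(sub.protocol_meg, d / "events.tsv")
        if sub.protocol_micro is not None:
            write_events(sub.protocol_micro, d / "events_micro.tsv")
        if sub.neurogram is not None:
            write_neurogram(sub.neurogram, d / "neurogram.h5")
        if sub.source_epochs is not None:
            write_source_epochs(sub.source_epochs, d / "source_epochs.h5")
    if cohort.bp_beats is not None:
        cohort.bp_beats.to_csv(out_dir / "bp_beats.csv", index=False)
    if cohort.thickness is not None:
        cohort.thickness.to_csv(out_dir / "thickness.csv", index=False)
    gt = cohort.ground_truth
    payload = {
        "inhibition": gt.inhibition.tolist(),
        "group": gt.group.tolist(),
        "rebound_gain": {k: v.tolist() for k, v in gt.rebound_gain.items()},
        "realized_spearman": gt.realized_spearman,
        "cluster_window": list(gt.cluster_window),
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))


def dump_json(obj, path: Path) -> None:
    """Deterministic JSON dump (sorted keys, plain floats)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
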