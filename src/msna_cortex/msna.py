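"""MSNA burst quantification and the stimulus-induced inhibition statistic.

The integrated neurogram is reduced to one burst amplitude per cardiac
interval (absent burst = amplitude exactly 0).  Stimulus-induced MSNA
inhibition is the percent reduction of the mean post-stimulus amplitude
relative to a control period of 8 cardiac intervals immediately preceding
each stimulation:

    inhibition% = 100 * (1 - mean(post) / mean(control))

Absent bursts contribute zeros to both means, so the statistic mixes burst
incidence and amplitude effects.  It is bounded above by +100% (complete
post-stimulus burst absence; amplitudes are non-negative) and unbounded
below (-200% corresponds to post-stimulus bursts three times the baseline
mean).  Subjects with inhibition strictly greater than 30% are classified
as Inhibitors; the 30% bound is the calibrated 95% normal-variability band
of the same statistic computed against dummy (R-wave-timed, no stimulus)
triggers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import (BURST_LATENCY_S, CardiacSeries, NeurogramRecording,
                        StimulusProtocol)

#: peak-search window relative to each R-wave (s); brackets the typical
#: peroneal reflex latency of the integrated burst
DETECTION_WINDOW_S = (0.8, 1.8)

INHIBITOR = "Inhibitor"
NON_INHIBITOR = "Non-inhibitor"


class UndefinedStatisticError(ArithmeticError):
    """Zero baseline amplitude: relative change is undefined."""


@dataclass
class BurstSeries:
    """One amplitude per cardiac interval, aligned to r_times[:-1]."""

    amplitudes: np.ndarray
    detected: np.ndarray  # bool
    r_times: np.ndarray

    @property
    def n_intervals(self) -> int:
        return len(self.amplitudes)


@dataclass
class InhibitionProfile:
    inhibition: float  # percent
    group: str
    n_trials_used: int
    burst_incidence: float | None = None  # per 100 heartbeats
    burst_frequency: float | None = None  # per minute
    reliable: bool = True


@dataclass
class DummyCalibration:
    deviations: np.ndarray  # per-subject inhibition vs dummy triggers (%)
    bound: float            # symmetric bound covering 95% of subjects (%)


def detect_bursts(neurogram: NeurogramRecording,
                  window: tuple[float, float] = DETECTION_WINDOW_S,
                  baseline_window_s: float = 10.0) -> BurstSeries:
    """Peak-pick one burst amplitude per cardiac interval.

    The neurogram is baseline-corrected with a rolling 10 s median, then
    the peak within [0.8, 1.8] s after each R-wave is attributed to that
    interval.  Peaks below 3x the robust noise SD (1.4826 * MAD), or below
    2% of the largest corrected peak, are treated as absent bursts
    (amplitude 0).
    """
    import pandas as pd

    x = np.asarray(neurogram.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty neurogram")
    r = np.asarray(neurogram.r_times, dtype=float)
    if len(r) < 11:
        raise ValueError("need at least 10 cardiac intervals")
    fs = neurogram.fs
    if fs < 100:
        raise ValueError("neurogram sampling rate must be >= 100 Hz")
    if r[0] < 0 or r[-1] * fs > len(x):
        raise ValueError("r_times outside the sampled range")

    w = int(round(baseline_window_s * fs)) | 1
    baseline = pd.Series(x).rolling(w, min_periods=1, center=True) \
        .median().to_numpy()
    corr = x - baseline

    mad = np.median(np.abs(corr - np.median(corr)))
    peak_max = corr.max() if corr.size else 0.0
    threshold = max(3.0 * 1.4826 * mad, 0.02 * peak_max, 1e-12)

    n = len(r) - 1
    amps = np.zeros(n)
    for i in range(n):
        lo = int(round((r[i] + window[0]) * fs))
        hi = int(round((r[i] + window[1]) * fs))
        lo, hi = max(lo, 0), min(hi, len(corr))
        if lo >= hi:
            continue
        peak = corr[lo:hi].max()
        if peak > threshold:
            amps[i] = peak
    return BurstSeries(amplitudes=amps, detected=amps > 0, r_times=r)


def _trial_windows(protocol: StimulusProtocol, n_intervals: int,
                   n_baseline: int, post_intervals_per_pulse: int):
    """(control_idx, post_idx) per usable trial."""
    out = []
    for t in range(protocol.n_trials):
        pulses = protocol.pulse_intervals[t]
        first = int(pulses[0])
        ctrl = np.arange(first - n_baseline, first)
        post = np.concatenate([np.arange(p, p + post_intervals_per_pulse)
                               for p in pulses])
        if ctrl[0] < 0 or post[-1] >= n_intervals:
            continue
        out.append((ctrl, post))
    return out


def compute_inhibition(bursts: BurstSeries, protocol: StimulusProtocol,
                       n_baseline: int = 8,
                       post_intervals_per_pulse: int = 1,
                       threshold: float = 30.0,
                       mode: str = "grand") -> InhibitionProfile:
    """Stimulus-induced MSNA inhibition (%) and Inhibitor classification.

    ``mode='grand'`` (default) pools amplitudes over all trials before
    forming the post/control ratio, which stays defined when individual
    trials have no baseline bursts; ``mode='per_trial'`` averages per-trial
    ratios instead.
    """
    amps = bursts.amplitudes
    windows = _trial_windows(protocol, len(amps), n_baseline,
                             post_intervals_per_pulse)
    if not windows:
        raise ValueError("no trial has the required control period")
    ctrl_vals = np.concatenate([amps[c] for c, _ in windows])
    post_vals = np.concatenate([amps[p] for _, p in windows])

    if mode == "grand":
        base_mean = ctrl_vals.mean()
        if base_mean == 0:
            raise UndefinedStatisticError("zero baseline burst amplitude")
        inhibition = 100.0 * (1.0 - post_vals.mean() / base_mean)
    elif mode == "per_trial":
        ratios = []
        for c, p in windows:
            b = amps[c].mean()
            if b > 0:
                ratios.append(amps[p].mean() / b)
        if not ratios:
            raise UndefinedStatisticError("zero baseline burst amplitude")
        inhibition = 100.0 * (1.0 - float(np.mean(ratios)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    reliable = int(np.count_nonzero(ctrl_vals)) >= 5
    if not reliable:
        warnings.warn("fewer than 5 baseline bursts: inhibition estimate "
                      "flagged unreliable", stacklevel=2)
    return InhibitionProfile(inhibition=float(inhibition),
                             group=classify(inhibition, threshold),
                             n_trials_used=len(windows), reliable=reliable)


def classify(inhibition: float, threshold: float = 30.0) -> str:
    """Strictly-greater rule: Inhibitor iff inhibition > threshold (%).

    A strongly negative value (e.g. the -132% sympathetic-excitation
    outlier) is a Non-inhibitor by definition.
    """
    if not np.isfinite(inhibition):
        raise ValueError("inhibition must be finite")
    return INHIBITOR if inhibition > threshold else NON_INHIBITOR


def calibrate_dummy(deviation_sets, coverage: float = 95.0) -> DummyCalibration:
    """Normal-variability bound from dummy (no-stimulus) triggers.

    ``deviation_sets`` holds one inhibition-vs-dummy value per subject
    (either precomputed percents, or (BurstSeries, StimulusProtocol) pairs
    to evaluate).  The bound is the ``coverage``-th percentile of absolute
    deviations (linear interpolation), i.e. the symmetric band within
    which that fraction of null subjects falls.
    """
    devs = []
    for item in deviation_sets:
        if isinstance(item, tuple):
            series, dummy_protocol = item
            devs.append(compute_inhibition(series, dummy_protocol).inhibition)
        else:
            devs.append(float(item))
    devs = np.asarray(devs, dtype=float)
    if len(devs) < 5:
        warnings.warn("dummy calibration on < 5 subjects is unstable",
                      stacklevel=2)
    bound = float(np.percentile(np.abs(devs), coverage))
    return DummyCalibration(deviations=devs, bound=bound)


def resting_metrics(bursts: BurstSeries, cardiac: CardiacSeries,
                    protocol: StimulusProtocol | None = None,
                    n_baseline: int = 8,
                    post_intervals_per_pulse: int = 1
                    ) -> tuple[float, float]:
    """Resting burst incidence (per 100 heartbeats) and frequency (per min).

    When a protocol is given, intervals from each trial's control period
    through its post-stimulus window are excluded so only stimulus-free
    segments count as rest; control intervals themselves are pre-stimulus
    but are excluded to keep the segments strictly task-free.
    """
    n = bursts.n_intervals
    mask = np.ones(n, dtype=bool)
    if protocol is not None:
        for t in range(protocol.n_trials):
            pulses = protocol.pulse_intervals[t]
            lo = max(int(pulses[0]) - n_baseline, 0)
            hi = min(int(pulses[-1]) + post_intervals_per_pulse, n)
            mask[lo:hi] = False
    n_beats = int(mask.sum())
    if n_beats == 0:
        raise ValueError("no stimulus-free intervals")
    n_bursts = int(np.count_nonzero(bursts.amplitudes[mask]))
    rr = np.diff(cardiac.r_times)[:n]
    minutes = float(rr[mask].sum()) / 60.0
    bi = 100.0 * n_bursts / n_beats
    bf = n_bursts / minutes if minutes > 0 else 0.0
    return bi, bf


def profile_subject(neurogram: NeurogramRecording, cardiac: CardiacSeries,
                    protocol: StimulusProtocol,
                    **inhibition_kwargs) -> InhibitionProfile:
    """Detect bursts, compute inhibition, classify, and attach resting
    metrics: the per-subject microneurography analysis in one call."""
    bursts = detect_bursts(neurogram)
    prof = compute_inhibition(bursts, protocol, **inhibition_kwargs)
    bi, bf = resting_metrics(bursts, cardiac, protocol)
    prof.burst_incidence = bi
    prof.burst_frequency = bf
    return prof
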