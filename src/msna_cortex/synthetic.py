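"""Synthetic cohort generator for stimulus-locked MSNA / MEG / BP studies.

Every input the analysis chain consumes is generated here with controllable
ground-truth couplings: ECG R-wave series, integrated MSNA neurograms with a
per-subject stimulus-induced inhibition parameter, the two R-wave-locked
stimulation protocols (microneurography: 5 shocks in 5 consecutive cardiac
intervals; MEG: 3 pulses every other heartbeat, 200 ms post-R), beat-by-beat
blood-pressure tables with a group-dependent post-stimulus rise, ROI
source-space oscillatory epochs with beta desynchronization/rebound coupled
to inhibition, toy leadfields with sensor projections, and per-subject ROI
cortical-thickness tables.

All randomness flows from one integer seed; per-subject, per-stage streams
are split so stages can be regenerated independently and a fixed spec is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ROI_LABELS = ("racc", "insula", "rolandic")
CONDITIONS = ("baseline", "pulse1", "pulse2", "pulse3")

#: post-R latency of every stimulus pulse (s)
PULSE_LATENCY_S = 0.200
#: reflex burst latency on the integrated neurogram (s post-R)
BURST_LATENCY_S = 1.3
#: burst hump full width at half maximum (s)
BURST_FWHM_S = 0.3
#: analysis window after each pulse (s)
EPOCH_WINDOW_S = 1.5

# stage codes used to split per-subject RNG streams
_STAGE = {
    "inhibition": 11,
    "cardiac": 23,
    "neurogram": 37,
    "source": 53,
    "bp": 67,
    "thickness": 79,
    "protocol": 97,
    "sensors": 113,
}


class SpecError(ValueError):
    """Invalid cohort specification."""


class TruncationError(RuntimeError):
    """Recording too short to host the requested protocol."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the resting characteristics of the modeled cohort
    (20 healthy males; resting HR 56 +/- 7.8 bpm, burst incidence 44.3
    per 100 heartbeats, burst frequency ~25/min) and its protocol
    (72 trials, ITI 30/45/60 s).
    """

    n_subjects: int = 20
    seed: int = 0
    inhibition_mean: float = 30.0   # percent
    inhibition_sd: float = 25.0     # percent
    outlier_inhibition: float | None = None
    heart_rate_mean: float = 56.0   # beats/min
    heart_rate_sd: float = 7.8
    burst_incidence: float = 44.3   # bursts per 100 heartbeats
    burst_amplitude_cv: float = 0.3
    rebound_coupling: float = 0.8   # in [0, 1]
    thickness_coupling: float = 0.6  # in [-1, 1]
    bp_rise_nonin: float = 4.0      # mmHg at beat 6
    n_trials: int = 72
    iti_menu: tuple[float, ...] = (30.0, 45.0, 60.0)
    neurogram_fs: float = 100.0
    source_fs: float = 200.0
    neurogram_noise_sd: float = 0.03
    bp_beat_noise_sd: float = 2.0
    bp_subject_sd: float = 1.5
    thickness_noise_sd: float = 0.08
    # which pulses of a trial carry the inhibition effect (1-based)
    inhibited_pulses: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SpecError("n_subjects must be >= 2")
        if self.inhibition_sd <= 0:
            raise SpecError("inhibition_sd must be positive")
        if self.heart_rate_mean <= 0:
            raise SpecError("heart_rate_mean must be positive")
        if not 0.0 <= self.burst_incidence <= 100.0:
            raise SpecError("burst_incidence must be in [0, 100]")
        if not 0.0 <= self.rebound_coupling <= 1.0:
            raise SpecError("rebound_coupling must be in [0, 1]")
        if not -1.0 <= self.thickness_coupling <= 1.0:
            raise SpecError("thickness_coupling must be in [-1, 1]")
        if self.n_trials < 1:
            raise SpecError("n_trials must be >= 1")


@dataclass
class CardiacSeries:
    """Strictly increasing R-wave times (s) over a recording."""

    r_times: np.ndarray
    duration: float

    @property
    def heart_rate(self) -> float:
        return 60.0 / float(np.mean(np.diff(self.r_times)))

    @property
    def n_intervals(self) -> int:
        return len(self.r_times) - 1


@dataclass
class NeurogramRecording:
    """Rectified/integrated MSNA neurogram, non-negative by construction."""

    samples: np.ndarray
    fs: float
    r_times: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class StimulusProtocol:
    """Trials of R-wave-locked pulses.

    pulse_intervals[t, k] is the cardiac-interval index hosting pulse k of
    trial t; pulse_times[t, k] = r_times[idx] + 200 ms.
    """

    variant: str  # "microneurography" | "meg"
    pulse_intervals: np.ndarray  # (n_trials, n_pulses) int
    pulse_times: np.ndarray      # (n_trials, n_pulses) float s
    iti_seq: np.ndarray          # (n_trials,) s, ITI preceding each trial
    post_r_latency: float = PULSE_LATENCY_S

    @property
    def n_trials(self) -> int:
        return self.pulse_intervals.shape[0]

    @property
    def n_pulses(self) -> int:
        return self.pulse_intervals.shape[1]


@dataclass
class SourceEpochSet:
    """Per-ROI trial epochs for baseline and the three pulse conditions."""

    epochs: dict  # condition -> (n_trials, n_samples)
    fs: float
    roi: str
    window_s: float = EPOCH_WINDOW_S

    def __post_init__(self) -> None:
        counts = {c: self.epochs[c].shape[0] for c in CONDITIONS}
        if len(set(counts.values())) != 1:
            raise SpecError(f"unequal trial counts across conditions: {counts}")


@dataclass
class LeadfieldModel:
    """Toy forward model: per-grid-point fixed-orientation sensor topographies."""

    grid_points: np.ndarray   # (G, 3) mm, 5 mm lattice
    leadfield: np.ndarray     # (G, n_channels) or (G, n_channels, 3)
    roi_label: np.ndarray     # (G,) str

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[1]


@dataclass
class GroundTruth:
    """Generator-side truth, stored with every cohort, never fed to analysis."""

    inhibition: np.ndarray
    group: np.ndarray  # "Inhibitor" | "Non-inhibitor"
    rebound_gain: dict  # roi -> (n_subjects,) multiplicative rebound gain
    realized_spearman: dict  # name -> float
    cluster_window: tuple = (0.5, 1.2, 13.0, 25.0)  # t0, t1, f0, f1
    bp_rise: np.ndarray | None = None


@dataclass
class SubjectData:
    subject: int
    inhibition: float
    group: str
    cardiac: CardiacSeries
    protocol_meg: StimulusProtocol
    protocol_micro: StimulusProtocol | None = None
    neurogram: NeurogramRecording | None = None
    source_epochs: dict | None = None  # roi -> SourceEpochSet


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list
    bp_beats: "object"          # pandas DataFrame
    thickness: "object"         # pandas DataFrame
    ground_truth: GroundTruth


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _squash(z: np.ndarray | float) -> np.ndarray | float:
    """Strictly monotone soft clip of a z-score to (-2.5, 2.5)."""
    return 2.5 * np.tanh(np.asarray(z, dtype=float) / 2.5)


# ---------------------------------------------------------------------------
# cardiac series and protocols
# ---------------------------------------------------------------------------

def gen_cardiac(heart_rate: float, duration: float, rng: np.random.Generator,
                rr_log_sd: float = 0.05) -> CardiacSeries:
    """R-wave series with log-normal RR jitter around 60/heart_rate."""
    mean_rr = 60.0 / heart_rate
    n = int(np.ceil(duration / mean_rr)) + 16
    rr = mean_rr * np.exp(rng.normal(-0.5 * rr_log_sd ** 2, rr_log_sd, n))
    rr = np.maximum(rr, 0.31)  # physiological floor, keeps diffs > 0.3 s
    r = np.concatenate([[1.0], 1.0 + np.cumsum(rr)])
    r = r[r < duration]
    return CardiacSeries(r_times=r, duration=duration)


def gen_protocol(cardiac: CardiacSeries, variant: str, n_trials: int = 72,
                 iti_menu: Sequence[float] = (30.0, 45.0, 60.0),
                 seed: int = 0) -> StimulusProtocol:
    """R-wave-locked stimulus trains.

    microneurography: 5 shocks in 5 consecutive cardiac intervals.
    meg: 3 pulses every other heartbeat, spaced so a 1.5 s post-pulse
    window never overlaps the next pulse (trials shifted to slower beats
    when the local heart rate is too high).

    The ITI sequence depends only on ``seed`` and the menu, so one seed
    reproduces the same randomized sequence for every subject.
    """
    if variant not in ("microneurography", "meg"):
        raise ValueError(f"unknown protocol variant {variant!r}")
    menu = np.sort(np.asarray(list(iti_menu), dtype=float))
    iti_seq = _rng(seed, _STAGE["protocol"]).choice(menu, size=n_trials)

    r = cardiac.r_times
    if variant == "microneurography":
        offsets = np.arange(5)
    else:
        offsets = np.array([0, 2, 4])
    pulse_intervals = np.empty((n_trials, len(offsets)), dtype=int)
    cursor = iti_seq[0]
    max_scan = 40  # beats to look ahead for a non-overlapping placement
    for t in range(n_trials):
        b0 = int(np.searchsorted(r, cursor))
        b = None
        if variant == "meg":
            # prefer a start beat whose inter-pulse gaps fit the 1.5 s
            # analysis window; at fast heart rates no such beat may exist,
            # so fall back to the widest-gap placement in the scan range
            best, best_gap = None, -np.inf
            for cand in range(b0, b0 + max_scan):
                if cand + offsets[-1] + 1 >= len(r):
                    break
                gaps = r[cand + offsets[1:]] - r[cand + offsets[:-1]]
                g = gaps.min()
                if g >= EPOCH_WINDOW_S + 0.05:
                    b = cand
                    break
                if g > best_gap:
                    best, best_gap = cand, g
            if b is None:
                b = best
        elif b0 + offsets[-1] + 1 < len(r):
            b = b0
        if b is None:
            raise TruncationError(
                f"cardiac series too short: trial {t}/{n_trials}")
        pulse_intervals[t] = b + offsets
        cursor = r[pulse_intervals[t, -1]] + PULSE_LATENCY_S
        if t + 1 < n_trials:
            cursor += iti_seq[t + 1]
    pulse_times = r[pulse_intervals] + PULSE_LATENCY_S
    return StimulusProtocol(variant=variant, pulse_intervals=pulse_intervals,
                            pulse_times=pulse_times, iti_seq=iti_seq)


def protocol_duration(n_trials: int, iti_menu: Sequence[float],
                      heart_rate: float) -> float:
    """Conservative recording length needed to host a protocol."""
    mean_rr = 60.0 / heart_rate
    trial_span = 6 * max(mean_rr, EPOCH_WINDOW_S)
    return n_trials * (max(iti_menu) + trial_span) + 60.0


# ---------------------------------------------------------------------------
# neurogram
# ---------------------------------------------------------------------------

def stimulated_intervals(protocol: StimulusProtocol,
                         pulses: Iterable[int] | None = None) -> np.ndarray:
    """Cardiac-interval indices hosting the inhibition effect.

    ``pulses`` selects which pulses of each trial carry it (1-based);
    default all pulses of the trial.
    """
    if pulses is None:
        cols = slice(None)
    else:
        cols = [p - 1 for p in pulses]
    return np.unique(protocol.pulse_intervals[:, cols])


def gen_burst_amplitudes(cardiac: CardiacSeries, inhibition: float,
                         protocol: StimulusProtocol | None, spec: CohortSpec,
                         rng: np.random.Generator,
                         amplitude_floor: float = 0.05) -> np.ndarray:
    """Per-cardiac-interval burst amplitudes (0 = absent burst).

    Baseline bursts occur with probability burst_incidence/100 and carry
    log-normal amplitudes with mean 1 and the spec's CV.  In stimulated
    intervals the amplitude expectation is scaled by (1 - inhibition/100);
    a scaled amplitude below ``amplitude_floor`` renders the burst absent,
    so inhibition = 100 means complete post-stimulus burst absence.
    """
    if inhibition > 100:
        raise SpecError("inhibition cannot exceed 100% (complete absence)")
    n = cardiac.n_intervals
    occ = rng.random(n) < spec.burst_incidence / 100.0
    cv = spec.burst_amplitude_cv
    sig2 = np.log1p(cv ** 2)
    amps = np.exp(rng.normal(-0.5 * sig2, np.sqrt(sig2), n))
    amps[~occ] = 0.0
    if protocol is not None:
        idx = stimulated_intervals(protocol, spec.inhibited_pulses)
        idx = idx[idx < n]
        amps[idx] *= (1.0 - inhibition / 100.0)
        low = amps[idx] < amplitude_floor
        amps[idx] = np.where(low, 0.0, amps[idx])
    return amps


def render_neurogram(amplitudes: np.ndarray, cardiac: CardiacSeries,
                     fs: float = 100.0, noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     baseline_offset: float = 0.1) -> NeurogramRecording:
    """Render per-interval amplitudes into an integrated neurogram.

    Bursts are Gaussian humps (FWHM 0.3 s) at 1.3 s after the R-wave of
    their interval, on a constant baseline offset with optional additive
    noise, clipped at zero (the integrated signal is non-negative).
    """
    n_samp = int(round(cardiac.duration * fs))
    sig = np.full(n_samp, baseline_offset)
    sigma = BURST_FWHM_S / 2.3548
    half = int(round(4 * sigma * fs))
    kt = (np.arange(2 * half + 1) - half) / fs
    kernel = np.exp(-0.5 * (kt / sigma) ** 2)
    centers = cardiac.r_times[:-1] + BURST_LATENCY_S
    for amp, c in zip(amplitudes, centers):
        if amp <= 0:
            continue
        i0 = int(round(c * fs)) - half
        lo, hi = max(i0, 0), min(i0 + len(kernel), n_samp)
        if lo >= hi:
            continue
        sig[lo:hi] += amp * kernel[lo - i0:hi - i0]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        sig = sig + rng.normal(0.0, noise_sd, n_samp)
    return NeurogramRecording(samples=np.clip(sig, 0.0, None), fs=fs,
                              r_times=cardiac.r_times)


def gen_neurogram(cardiac: CardiacSeries, inhibition: float,
                  protocol: StimulusProtocol | None, spec: CohortSpec,
                  rng: np.random.Generator) -> NeurogramRecording:
    amps = gen_burst_amplitudes(cardiac, inhibition, protocol, spec, rng)
    return render_neurogram(amps, cardiac, fs=spec.neurogram_fs,
                            noise_sd=spec.neurogram_noise_sd, rng=rng)


# ---------------------------------------------------------------------------
# source-space oscillatory epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float) -> np.ndarray:
    """1/f-amplitude broadband noise, unit-ish variance."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.normal(size=(shape[0], len(freqs)))
            + 1j * rng.normal(size=(shape[0], len(freqs)))) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    return x / x.std()


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-variance noise band-limited to [f_lo, f_hi] Hz."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec = (rng.normal(size=(shape[0], len(freqs)))
            + 1j * rng.normal(size=(shape[0], len(freqs)))) * mask
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std()
    return x / sd if sd > 0 else x


def rebound_gain(inhibition: float | np.ndarray, spec: CohortSpec,
                 rng: np.random.Generator,
                 base: float = 0.8) -> np.ndarray:
    """Subject-level multiplicative beta-rebound gain.

    Monotone in inhibition with strength ``spec.rebound_coupling``: at
    coupling 1 the gain is a deterministic strictly increasing function of
    inhibition; at 0 it is independent of it.
    """
    z = (np.asarray(inhibition, dtype=float) - spec.inhibition_mean) \
        / spec.inhibition_sd
    s = _squash(z)
    rc = spec.rebound_coupling
    eps = rng.normal(size=np.shape(s)) if rc < 1.0 else np.zeros(np.shape(s))
    mix = rc * s + np.sqrt(max(0.0, 1.0 - rc ** 2)) * eps
    return base * np.exp(0.35 * mix)


# per-ROI rebound amplitude factor for pulses 1..3 (None = uncoupled constant)
_ROI_PULSE_REBOUND = {
    # racc responds (rebound-like synchronization) only after the expected
    # pulses 2 and 3; pulse 1 carries no coupled response
    "racc": {"pulse1": 0.0, "pulse2": 1.0, "pulse3": 1.0},
    # insula responds to all pulses but its power is uncoupled to inhibition
    "insula": {"pulse1": 0.5, "pulse2": 1.0, "pulse3": 1.0},
    # rolandic: classic somatosensory ERD/rebound after every pulse, weak
    # after the unexpected first one
    "rolandic": {"pulse1": 0.4, "pulse2": 1.0, "pulse3": 1.0},
}
_UNCOUPLED_ROIS = ("insula",)


def gen_source_epochs(inhibition: float, protocol: StimulusProtocol,
                      spec: CohortSpec, seed: int,
                      roi: str = "rolandic",
                      gain: float | None = None) -> SourceEpochSet:
    """ROI source epochs: 1/f background + beta (13-25 Hz) with early
    (0-0.4 s) desynchronization and a (0.5-1.2 s) rebound whose amplitude
    is coupled to subject inhibition through :func:`rebound_gain`.

    ``gain`` overrides the subject gain (used by gen_cohort so the stored
    ground truth matches the generated epochs exactly).
    """
    rng = _rng(seed, _STAGE["source"], ROI_LABELS.index(roi))
    fs = spec.source_fs
    n = int(round(EPOCH_WINDOW_S * fs))
    t = np.arange(n) / fs
    n_trials = protocol.n_trials

    if gain is None:
        g_spec = spec if roi not in _UNCOUPLED_ROIS else \
            CohortSpec(**{**spec.__dict__, "rebound_coupling": 0.0})
        gain = float(rebound_gain(inhibition, g_spec,
                                  _rng(seed, _STAGE["source"], 7)))

    desync = 0.6 / (1 + np.exp(-(t - 0.05) / 0.02)) \
        / (1 + np.exp((t - 0.40) / 0.03))
    bump = np.exp(-0.5 * ((t - 0.85) / 0.18) ** 2)

    epochs = {}
    for cond in CONDITIONS:
        pink = _pink_noise(rng, (n_trials, n), fs)
        beta = _band_noise(rng, (n_trials, n), fs, 13.0, 25.0)
        if cond == "baseline":
            env = np.ones(n)
            amp = np.zeros(n_trials)
        else:
            factor = _ROI_PULSE_REBOUND[roi][cond]
            amp = gain * factor * np.exp(rng.normal(0.0, 0.2, n_trials))
            env = 1.0 - desync
        x = pink + (env[None, :] + amp[:, None] * bump[None, :]
                    * (0.0 if cond == "baseline" else 1.0)) * beta
        epochs[cond] = x
    return SourceEpochSet(epochs=epochs, fs=fs, roi=roi)


def make_toy_leadfield(n_channels: int = 24, points_per_roi: int = 8,
                       seed: int = 0) -> LeadfieldModel:
    """Random smooth fixed-orientation leadfields on a 5 mm lattice per ROI."""
    rng = _rng(seed, _STAGE["sensors"])
    pts, lf, labels = [], [], []
    for r, roi in enumerate(ROI_LABELS):
        base = np.array([40.0 * r, 0.0, 0.0])
        for p in range(points_per_roi):
            pts.append(base + 5.0 * np.array([p % 2, (p // 2) % 2, p // 4]))
            v = rng.normal(size=n_channels)
            lf.append(v / np.linalg.norm(v))
            labels.append(roi)
    return LeadfieldModel(grid_points=np.array(pts),
                          leadfield=np.array(lf),
                          roi_label=np.array(labels))


def gen_sensor_epochs(source: Mapping[str, SourceEpochSet],
                      leadfields: LeadfieldModel, snr: float = 1.0,
                      active_points: Mapping[str, int] | None = None,
                      seed: int = 0) -> dict:
    """Project ROI source series through one active grid point per ROI.

    Returns condition -> (n_trials, n_channels, n_samples) arrays with
    white sensor noise at the requested SNR (signal/noise variance ratio);
    ``snr=np.inf`` gives noiseless projections.
    """
    rng = _rng(seed, _STAGE["sensors"], 1)
    if active_points is None:
        active_points = {}
        for roi in source:
            idx = np.flatnonzero(leadfields.roi_label == roi)
            if len(idx) == 0:
                raise ValueError(f"leadfield has no points for ROI {roi!r}")
            active_points[roi] = int(idx[len(idx) // 2])
    out = {}
    rois = list(source)
    any_set = source[rois[0]]
    for cond in CONDITIONS:
        n_trials, n_samp = any_set.epochs[cond].shape
        y = np.zeros((n_trials, leadfields.n_channels, n_samp))
        for roi in rois:
            l = leadfields.leadfield[active_points[roi]]
            if l.ndim != 1:
                raise ValueError("sensor projection expects fixed-orientation "
                                 "leadfields (channels vector per point)")
            y += l[None, :, None] * source[roi].epochs[cond][:, None, :]
        if np.isfinite(snr):
            sig_var = y.var()
            noise_sd = np.sqrt(sig_var / snr) if sig_var > 0 else 1.0
            y = y + rng.normal(0.0, noise_sd, y.shape)
        out[cond] = y
    return out, dict(active_points)


# ---------------------------------------------------------------------------
# blood pressure and thickness
# ---------------------------------------------------------------------------

BEAT_RANGE = np.arange(-8, 16)  # beat 1 = first stimulated cardiac cycle
BP_MEASURES = ("map", "sbp", "dbp", "hr", "pulse_pressure")


def gen_bp_series(groups: Sequence[str], spec: CohortSpec, seed: int,
                  n_trials: int | None = None):
    """Beat-aligned BP/HR table, long format.

    Non-inhibitors carry a MAP rise peaking at post-stimulus beat 6 with
    subject-mean ``spec.bp_rise_nonin`` mmHg (driven by diastolic pressure);
    Inhibitors stay flat.  HR and pulse pressure carry no group effect.
    """
    import pandas as pd

    rng = _rng(seed, _STAGE["bp"])
    if n_trials is None:
        n_trials = spec.n_trials
    rows = []
    beat_profile = np.where(BEAT_RANGE >= 1,
                            np.exp(-0.5 * ((BEAT_RANGE - 6) / 2.0) ** 2), 0.0)
    for s, grp in enumerate(groups):
        rise = spec.bp_rise_nonin if grp == "Non-inhibitor" else 0.0
        rise = rise + rng.normal(0.0, spec.bp_subject_sd)
        dbp0 = rng.normal(64.7, 7.8)
        sbp0 = dbp0 + rng.normal(53.0, 6.0)
        hr0 = rng.normal(spec.heart_rate_mean, spec.heart_rate_sd)
        nb = len(BEAT_RANGE)
        bump = rise * beat_profile
        dbp = dbp0 + 0.9 * bump + rng.normal(0, spec.bp_beat_noise_sd,
                                             (n_trials, nb))
        sbp = sbp0 + 1.1 * bump + rng.normal(0, 1.5 * spec.bp_beat_noise_sd,
                                             (n_trials, nb))
        hr = hr0 + rng.normal(0, 1.5, (n_trials, nb))
        mapv = dbp + (sbp - dbp) / 3.0
        pp = sbp - dbp
        for tr in range(n_trials):
            for b, beat in enumerate(BEAT_RANGE):
                rows.append((s, grp, tr, int(beat), mapv[tr, b], sbp[tr, b],
                             dbp[tr, b], hr[tr, b], pp[tr, b]))
    return pd.DataFrame(rows, columns=["subject", "group", "trial", "beat",
                                       *BP_MEASURES])


THICKNESS_COLUMNS = ("rACC_left", "rACC_right", "insula_left",
                     "insula_right", "rolandic")
_THICKNESS_BASE = {"rACC_left": 2.75, "rACC_right": 2.75,
                   "insula_left": 3.0, "insula_right": 3.0, "rolandic": 2.5}
_THICKNESS_SCALE = 0.28  # mm per squashed z-unit of inhibition


def gen_thickness(inhibition: np.ndarray, spec: CohortSpec, seed: int,
                  return_effect: bool = False):
    """Per-subject ROI cortical-thickness table (mm).

    rACC thickness = base - thickness_coupling * squash(z(inhibition)) *
    scale + noise (so positive coupling yields the negative
    thickness-inhibition correlation); other ROIs are uncoupled.  Values
    clipped to the plausible 1.5-4.5 mm range.  ``return_effect`` also
    returns the noise-free structural signal (the measurement-noise-free
    rACC deviation) for ground-truth bookkeeping.
    """
    import pandas as pd

    rng = _rng(seed, _STAGE["thickness"])
    inh = np.asarray(inhibition, dtype=float)
    n = len(inh)
    s = _squash((inh - spec.inhibition_mean) / spec.inhibition_sd)
    tc = spec.thickness_coupling
    eps = rng.normal(size=n)
    effect = tc * s + np.sqrt(max(0.0, 1.0 - tc ** 2)) \
        * eps * spec.thickness_noise_sd / _THICKNESS_SCALE
    data = {"subject": np.arange(n)}
    for col in THICKNESS_COLUMNS:
        base = _THICKNESS_BASE[col]
        if col.startswith("rACC"):
            val = base - _THICKNESS_SCALE * effect \
                + rng.normal(0, spec.thickness_noise_sd, n)
        else:
            val = base + rng.normal(0, 2 * spec.thickness_noise_sd, n)
        data[col] = np.clip(val, 1.5, 4.5)
    table = pd.DataFrame(data)
    if return_effect:
        return table, -_THICKNESS_SCALE * effect
    return table


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def draw_inhibition(spec: CohortSpec) -> np.ndarray:
    """Per-subject ground-truth inhibition (%), Normal(mean, sd) truncated
    at the +100% hard bound, with the optional outlier replacing the last
    subject."""
    rng = _rng(spec.seed, _STAGE["inhibition"])
    inh = rng.normal(spec.inhibition_mean, spec.inhibition_sd,
                     spec.n_subjects)
    inh = np.minimum(inh, 100.0)
    if spec.outlier_inhibition is not None:
        inh[-1] = spec.outlier_inhibition
    return inh


def gen_cohort(spec: CohortSpec,
               stages: Iterable[str] = ("neurogram", "source", "bp",
                                        "thickness")) -> Cohort:
    """Generate a full cohort bundle; deterministic under spec.seed.

    ``stages`` restricts the expensive pieces; cardiac series and
    protocols are always generated.
    """
    from scipy.stats import spearmanr

    from .msna import classify

    stages = set(stages)
    inh = draw_inhibition(spec)
    groups = np.array([classify(v) for v in inh])

    # shared rebound gains per coupled ROI so ground truth matches epochs
    gain_rng = {roi: _rng(spec.seed, _STAGE["source"], 100 + i)
                for i, roi in enumerate(ROI_LABELS)}
    gains = {}
    for roi in ROI_LABELS:
        rspec = spec if roi not in _UNCOUPLED_ROIS else \
            CohortSpec(**{**spec.__dict__, "rebound_coupling": 0.0})
        gains[roi] = rebound_gain(inh, rspec, gain_rng[roi])

    subjects = []
    for s in range(spec.n_subjects):
        srng = _rng(spec.seed, s, _STAGE["cardiac"])
        hr = float(np.clip(srng.normal(spec.heart_rate_mean,
                                       spec.heart_rate_sd), 42.0, 95.0))
        dur = protocol_duration(spec.n_trials, spec.iti_menu, hr)
        cardiac = gen_cardiac(hr, dur, srng)
        prot_meg = gen_protocol(cardiac, "meg", spec.n_trials,
                                spec.iti_menu, seed=spec.seed)
        prot_micro = gen_protocol(cardiac, "microneurography", spec.n_trials,
                                  spec.iti_menu, seed=spec.seed)
        neuro = None
        if "neurogram" in stages:
            nrng = _rng(spec.seed, s, _STAGE["neurogram"])
            neuro = gen_neurogram(cardiac, inh[s], prot_micro, spec, nrng)
        src = None
        if "source" in stages:
            src = {roi: gen_source_epochs(inh[s], prot_meg, spec,
                                          seed=(spec.seed * 1009 + s) & 0x7FFFFFFF,
                                          roi=roi, gain=float(gains[roi][s]))
                   for roi in ROI_LABELS}
        subjects.append(SubjectData(subject=s, inhibition=float(inh[s]),
                                    group=str(groups[s]), cardiac=cardiac,
                                    protocol_meg=prot_meg,
                                    protocol_micro=prot_micro,
                                    neurogram=neuro, source_epochs=src))

    bp = gen_bp_series(groups, spec, seed=spec.seed) if "bp" in stages else None
    thick = thick_effect = None
    if "thickness" in stages:
        thick, thick_effect = gen_thickness(inh, spec, seed=spec.seed,
                                            return_effect=True)

    realized = {}
    for roi in ROI_LABELS:
        r = spearmanr(gains[roi], inh).statistic if spec.n_subjects > 2 else np.nan
        realized[f"rebound_{roi}"] = float(r)
    if thick_effect is not None:
        realized["thickness_racc"] = float(
            spearmanr(thick_effect, inh).statistic)

    gt = GroundTruth(inhibition=inh, group=groups, rebound_gain=gains,
                     realized_spearman=realized)
    return Cohort(spec=spec, subjects=subjects, bp_beats=bp,
                  thickness=thick, ground_truth=gt)
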