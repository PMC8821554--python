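"""Time-frequency decomposition and cluster-based permutation correlation.

ROI trial series are decomposed over 5-40 Hz with a 7-cycle
Hanning-tapered sliding window shifted in 5 ms steps (window length at
frequency f is 7/f seconds; edge positions without a full window are
missing values, never silently zero-padded).  Post-pulse power is
normalized to the 1.5 s pre-pulse-1 baseline as relative change
(P - B)/B per frequency.

Across subjects, the per-bin Spearman correlation between relative power
and MSNA inhibition is thresholded (two-sided p < 0.05 via the
t-approximation), supra-threshold bins are clustered by 4-adjacency
separately by sign, and each cluster's mass (sum of bin correlations) is
compared to the permutation null of the maximum absolute cluster mass
obtained by shuffling the inhibition values (1000 permutations; p =
(1 + #{null >= observed}) / (n_perm + 1), so p is never zero).  Power in
significant clusters is averaged per subject and correlated with
inhibition; a generic 13-25 Hz x 0.5-1.2 s window provides the
cluster-free confirmatory correlation, and group beta time courses with
uncorrected t-test marks give visual guidance only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

BETA_BAND = (13.0, 25.0)
GENERIC_WINDOW_S = (0.5, 1.2)


@dataclass(frozen=True)
class TFRConfig:
    f_min: float = 5.0
    f_max: float = 40.0
    f_step: float = 2.5
    n_cycles: float = 7.0
    step_s: float = 0.005

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.f_min, self.f_max + 1e-9, self.f_step)


@dataclass(frozen=True)
class PermConfig:
    n_perm: int = 1000
    alpha: float = 0.05
    cluster_alpha: float = 0.05  # cluster-forming per-bin threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass
class Cluster:
    mask: np.ndarray   # (F, T) bool
    sign: int
    mass: float
    p_value: float
    subject_power: np.ndarray | None = None
    spearman_r: float | None = None
    spearman_p: float | None = None


@dataclass
class ClusterResult:
    r_map: np.ndarray          # per-bin Spearman across subjects
    threshold: float           # |r| cluster-forming threshold
    clusters: list             # all clusters, sorted by |mass| desc
    null_max_mass: np.ndarray  # (n_perm,)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value <= 0.05]


# ---------------------------------------------------------------------------
# spectral decomposition
# ---------------------------------------------------------------------------

def tfr_hanning(data: np.ndarray, fs: float,
                cfg: TFRConfig = TFRConfig(), t_start: float = 0.0):
    """Per-trial power maps from a 7-cycle Hanning sliding window.

    ``data`` is (n_trials, n_samples) or (n_samples,).  Returns
    (power (n_trials, F, n_times), times (s), freqs (Hz)); power at a
    frequency whose full window does not fit a given position is NaN, and
    a frequency whose window exceeds the whole series yields an all-NaN
    row with a warning.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n_trials, n_samp = x.shape
    freqs = cfg.freqs
    step = max(1, int(round(cfg.step_s * fs)))
    t_idx = np.arange(0, n_samp, step)
    times = t_start + t_idx / fs
    power = np.full((n_trials, len(freqs), len(t_idx)), np.nan)
    for fi, f in enumerate(freqs):
        wlen = int(round(cfg.n_cycles / f * fs)) | 1  # odd, centered
        if wlen > n_samp:
            warnings.warn(f"series shorter than the {cfg.n_cycles}-cycle "
                          f"window at {f} Hz; row left missing",
                          stacklevel=2)
            continue
        half = wlen // 2
        k = np.arange(wlen) - half
        taper = np.hanning(wlen)
        kernel = taper * np.exp(2j * np.pi * f * k / fs)
        coef = signal.fftconvolve(x, kernel[None, :], mode="same", axes=1)
        amp = 2.0 * np.abs(coef) / taper.sum()
        p = amp ** 2
        p[:, :half] = np.nan
        if half > 0:
            p[:, -half:] = np.nan
        power[:, fi, :] = p[:, t_idx]
    return power, times, freqs


def hanning_window_length(f: float, n_cycles: float = 7.0) -> float:
    """Sliding-window length (s) at frequency f."""
    return n_cycles / f


def baseline_normalize(power: np.ndarray, baseline_power: np.ndarray
                       ) -> np.ndarray:
    """Relative power change vs the pre-stimulus baseline.

    Trials are averaged first; the baseline mean is taken per frequency
    over its trials and valid times.  Output (F, T): (P - B_f)/B_f, which
    is invariant to any overall scaling of the subject's series.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
        p = np.nanmean(np.asarray(power, dtype=float), axis=0)
        b = np.nanmean(np.asarray(baseline_power, dtype=float), axis=(0, 2))
    if np.any(~np.isfinite(b) | (b <= 0)):
        bad = np.flatnonzero(~np.isfinite(b) | (b <= 0))
        warnings.warn(f"non-positive/undefined baseline power at frequency "
                      f"rows {bad}; rows left missing", stacklevel=2)
        b = b.copy()
        b[bad] = np.nan
    return (p - b[:, None]) / b[:, None]


def subject_tfr_map(post_series: np.ndarray, baseline_series: np.ndarray,
                    fs: float, cfg: TFRConfig = TFRConfig()):
    """Per-trial decomposition of both windows, then trial averaging and
    baseline normalization: one subject's TFRMap for one condition."""
    p_post, times, freqs = tfr_hanning(post_series, fs, cfg)
    p_base, _, _ = tfr_hanning(baseline_series, fs, cfg)
    return baseline_normalize(p_post, p_base), times, freqs


# ---------------------------------------------------------------------------
# cluster-based permutation correlation
# ---------------------------------------------------------------------------

def _rank_standardize(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Ranks along ``axis``, centered and scaled to unit norm, so that a
    dot product of two such vectors is the Spearman correlation."""
    r = stats.rankdata(a, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=axis, keepdims=True))
    norm[norm == 0] = np.nan
    return r / norm


def spearman_threshold(n: int, alpha: float) -> float:
    """|r| above which the Spearman t-approximation gives two-sided
    p < alpha for sample size n."""
    tc = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(tc / np.sqrt(n - 2 + tc ** 2))


def _cluster_masses(r_row: np.ndarray, shape: tuple[int, int],
                    threshold: float):
    """Clusters of supra-threshold bins, 4-adjacency, split by sign.

    Returns (labels_list, masses): per cluster a (mask, sign, mass).
    """
    grid = r_row.reshape(shape)
    out = []
    for sign in (1, -1):
        mask = (sign * grid) >= threshold
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)  # default: 4-neighborhood
        sums = ndimage.sum_labels(grid, labels, index=np.arange(1, n_lab + 1))
        for li in range(n_lab):
            out.append((labels == li + 1, sign, float(sums[li])))
    return out


def cluster_perm_corr(maps: np.ndarray, inhibition: np.ndarray,
                      pcfg: PermConfig = PermConfig()) -> ClusterResult:
    """Cluster-based permutation test of the per-bin Spearman correlation
    between subject TFR maps (n_subjects, F, T) and inhibition values.

    NaN bins (incomplete spectral windows) never enter clusters.  The
    null distribution is the maximum absolute cluster mass over both
    signs under random permutation of the inhibition values.
    """
    maps = np.asarray(maps, dtype=float)
    inh = np.asarray(inhibition, dtype=float)
    n_subj, n_f, n_t = maps.shape
    if n_subj < 8:
        raise ValueError("need >= 8 subjects for the permutation test")
    if len(inh) != n_subj:
        raise ValueError("inhibition length mismatch")
    if np.all(inh == inh[0]):
        raise ValueError("constant inhibition vector: ranks undefined")

    flat = maps.reshape(n_subj, -1)
    valid = np.all(np.isfinite(flat), axis=0) & (np.ptp(flat, axis=0) > 0)
    zx = _rank_standardize(inh)
    zm = np.full_like(flat, np.nan)
    if valid.any():
        zm[:, valid] = _rank_standardize(flat[:, valid], axis=0)

    r_obs = np.where(valid, zx @ np.nan_to_num(zm), np.nan)
    threshold = spearman_threshold(n_subj, pcfg.cluster_alpha)

    rng = np.random.default_rng(pcfg.seed)
    perm_z = np.stack([zx[rng.permutation(n_subj)]
                       for _ in range(pcfg.n_perm)])
    r_perm = perm_z @ np.nan_to_num(zm)          # (n_perm, bins)
    r_perm[:, ~valid] = 0.0

    null_max = np.zeros(pcfg.n_perm)
    for i in range(pcfg.n_perm):
        clusters = _cluster_masses(r_perm[i], (n_f, n_t), threshold)
        if clusters:
            null_max[i] = max(abs(m) for _, _, m in clusters)

    obs_clusters = _cluster_masses(np.where(valid, np.nan_to_num(r_obs), 0.0)
                                   .reshape(-1), (n_f, n_t), threshold)
    results = []
    for mask, sign, mass in obs_clusters:
        p = (1.0 + np.count_nonzero(null_max >= abs(mass))) \
            / (pcfg.n_perm + 1.0)
        c = Cluster(mask=mask, sign=sign, mass=mass, p_value=float(p))
        cl_power = np.nanmean(maps[:, mask], axis=1)
        c.subject_power = cl_power
        sr = stats.spearmanr(cl_power, inh)
        c.spearman_r = float(sr.statistic)
        c.spearman_p = float(sr.pvalue)
        results.append(c)
    results.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(r_map=r_obs.reshape(n_f, n_t), threshold=threshold,
                         clusters=results, null_max_mass=null_max)


def generic_window_corr(maps: np.ndarray, times: np.ndarray,
                        freqs: np.ndarray, inhibition: np.ndarray,
                        band: tuple[float, float] = BETA_BAND,
                        window: tuple[float, float] = GENERIC_WINDOW_S
                        ) -> tuple[float, float]:
    """Spearman correlation between inhibition and mean relative power in
    a fixed time-frequency window (clipped to map bounds)."""
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    tmask = (times >= window[0]) & (times <= window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("window does not intersect the map grid")
    sub = np.asarray(maps)[:, fmask][:, :, tmask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_subject = np.nanmean(sub, axis=(1, 2))
    res = stats.spearmanr(per_subject, np.asarray(inhibition, dtype=float))
    return float(res.statistic), float(res.pvalue)


def group_beta_timecourse(maps: np.ndarray, times: np.ndarray,
                          freqs: np.ndarray, groups,
                          band: tuple[float, float] = BETA_BAND) -> dict:
    """Beta-band power over time per group with SEM and uncorrected
    bin-wise two-tailed t-test marks (visual guidance only)."""
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmean(np.asarray(maps)[:, fmask, :], axis=1)  # (S, T)
    groups = np.asarray(groups)
    out = {"times": times, "groups": {}}
    arrays = {}
    for g in np.unique(groups):
        x = beta[groups == g]
        arrays[g] = x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
            out["groups"][str(g)] = {
                "mean": np.nanmean(x, axis=0),
                "sem": np.nanstd(x, axis=0, ddof=1) / np.sqrt(x.shape[0]),
                "n": int(x.shape[0]),
            }
    if len(arrays) == 2:
        a, b = arrays.values()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tt = stats.ttest_ind(a, b, axis=0, nan_policy="omit")
        pv = np.asarray(tt.pvalue, dtype=float)
        out["t_p"] = pv
        out["marks_05"] = pv < 0.05
        out["marks_01"] = pv < 0.01
        out["note"] = "uncorrected t-tests; visual guidance only"
    return out


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_fwer(n_cohorts: int = 200, n_subjects: int = 20,
              grid: tuple[int, int] = (10, 50), n_perm: int = 1000,
              alpha: float = 0.05, seed: int = 0) -> float:
    """Family-wise false-positive rate of the cluster permutation test on
    white-noise maps independent of inhibition (one fraction in [0, 1])."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_cohorts):
        maps = rng.normal(size=(n_subjects, *grid))
        inh = rng.normal(size=n_subjects)
        res = cluster_perm_corr(maps, inh,
                                PermConfig(n_perm=n_perm, alpha=alpha,
                                           seed=int(rng.integers(2 ** 31))))
        if any(c.p_value <= alpha for c in res.clusters):
            hits += 1
    return hits / n_cohorts
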