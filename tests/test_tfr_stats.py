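"""Hanning TFR scaling, baseline normalization invariances, cluster
permutation validity and the generic beta-window correlation."""

import numpy as np
import pytest
from scipy import stats

from msna_cortex.tfr_stats import (BETA_BAND, Cluster, PermConfig, TFRConfig,
                                   baseline_normalize, cluster_perm_corr,
                                   generic_window_corr,
                                   group_beta_timecourse,
                                   hanning_window_length, spearman_threshold,
                                   subject_tfr_map, tfr_hanning)

FS = 200.0


def sinusoid(f, a=1.0, dur=2.0, fs=FS, n_trials=1):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(a * np.sin(2 * np.pi * f * t), (n_trials, 1))


# ---------------------------------------------------------------------------
# spectral estimates
# ---------------------------------------------------------------------------

def test_pure_tone_peaks_at_its_frequency():
    p, times, freqs = tfr_hanning(sinusoid(20.0), FS)
    interior = np.all(np.isfinite(p[0]), axis=0)
    assert interior.any()
    peak_freqs = freqs[np.argmax(p[0][:, interior], axis=0)]
    assert np.all(peak_freqs == 20.0)


def test_window_length_is_seven_cycles():
    assert hanning_window_length(10.0) == pytest.approx(0.7)
    assert hanning_window_length(5.0) == pytest.approx(1.4)
    # the 5 Hz window (1.4 s) fits a 1.5 s epoch; edges are NaN, not zero
    p, _, freqs = tfr_hanning(np.ones(int(1.5 * FS)), FS)
    row = p[0][freqs == 5.0][0]
    assert np.isnan(row[0]) and np.isnan(row[-1])
    assert np.isfinite(row[len(row) // 2])


def test_too_short_series_leaves_row_missing_with_warning():
    with pytest.warns(UserWarning, match="cycle"):
        p, _, freqs = tfr_hanning(np.ones(int(1.0 * FS)), FS)
    assert np.all(np.isnan(p[0][freqs == 5.0]))
    assert np.isfinite(p[0][freqs == 20.0]).any()


def test_power_scales_with_amplitude_squared():
    p1, _, freqs = tfr_hanning(sinusoid(20.0, a=1.0), FS)
    p2, _, _ = tfr_hanning(sinusoid(20.0, a=2.0), FS)
    fi = np.flatnonzero(freqs == 20.0)[0]
    mid = p1.shape[2] // 2
    assert p2[0, fi, mid] / p1[0, fi, mid] == pytest.approx(4.0, rel=1e-6)


def test_white_noise_power_tracks_variance_across_seeds():
    """Summed spectral power is proportional to signal variance with a
    stable taper-loss factor (Parseval-style bound)."""
    ratios = []
    for seed in (0, 1, 2):
        x = np.random.default_rng(seed).normal(0, 1.5, (20, 800))
        p, _, _ = tfr_hanning(x, FS)
        interior = np.all(np.isfinite(p), axis=(0, 1))
        ratios.append(np.mean(p[:, :, interior].sum(axis=1)) / x.var())
    assert np.std(ratios) / np.mean(ratios) < 0.05


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------

def test_baseline_normalization_fixed_points():
    base = np.full((5, 3, 10), 2.0)
    assert np.allclose(baseline_normalize(base, base), 0.0)
    assert np.allclose(baseline_normalize(2.0 * base, base), 1.0)


def test_relative_power_invariant_to_series_scaling():
    rng = np.random.default_rng(0)
    post = rng.normal(size=(10, 300))
    base = rng.normal(size=(10, 300))
    m1, _, _ = subject_tfr_map(post, base, FS)
    m2, _, _ = subject_tfr_map(3.7 * post, 3.7 * base, FS)
    np.testing.assert_allclose(m1, m2, rtol=1e-9)


# ---------------------------------------------------------------------------
# cluster permutation correlation
# ---------------------------------------------------------------------------

def test_identical_maps_produce_no_clusters():
    maps = np.tile(np.random.default_rng(1).normal(size=(1, 6, 20)),
                   (10, 1, 1))
    inh = np.arange(10, dtype=float)
    res = cluster_perm_corr(maps, inh, PermConfig(n_perm=200, seed=0))
    assert res.clusters == []


def test_constant_inhibition_rejected():
    maps = np.random.default_rng(2).normal(size=(10, 6, 20))
    with pytest.raises(ValueError, match="constant inhibition"):
        cluster_perm_corr(maps, np.full(10, 5.0),
                          PermConfig(n_perm=200, seed=0))
    with pytest.raises(ValueError, match=">= 8 subjects"):
        cluster_perm_corr(maps[:5], np.arange(5.0),
                          PermConfig(n_perm=200, seed=0))


def test_injected_block_detected_with_high_overlap():
    """A monotone coupling confined to a time-frequency block is found as
    a significant cluster covering >= 80% of the block."""
    rng = np.random.default_rng(3)
    n_subj, F, T = 20, 10, 50
    inh = rng.normal(30, 25, n_subj)
    maps = rng.normal(0, 0.3, (n_subj, F, T))
    block = np.zeros((F, T), dtype=bool)
    block[3:7, 20:40] = True
    effect = (inh - inh.mean()) / inh.std()
    maps[:, block] += 2.0 * effect[:, None]
    res = cluster_perm_corr(maps, inh, PermConfig(n_perm=500, seed=4))
    sig = res.significant
    assert sig
    top = max(sig, key=lambda c: abs(c.mass))
    assert top.p_value <= 0.05
    overlap = (top.mask & block).sum() / block.sum()
    assert overlap >= 0.8
    assert top.spearman_r > 0.9


def test_pvalues_bounded_away_from_zero():
    res = cluster_perm_corr(
        np.random.default_rng(5).normal(size=(12, 6, 30)),
        np.arange(12, dtype=float), PermConfig(n_perm=200, seed=6))
    for c in res.clusters:
        assert 1.0 / 201.0 <= c.p_value <= 1.0


def test_cluster_stat_rank_invariances():
    """The per-bin statistic is a rank correlation: invariant to strictly
    monotone transforms of the covariate and to offsets/scalings shared by
    all subjects."""
    rng = np.random.default_rng(7)
    maps = rng.normal(size=(12, 6, 30))
    inh = rng.normal(size=12)
    r1 = cluster_perm_corr(maps, inh, PermConfig(n_perm=100, seed=8)).r_map
    r2 = cluster_perm_corr(maps, np.exp(inh) + 3.0,
                           PermConfig(n_perm=100, seed=8)).r_map
    np.testing.assert_allclose(r1, r2, atol=1e-12)
    r3 = cluster_perm_corr(2.5 * maps - 7.0, inh,
                           PermConfig(n_perm=100, seed=8)).r_map
    np.testing.assert_allclose(r1, r3, atol=1e-12)


def test_nan_bins_never_enter_clusters():
    rng = np.random.default_rng(9)
    maps = rng.normal(size=(10, 6, 20))
    inh = np.arange(10, dtype=float)
    maps[:, :, :3] = np.nan
    maps[:, 2:4, 5:15] += 3.0 * (inh - inh.mean())[:, None, None] / inh.std()
    res = cluster_perm_corr(maps, inh, PermConfig(n_perm=200, seed=10))
    assert np.all(np.isnan(res.r_map[:, :3]))
    for c in res.clusters:
        assert not c.mask[:, :3].any()


def test_spearman_threshold_matches_t_quantile():
    n = 20
    thr = spearman_threshold(n, 0.05)
    t = thr * np.sqrt((n - 2) / (1 - thr ** 2))
    assert 2 * stats.t.sf(t, n - 2) == pytest.approx(0.05, abs=1e-10)


# ---------------------------------------------------------------------------
# generic window and group time courses
# ---------------------------------------------------------------------------

def _maps_with_window_effect(effect, n_subj=20, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    freqs = np.arange(5.0, 41.0, 2.5)
    times = np.arange(0, 1.5, 0.005)
    maps = rng.normal(0, noise or 1e-12, (n_subj, len(freqs), len(times)))
    fmask = (freqs >= 13) & (freqs <= 25)
    tmask = (times >= 0.5) & (times <= 1.2)
    maps[np.ix_(np.arange(n_subj), np.flatnonzero(fmask),
                np.flatnonzero(tmask))] += effect[:, None, None]
    return maps, times, freqs


def test_generic_window_perfect_monotone_coupling():
    inh = np.linspace(-50, 90, 20)
    maps, times, freqs = _maps_with_window_effect(np.exp(inh / 50.0))
    r, _ = generic_window_corr(maps, times, freqs, inh)
    assert r == pytest.approx(1.0)


def test_generic_window_matches_brute_force_rank_formula():
    rng = np.random.default_rng(11)
    inh = rng.permutation(20).astype(float)  # tie-free
    effect = rng.normal(size=20)
    maps, times, freqs = _maps_with_window_effect(effect)
    r, _ = generic_window_corr(maps, times, freqs, inh)
    rx = stats.rankdata(inh)
    ry = stats.rankdata(effect)
    d2 = np.sum((rx - ry) ** 2)
    n = 20
    assert r == pytest.approx(1 - 6 * d2 / (n * (n ** 2 - 1)))


def test_generic_window_clips_or_errors_on_bad_bounds():
    inh = np.linspace(0, 1, 20)
    maps, times, freqs = _maps_with_window_effect(inh)
    r_clip, _ = generic_window_corr(maps, times, freqs, inh,
                                    window=(0.5, 9.0))
    assert np.isfinite(r_clip)
    with pytest.raises(ValueError, match="window"):
        generic_window_corr(maps, times, freqs, inh, window=(5.0, 9.0))


def test_group_timecourse_sem_and_marks():
    rng = np.random.default_rng(12)
    freqs = np.arange(5.0, 41.0, 2.5)
    times = np.arange(0, 1.5, 0.005)
    maps = rng.normal(0, 1.0, (20, len(freqs), len(times)))
    groups = np.array(["Inhibitor"] * 10 + ["Non-inhibitor"] * 10)
    # group difference confined to the rebound window in the beta rows
    fmask = (freqs >= 13) & (freqs <= 25)
    tmask = (times >= 0.5) & (times <= 1.2)
    maps[np.ix_(np.arange(10), np.flatnonzero(fmask),
                np.flatnonzero(tmask))] += 3.0
    tc = group_beta_timecourse(maps, times, freqs, groups)
    g = tc["groups"]["Inhibitor"]
    beta = np.nanmean(maps[:10][:, fmask, :], axis=1)
    np.testing.assert_allclose(
        g["sem"], beta.std(axis=0, ddof=1) / np.sqrt(10), rtol=1e-9)
    marks = tc["marks_05"]
    inside = tmask
    assert marks[inside].mean() > 0.9
    assert marks[~inside].mean() < 0.2
    assert "visual guidance" in tc["note"]


def test_equal_groups_mark_rate_near_alpha():
    rng = np.random.default_rng(13)
    freqs = np.arange(5.0, 41.0, 2.5)
    times = np.arange(0, 1.5, 0.01)
    maps = rng.normal(size=(20, len(freqs), len(times)))
    groups = np.array(["A"] * 10 + ["B"] * 10)
    tc = group_beta_timecourse(maps, times, freqs, groups)
    assert tc["marks_05"].mean() < 0.05 + 2 * np.sqrt(
        0.05 * 0.95 / len(times))
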