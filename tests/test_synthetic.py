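"""Generator-level checks: determinism, protocol geometry, and that every
injected ground-truth coupling is actually present in the generated data."""

import numpy as np
import pytest
from scipy import stats

from msna_cortex.synthetic import (CohortSpec, SpecError, draw_inhibition,
                                   gen_bp_series, gen_burst_amplitudes,
                                   gen_cardiac, gen_cohort, gen_protocol,
                                   gen_sensor_epochs, gen_source_epochs,
                                   gen_thickness, make_toy_leadfield,
                                   protocol_duration, rebound_gain,
                                   stimulated_intervals)
from msna_cortex.msna import classify


def test_same_seed_gives_identical_cohorts(small_spec):
    a = gen_cohort(small_spec)
    b = gen_cohort(small_spec)
    np.testing.assert_array_equal(a.ground_truth.inhibition,
                                  b.ground_truth.inhibition)
    np.testing.assert_array_equal(a.subjects[0].neurogram.samples,
                                  b.subjects[0].neurogram.samples)
    np.testing.assert_array_equal(
        a.subjects[1].source_epochs["racc"].epochs["pulse2"],
        b.subjects[1].source_epochs["racc"].epochs["pulse2"])
    assert a.bp_beats.equals(b.bp_beats)
    assert a.thickness.equals(b.thickness)


def test_invalid_specs_rejected():
    with pytest.raises(SpecError):
        CohortSpec(n_subjects=1)
    with pytest.raises(SpecError):
        CohortSpec(inhibition_sd=0.0)
    with pytest.raises(SpecError):
        CohortSpec(burst_incidence=120.0)
    with pytest.raises(SpecError):
        CohortSpec(rebound_coupling=1.5)


def test_outlier_subject_injected_exactly_once():
    spec = CohortSpec(n_subjects=20, seed=3, outlier_inhibition=-132.0)
    inh = draw_inhibition(spec)
    assert len(inh) == 20
    assert np.count_nonzero(inh == -132.0) == 1


def test_inhibitor_fraction_matches_normal_tail():
    spec = CohortSpec(n_subjects=1000, seed=5, inhibition_mean=40.0,
                      inhibition_sd=20.0)
    inh = draw_inhibition(spec)
    frac = np.mean(inh > 30.0)
    expected = 1.0 - stats.norm.cdf(30.0, 40.0, 20.0)
    se = np.sqrt(expected * (1 - expected) / 1000)
    assert abs(frac - expected) < 3 * se


def test_ground_truth_groups_match_classifier(small_spec):
    cohort = gen_cohort(small_spec, stages=())
    for inh, grp in zip(cohort.ground_truth.inhibition,
                        cohort.ground_truth.group):
        assert classify(inh) == grp


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def test_meg_protocol_geometry(study_protocol_pair):
    card, meg, _ = study_protocol_pair
    assert meg.pulse_intervals.shape == (72, 3)
    # every pulse exactly 200 ms after its R-wave
    np.testing.assert_allclose(
        meg.pulse_times - card.r_times[meg.pulse_intervals], 0.200,
        atol=1e-12)
    # pulses on alternating heartbeats, none sharing an interval
    assert np.all(np.diff(meg.pulse_intervals, axis=1) == 2)
    for row in meg.pulse_intervals:
        assert len(set(row)) == 3
    # 1.5 s post-pulse windows never overlap the next pulse of the trial
    gaps = meg.pulse_times[:, 1:] - meg.pulse_times[:, :-1]
    assert gaps.min() >= 1.5


def test_micro_protocol_uses_consecutive_intervals(study_protocol_pair):
    _, _, micro = study_protocol_pair
    assert micro.pulse_intervals.shape == (72, 5)
    assert np.all(np.diff(micro.pulse_intervals, axis=1) == 1)


def test_iti_menu_respected_and_shared_across_subjects():
    rng = np.random.default_rng(0)
    menu = (30.0, 45.0, 60.0)
    cards = [gen_cardiac(hr, protocol_duration(10, menu, hr), rng)
             for hr in (50.0, 65.0)]
    prots = [gen_protocol(c, "meg", 10, menu, seed=4) for c in cards]
    assert set(prots[0].iti_seq) <= set(menu)
    np.testing.assert_array_equal(prots[0].iti_seq, prots[1].iti_seq)

    single = gen_protocol(cards[0], "meg", 10, (30.0,), seed=4)
    assert np.all(single.iti_seq == 30.0)


# ---------------------------------------------------------------------------
# neurogram amplitudes
# ---------------------------------------------------------------------------

def test_complete_inhibition_silences_post_stimulus_bursts(
        study_protocol_pair):
    card, _, micro = study_protocol_pair
    spec = CohortSpec(n_subjects=2, seed=0)
    amps = gen_burst_amplitudes(card, 100.0, micro, spec,
                                np.random.default_rng(1))
    assert np.all(amps[stimulated_intervals(micro)] == 0.0)
    assert np.all(amps >= 0.0)


def test_zero_inhibition_leaves_post_distribution_at_baseline(
        study_protocol_pair):
    card, _, micro = study_protocol_pair
    spec = CohortSpec(n_subjects=2, seed=0)
    amps = gen_burst_amplitudes(card, 0.0, micro, spec,
                                np.random.default_rng(2))
    post = stimulated_intervals(micro)
    base = np.setdiff1d(np.arange(len(amps)), post)
    ks = stats.ks_2samp(amps[post], amps[base])
    assert ks.pvalue > 0.01


def test_negative_200_triples_post_stimulus_mean(study_protocol_pair):
    card, _, micro = study_protocol_pair
    spec = CohortSpec(n_subjects=2, seed=0)
    amps = gen_burst_amplitudes(card, -200.0, micro, spec,
                                np.random.default_rng(3))
    post = stimulated_intervals(micro)
    base = np.setdiff1d(np.arange(len(amps)), post)
    ratio = amps[post].mean() / amps[base].mean()
    # post mean amplitude ~ 3x baseline (bursts 2x *higher* than baseline)
    se = 3.0 * np.sqrt(amps[post].var() / amps[post].size
                       / amps[post].mean() ** 2
                       + amps[base].var() / amps[base].size
                       / amps[base].mean() ** 2)
    assert abs(ratio - 3.0) < 3 * 3.0 * se + 0.3


def test_inhibition_above_100_rejected(study_protocol_pair):
    card, _, micro = study_protocol_pair
    spec = CohortSpec(n_subjects=2, seed=0)
    with pytest.raises(SpecError):
        gen_burst_amplitudes(card, 120.0, micro, spec,
                             np.random.default_rng(0))


# ---------------------------------------------------------------------------
# source epochs and sensors
# ---------------------------------------------------------------------------

def _window_power(epochs, fs, lo, hi):
    sl = slice(int(lo * fs), int(hi * fs))
    return float(np.mean(epochs[:, sl] ** 2))


def test_rebound_gain_coupling_extremes():
    spec1 = CohortSpec(n_subjects=20, seed=0, rebound_coupling=1.0)
    inh = draw_inhibition(spec1)
    g1 = rebound_gain(inh, spec1, np.random.default_rng(0))
    assert stats.spearmanr(g1, inh).statistic == pytest.approx(1.0)

    spec0 = CohortSpec(n_subjects=20, seed=0, rebound_coupling=0.0)
    g0 = rebound_gain(inh, spec0, np.random.default_rng(1))
    assert abs(stats.spearmanr(g0, inh).statistic) < 0.45


def test_rebound_window_exceeds_desync_window_for_inhibitors(small_spec):
    cohort = gen_cohort(small_spec, stages=("source",))
    fs = small_spec.source_fs
    for sub in cohort.subjects:
        ep = sub.source_epochs["rolandic"].epochs["pulse3"]
        assert _window_power(ep, fs, 0.5, 1.2) > _window_power(ep, fs,
                                                               0.05, 0.4)


def test_source_epochs_have_equal_trial_counts(small_spec):
    cohort = gen_cohort(small_spec, stages=("source",))
    es = cohort.subjects[0].source_epochs["racc"]
    counts = {c: e.shape[0] for c, e in es.epochs.items()}
    assert len(set(counts.values())) == 1
    assert es.epochs["baseline"].shape[1] == int(1.5 * small_spec.source_fs)


def test_sensor_projection_covariance_closed_form():
    """Known mixing of independent sources reproduces L diag(P) L^T +
    sigma^2 I within sampling error."""
    rng = np.random.default_rng(8)
    n_ch, n_src, n_samp = 8, 2, 40000
    L = rng.normal(size=(n_ch, n_src))
    P = np.array([2.0, 0.5])
    S = rng.normal(size=(n_src, n_samp)) * np.sqrt(P)[:, None]
    sigma = 0.3
    X = L @ S + rng.normal(0, sigma, (n_ch, n_samp))
    C = X @ X.T / n_samp
    C_expected = L @ np.diag(P) @ L.T + sigma ** 2 * np.eye(n_ch)
    assert np.abs(C - C_expected).max() < 0.15


def test_noiseless_single_source_sensor_rank_one(small_spec):
    prot_card = np.random.default_rng(0)
    spec = small_spec
    card = gen_cardiac(60.0, protocol_duration(4, (12.0,), 60.0), prot_card)
    prot = gen_protocol(card, "meg", 4, (12.0,), seed=1)
    src = {"racc": gen_source_epochs(40.0, prot, spec, seed=2, roi="racc")}
    lead = make_toy_leadfield(n_channels=12, seed=0)
    sens, _ = gen_sensor_epochs(src, lead, snr=np.inf, seed=3)
    x = sens["pulse2"][0]  # (channels, samples)
    s = np.linalg.svd(x, compute_uv=False)
    assert s[1] / s[0] < 1e-10


# ---------------------------------------------------------------------------
# BP and thickness
# ---------------------------------------------------------------------------

def test_inhibitor_bp_flat_at_beat_6():
    spec = CohortSpec(n_subjects=10, seed=2, bp_rise_nonin=6.0,
                      bp_subject_sd=0.5, n_trials=40)
    bp = gen_bp_series(["Inhibitor"] * 10, spec, seed=2)
    sel = bp[bp["beat"] == 6].groupby("subject")["map"].mean()
    base = bp[bp["beat"] < 0].groupby("subject")["map"].mean()
    assert np.abs((sel - base).mean()) < 1.0


def test_noninhibitor_bp_rise_peaks_at_beat_6():
    spec = CohortSpec(n_subjects=4, seed=2, bp_rise_nonin=8.0,
                      bp_subject_sd=0.1, bp_beat_noise_sd=0.5, n_trials=60)
    bp = gen_bp_series(["Non-inhibitor"] * 4, spec, seed=5)
    prof = (bp.groupby("beat")["map"].mean()
            - bp[bp["beat"] < 0]["map"].mean())
    assert prof.idxmax() == 6
    assert prof.loc[6] == pytest.approx(8.0, abs=1.5)


def test_thickness_coupling_and_range():
    inh = np.random.default_rng(3).normal(30, 25, 20)
    spec0 = CohortSpec(n_subjects=20, seed=0, thickness_coupling=0.0)
    t0 = gen_thickness(inh, spec0, seed=1)
    r0 = stats.spearmanr(0.5 * (t0["rACC_left"] + t0["rACC_right"]),
                         inh).statistic
    assert abs(r0) < 0.45

    spec1 = CohortSpec(n_subjects=20, seed=0, thickness_coupling=1.0,
                       thickness_noise_sd=0.0)
    t1 = gen_thickness(inh, spec1, seed=1)
    r1 = stats.spearmanr(0.5 * (t1["rACC_left"] + t1["rACC_right"]),
                         inh).statistic
    assert r1 == pytest.approx(-1.0)

    big = gen_thickness(np.random.default_rng(4).normal(30, 60, 10000),
                        CohortSpec(n_subjects=2, seed=0), seed=2)
    for col in ("rACC_left", "rACC_right", "insula_left", "insula_right",
                "rolandic"):
        assert big[col].between(1.5, 4.5).all()


def test_neurogram_samples_non_negative(small_spec):
    cohort = gen_cohort(small_spec, stages=("neurogram",))
    for sub in cohort.subjects:
        assert np.all(sub.neurogram.samples >= 0.0)
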