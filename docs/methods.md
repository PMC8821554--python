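# Methods

## The measurement model

A subject's stimulus-induced MSNA inhibition is a relative amplitude
change on the rectified/integrated neurogram. Bursts are bookkept as one
amplitude per cardiac interval, with absent bursts contributing exactly
zero, so the statistic

    inhibition% = 100 * (1 - mean(A_post) / mean(A_control))

mixes incidence and amplitude effects. The control period is the 8
cardiac intervals immediately preceding each stimulus train; the post
window defaults to the stimulated interval of each pulse in the train
(one interval per pulse, pooled over pulses), exposed as configuration
because the exact window length is a lab convention rather than a
derivable quantity. We pool amplitudes over all trials before forming the
ratio ("grand-mean" mode) so the statistic stays defined when individual
trials carry no baseline burst; a per-trial-ratio mode is provided as a
switch. The statistic is undefined when the pooled control mean is zero
(an error, never a fabricated value), and a profile with fewer than five
baseline bursts is flagged unreliable — relative change on a nearly
silent baseline is exactly the situation in which strongly negative
outliers (sympathetic excitation) are exaggerated.

Classification is strict: Inhibitor iff inhibition > 30 %. The bound is
reproduced by the dummy-trigger calibration: the inhibition statistic
evaluated against R-wave-timed triggers without stimulation, across
subjects, has a 95th-percentile absolute deviation near 30 % under the
generator's default burst statistics and 72-trial protocol.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions: 20 subjects, resting
heart rate 56 ± 7.8 bpm, burst incidence 44.3/100 heartbeats (burst
frequency then lands near 25/min), 72 trials, ITI drawn from {30, 45,
60} s by one randomized sequence shared across subjects, pulses 200 ms
post-R; microneurography trains use 5 consecutive cardiac intervals, MEG
trains 3 pulses on alternating heartbeats. Inhibition is drawn
Normal(30 %, 25 %) truncated at the +100 % hard bound — the mean/SD are
stipulations chosen to put roughly half the cohort above the 30 %
threshold, since only the split, the normality and the occasional outlier
are reported for the modeled cohort; an optional −132 % outlier replaces
the last subject.

Mechanics and deliberate simplifications:

- **Neurogram.** Bursts are Gaussian humps (FWHM 0.3 s) at 1.3 s post-R —
  a typical peroneal reflex latency — on a constant offset with additive
  Gaussian noise, clipped at zero. Real integrated neurograms have
  asymmetric bursts, drifting baselines and movement artifacts; none of
  that is modeled, so the detection stage (rolling 10 s median baseline,
  peak-pick in [0.8, 1.8] s post-R, threshold 3× robust noise SD) is
  validated for amplitude recovery, not for artifact robustness.
- **Inhibition mechanism.** Scaling acts on the amplitude expectation in
  stimulated intervals, with amplitudes falling below a floor (0.05 of
  the mean) rendered absent — at 100 % inhibition every post burst is
  absent, at −200 % the post mean is 3× baseline. Whether real inhibition
  follows mainly the first pulse is not settled; the generator applies it
  to every pulse of a trial and exposes a per-pulse toggle.
- **Source epochs.** 1/f background plus band-limited 13–25 Hz activity
  whose envelope carries an early (0–0.4 s) suppression and a Gaussian
  rebound bump centered at 0.85 s (SD 0.18 s). The subject-level rebound
  gain is `g = 0.8 * exp(0.35 * m)` with
  `m = c * s(inh) + sqrt(1-c^2) * eps`, `s` a soft-clipped z-score of
  inhibition and `c` the rebound coupling (default 0.8): at `c = 1` the
  gain is a deterministic strictly monotone function of inhibition, at
  `c = 0` independent of it. The rostral ACC carries the coupled rebound
  only after pulses 2 and 3, the Rolandic area after all three (weak
  after pulse 1), the insula responds but is uncoupled — mirroring the
  modeled result surface. No phase-locked evoked components, no 1/f
  slope differences, no cross-ROI leakage are simulated.
- **Sensors.** Per ROI one active grid point projects the ROI series
  through random unit-norm fixed-orientation topographies on a 5 mm
  lattice, plus white noise at a variance-ratio SNR (default 1.0).
  This is forward-model plumbing for testing the beamformer, not MEG
  physics; realistic head models are consumed as input in real use.
- **Blood pressure.** Diastolic-led MAP rise for Non-inhibitors with a
  Gaussian beat profile peaking at post-stimulus beat 6 (subject mean
  4 mmHg, between-subject SD 1.5 mmHg, per-beat noise 2 mmHg); Inhibitors
  flat; HR and pulse pressure carry no group effect, so the beats 1–15
  screen is null by construction. Baroreflex dynamics are not modeled.
- **Thickness.** rACC hemispheric thickness is base 2.75 mm minus
  0.28 mm × (coupled, squashed z of inhibition) plus 0.08 mm measurement
  noise, clipped to 1.5–4.5 mm; other ROIs uncoupled.

Passing tests therefore show that the analysis recovers the couplings the
generator injects under realistic trial counts and noise — not that it
would survive the artifact structure of real recordings.

All randomness descends from one integer seed; per-subject, per-stage
streams are split by fixed stage codes so any stage can be regenerated
independently and identical specs give bit-identical cohorts.

## Numerical and statistical choices

- **Rank-sum.** Exact enumeration for combined n ≤ 20 without ties,
  normal approximation with tie and continuity correction above; an
  all-tied sample returns p = 1 with a warning. Exactness is verified
  against full enumeration of rank assignments up to combined n = 12.
- **Spearman p-values (morphometry).** Exact permutation enumeration for
  n ≤ 8 (8! = 40320 permutations), t-approximation above. Full
  enumeration at n = 10 (3.6M permutations) buys no accuracy worth its
  cost here.
- **LCMV.** Diagonal loading λ = 5 % of the mean sensor variance
  (configurable); scalar beamformer via the max-power orientation of the
  reduced 3×3 problem; unit gain enforced by construction and tested to
  1e−10. Source power is the excision-aware mean squared filter output
  over the 1.5 s window. Unit-gain (not unit-noise-gain) weights are the
  default.
- **TFR.** Window length 7/f s, Hanning taper, amplitude-calibrated so a
  unit sinusoid yields unit peak power; positions without a full window
  are NaN and a frequency whose window exceeds the whole epoch yields an
  all-NaN row with a warning — never silent zero-padding. Frequency grid
  5–40 Hz in 2.5 Hz steps (the range is given, the spacing is ours).
  Per-trial decomposition precedes trial averaging; baseline power is
  averaged per frequency over the 1.5 s pre-pulse-1 window.
- **Cluster test.** Per-bin Spearman across subjects; cluster-forming
  threshold = two-sided p < 0.05 via the t-approximation; 4-neighborhood
  adjacency (no diagonals); cluster mass = sum of bin correlations;
  two-sided inference by pooling max |mass| over both signs in the
  permutation null; p = (1+k)/(n_perm+1) so p is never zero. NaN bins
  (incomplete windows) never enter clusters. Epoch timing under variable
  heart rate is handled upstream: trial placement prefers beats whose
  inter-pulse gaps fit the 1.5 s analysis window and falls back to the
  widest available gap at fast heart rates.
- **Degenerate inputs.** Constant inhibition vectors and constant maps
  are errors/no-clusters respectively; an ROI whose contrasts are all
  non-positive falls back to its single peak vertex with a warning;
  missing thickness hemispheres are errors, never silent single-side
  fallbacks.

## Problem sizes used by the checks

The null calibration of the cluster test uses 200 cohorts of 20 subjects
on a reduced 10×50 bin grid with 1000 permutations — the reduced grid
keeps the family-wise error estimate cheap while preserving the
clustering geometry. Parameter recovery runs 50 cohorts at full study
conditions (20 subjects, 72 trials) on the Rolandic pulse-3 condition;
the recovered statistic is the Spearman correlation of the top cluster's
averaged power with inhibition, compared against the realized
Spearman(rebound gain, inhibition) — median absolute error is well inside
±0.15. Thickness recovery compares against the noise-free structural
effect, so measurement noise is part of what must be overcome.

## Known limitations

- Cluster-averaged-power correlations are selection-biased upward
  (circularity of averaging within a cluster selected for correlation);
  the generic 13–25 Hz × 0.5–1.2 s window exists precisely as the
  unbiased confirmatory read-out, and both are reported.
- With few subjects the subject-level rebound-gain dispersion can align
  with inhibition by chance; the permutation test then (correctly) flags
  a real in-sample association. Null-coupling checks are therefore
  formulated as rates over seeds, not single-seed absolutes.
- The per-subject dummy-calibration bound depends on burst statistics
  and trial count; ±30 % emerges under the defaults but is not a
  universal constant.
- Group labels feed the BP contrast from the *measured* classification,
  so misclassified borderline subjects (measurement noise around the
  30 % threshold) dilute group differences exactly as they would in a
  real cohort.
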