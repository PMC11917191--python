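# Methods

This note documents the models, rules and numerical choices implemented in
`dyadnirs`, the assumptions behind the synthetic-data generators, and the
limits of what the simulation-based tests demonstrate.

## Behavioral contingency

### Detection rules

Coding is restricted to episodes of mutual gaze: only events whose onset
falls inside a gaze interval enter the analysis. For each infant behavior
the eligibility window for a maternal response is

* facial expression: `(onset, onset + W]`,
* vocalisation: `(onset, offset + W]` (a mother who waits for the
  utterance to end is still credited),

with W = 1000 ms. A maternal behavior starting at exactly the infant
onset is never contingent (it cannot be a response). If several maternal
behaviors fall inside one window only the earliest is paired. Infant
behaviors with identical onsets form a simultaneity group; one maternal
behavior may be credited to each member of the group.

Two conventions are configurable because the coding rules do not fix
them:

* **Window endpoint** (`inclusive_end`, default on): a maternal onset at
  exactly `onset + W` counts. The rules state "within 1000 ms" without
  fixing the boundary; the measure-zero choice is exposed.
* **Maternal reuse** (`reuse_maternal`, default on): a maternal behavior
  already paired with one infant behavior may still be the "first" for a
  later, non-simultaneous infant behavior. With reuse off, consumed
  maternal behaviors are skipped (except within a simultaneity group,
  where per-behavior crediting always applies). Both conventions are
  verified against an independent exhaustive scan.

The first 60 s of a session are a warm-up and are discarded; the
following 240 s are scored. All counts (C, I, M) and the gaze duration D
refer to the clipped window.

### Responsiveness index

```
index = C/I − (1 − exp(−M·W/D))
```

The subtracted term is the probability that a homogeneous Poisson process
with rate M/D produces at least one event in a window of length W — the
chance that an indiscriminately active mother lands in the window anyway.
D is carried in milliseconds and W = 1000 ms converts the rate to the 1-s
window; the formula is dimensionless. The index is undefined when I = 0
or D = 0 (`UndefinedIndexError`), marking an unanalyzable dyad rather
than silently returning 0.

The null calibration test draws independent mother/infant Poisson streams
and verifies the mean index is within 3 standard errors of zero. The null
uses facial-only infant behaviors: vocal behaviors lengthen the window to
`offset + W`, which the fixed-W chance term deliberately does not model,
so a vocal-inclusive null is positively biased by construction. This is a
property of the index as defined, not of the implementation.

## Maternal touch

The free-play video is divided into 2-s segments. Within a segment the
highest-priority category present is coded, the priority being the fixed
enumeration affective > harsh > playful > attention-getting >
instrumental > static > incidental (ordered by intentionality and
affective value); an untouched segment is "none". Each coded segment is
treated as touched for its full duration. Durations are summed per
category and divided by the video duration, which normalises away small
differences in interaction length. When the video length is not a
multiple of 2 s the final partial segment is weighted by its actual
length. "All touch" is the sum over the seven categories; affective touch
is also reported on its own because both enter the group regression.

## Observer reliability

* **Time-unit kappa** (GSEQ-style): sessions are discretized to 1-s units
  (configurable). A unit of one coder agrees when the other coder holds
  the same code within ±1 unit of tolerance. The tolerance rule is
  applied symmetrically — each coder's units are checked against the
  other's and both tallies enter the agreement matrix — so at tolerance 0
  the matrix is exactly twice the ordinary confusion matrix and the
  statistic reduces to Cohen's kappa (a tested identity). Degenerate
  marginals (one code everywhere) make kappa undefined; NaN is returned
  with percent agreement intact.
* **Event-alignment kappa**: the two coders' event sequences are aligned
  by global monotone dynamic programming. A pair may align when onsets
  differ by ≤ 2 s *and* the temporal overlap covers ≥ 80% of the shorter
  event (the convention — shorter, longer, or union — is not fixed by the
  coding rules; shorter is
  adopted and is configurable in spirit via `min_overlap`). Scoring is 2
  for a same-code pair, 1 for a different-code pair, 0 for a gap, so the
  alignment maximises matches with a preference for agreements. Aligned
  pairs are tallied by code, unmatched events against a nil code. The DP
  is verified against exhaustive enumeration of all monotone matchings
  for short sequences; when several matchings are optimal the tallied
  kappa equals that of one of them.
* **Cohen's kappa** on per-segment labels delegates to
  scikit-learn, cross-checked against the closed form in tests.
* **ICC**: "two-way mixed, single measures" is read as the consistency
  ICC(3,1) = (MS_targets − MS_error)/(MS_targets + (k−1)·MS_error),
  computed via pingouin; `kind="agreement"` switches to the
  absolute-agreement single-measures coefficient. Constant ratings raise
  `UndefinedStatisticError`.

GSEQ's exact internal tally conventions are not fully published; results
should be labelled "GSEQ-style" when compared with that software.

## fNIRS preprocessing

Stages run in a fixed order, recorded with all parameters in a per-run
manifest; every exclusion decision is a pure function of inputs and
configuration.

1. **Looking filter.** A trial is valid iff the infant looked at the
   screen for strictly more than 50% of the trial *and* at least 50% of
   the brushing period (pooled across the strokes of a trial). Missing
   looking data invalidates the trial with a warning.
2. **Channel pruning.** A channel is dropped when, at either wavelength,
   mean raw intensity falls outside 0.09–1 V or SNR = 20·log10(mean/SD)
   is below 0 dB.
3. **Optical density.** OD(t) = −ln(I(t)/mean(I)) per channel and
   wavelength. Because OD is referenced to the mean intensity, absolute
   concentration offsets are unobservable; every downstream quantity is a
   baseline-referenced change, and recovery tests compare mean-centred
   traces.
4. **Motion detection.** A sample is flagged when the signal range within
   the 1-s window centred on it exceeds 0.4 OD or 14 standard deviations
   of the channel's first differences (a sample-to-sample noise
   estimate), at either wavelength. Flagged windows are dilated to cover
   the full offending window. At zero noise the SD-relative criterion
   flags the hemodynamic slopes themselves (any deterministic change is
   infinitely many "SDs" of zero noise); noiseless validation runs
   therefore disable the motion stage.
5. **Wavelet correction.** Channels with flagged samples are decomposed
   (Daubechies-5) down to a detail scale of ~0.12 Hz; detail coefficients
   lying more than 0.5·IQR beyond the quartiles of their level are set to
   zero and the signal reconstructed. The hemodynamic band sits in the
   untouched approximation: the measured RMS change of a clean
   block-design signal is ≈ 4%, while injected spikes lose ≈ 95% of
   their amplitude. Clean channels pass through bit-identically.
6. **Heart-rate check** (automated surrogate for visual inspection): the
   Welch spectrum (256-sample segments) must show a peak in the 1.5–3.5 Hz
   cardiac band exceeding 3× the median in-band power at both
   wavelengths. An infant heart rate near 150 bpm (2.5 Hz) is resolvable
   at the 7.8125 Hz default sampling rate.
7. **Residual motion / trial rejection.** Detection is re-run on the
   corrected signal; a trial is rejected when any residual artifact on a
   surviving ROI channel overlaps its baseline-plus-trial span (the span
   can be restricted to the trial alone). The minimum of three valid
   trials per condition is then re-applied; a subject failing it in
   either condition is excluded.
8. **Band-pass.** Zero-phase 4th-order Butterworth, 0.01–1 Hz (applied
   forward and backward, so the effective order is 8 with no phase
   distortion); DC is removed.
9. **Beer–Lambert.** ΔOD = ε·Δc·d·DPF inverted per channel with
   DPF = 5.1 and the compiled hemoglobin extinction coefficients
   (Gratzer/Kollias values as distributed with Homer: 760 nm — HbO 586,
   HbR 1548.52; 850 nm — HbO 1058, HbR 691.32 cm⁻¹/(mol/L)); the table is
   swappable. Output is µmol/L.
10. **ROI epochs.** Right ROI = channels {8, 9, 13, 14}, left ROI =
    {23, 24, 28, 29}; an ROI is kept only with ≥ 2 surviving channels.
    Epochs span 18 s from trial onset (the six 3-s analysis bins; the
    final 3 s extend past the 15-s trial into the following baseline) and
    are corrected by the mean of the final 3 s of the preceding 12-s
    baseline. Both window and reference are configurable.

## Group statistics

The condition-averaged 18-s epochs are averaged in six 3-s bins per ROI,
chromophore and condition. The two-way within-subject ANOVA uses the
classical sums-of-squares decomposition, testing each effect against its
interaction with subject, with uncorrected degrees of freedom (condition:
1, n−1; bin and interaction: 5, 5(n−1)); a Greenhouse–Geisser correction
is deliberately not applied by default. The implementation is native
numpy (the null-calibration test runs thousands of fits) and is verified
against pingouin to 1e-10. An effect whose sum of squares is exactly zero
reports F = 0, p = 1 rather than 0/0 rounding noise.

Post-hoc per-bin paired t-tests are uncorrected by default; bins with
zero difference variance are flagged degenerate instead of reporting an
infinite t.

Difference scores average the condition-averaged HbO epoch over the whole
post-stimulus window and subtract noncontingent from contingent, so a
negative score means a stronger noncontingent response. ROI averaging
precedes condition averaging. The regression is OLS (statsmodels) with an
intercept on five predictors — all-touch %, affective-touch %,
sensitivity (1–7), responsiveness index, age in days — with listwise
deletion, per-coefficient t-tests, 95% CIs, overall F and adjusted R²;
rank-deficient designs fail loudly naming the most collinear predictor
pair. Post-hoc condition-wise regressions apply the same machinery to
each condition's mean activation.

## Synthetic data: what it emulates, and what it does not

**Dyads.** Mutual gaze covers a configurable fraction of the session
(default 0.8 over 8 episodes with Dirichlet-distributed lengths). Infant
behaviors are a homogeneous Poisson process inside gaze (default
0.1 s⁻¹); each triggers a maternal response with probability
`response_prob` at a Uniform(100, 900) ms latency; spontaneous maternal
behaviors add an independent Poisson stream (0.1 s⁻¹). Behaviors are
vocal with probability 0.4, otherwise a random facial code. Everything is
reproducible from the seed.

**Touch.** Independent per-segment category draws. Cohort simulations
draw each dyad's total-touch probability from a clipped Normal(0.62,
0.27) and its affective share from Normal(0.10, 0.09), matching the
descriptive spread reported for such samples.

**fNIRS.** Up to 10 trials per condition tile the ABBABAAB order
(contingent first), each 15 s preceded by a 12-s baseline, plus a 12-s
tail. Ground-truth HbO is a condition×ROI amplitude boxcar convolved with
a double-gamma HRF (peak 5 s, undershoot 15 s, ratio 0.35), scaled so a
single trial's response averages to the configured amplitude over the
18-s analysis window; HbR is −0.35× HbO. Default amplitudes
(contingent/noncontingent) are 0.41/0.50 µM left and 0.35/0.50 µM right,
so the generator's true difference scores are −0.09 and −0.15 µM.
Physiological noise is sinusoidal cardiac (~2.5 Hz, 0.15 µM — an infant
heart rate near 150 bpm), respiratory (~0.6 Hz, 0.10 µM) and Mayer-wave
(~0.1 Hz, 0.10 µM) components with jittered frequency and phase, plus a
random quadratic drift and white noise. Concentrations are
forward-projected to 760/850 nm intensity through the same Beer–Lambert
model the pipeline inverts (per-channel separations 20–25 mm, mean
intensity 0.3–0.8 V); motion spikes (double-exponential, 0.45–1.2 OD,
random sign) are injected in OD space with their realized sampled
amplitudes recorded. Per-trial looking fractions are Beta(3.5, 1.5)
(mean 0.7, ≈ 77% of trials pass the looking rule — matching the
attrition from 10 delivered to ~6 analyzable trials per condition).

Not emulated: photon transport and partial-volume effects (the forward
model is the same algebraic law the pipeline inverts, so the round-trip
test validates the inversion, not tissue optics); HRF variability across
infants; serially dependent behavior streams; coder disagreement beyond
what the reliability toys construct. Passing tests therefore demonstrate
correctness of the *computations* under the stated generative model, not
robustness to every property of real infant data.

## Problem sizes and runtime choices

The verification suite chooses sizes that make Monte-Carlo error small
relative to each acceptance band: 1000 random sessions for the detector
oracle, 500 dyads for the null calibration, 5000 replicates for the
ANOVA type-I rate (MC SE ≈ 0.003 against a ±0.015 band), 12 sessions
(~550 spikes) for motion detection, and n = 200 cohorts with 10
replicates for end-to-end recovery power. Recovery cohorts simulate 6
trials per condition (the typical number of analyzable trials) on the
8-channel ROI montage; the full 30-channel montage is exercised in the
pipeline tests and CLI demo.

## Known limitations

* The forward optical model shares its extinction algebra with the
  inversion; agreement is a consistency check, not a validation against
  tissue physics.
* The heart-rate check is a spectral-prominence heuristic standing in for
  expert visual inspection; its threshold (3× median in-band power) was
  chosen for clear separation of the simulated cardiac component from
  white noise and should be re-tuned for real recordings.
* GSEQ's exact tally conventions are approximated; kappas computed here
  can differ slightly from GSEQ output on the same data.
* The rm-ANOVA reports uncorrected degrees of freedom; with 6 bins,
  sphericity violations in real data would call for the optional
  Greenhouse–Geisser flag.
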