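# Methods

This note documents the models, parameter choices and numerical decisions
behind `nwreflex`, and what the synthetic cohorts do and do not show about
real recordings.

## Signal model and preprocessing

Epochs are two-channel (tibialis anterior TA, soleus SO) stimulus-locked
traces, −500…+3000 ms around laser onset at 1000 Hz (3501 samples), in µV.
Time is always expressed relative to stimulus onset; windows are half-open
`[a, b)` except the upper edge of TW2, which is closed at 3000 ms so that
the latest representable onset still classifies.

The conditioning chain is band-pass filter → segment → rectify. The filter
is a 4th-order Butterworth, 1–450 Hz, applied forward–backward
(`sosfiltfilt`): zero-phase filtering is essential because a causal filter
would add a group delay to every detected onset latency and bias the
conduction-velocity estimates. The 450 Hz edge sits at 0.9 of the Nyquist
frequency, so the design uses second-order sections for numerical
stability. Non-1000 Hz data are accepted as long as the sampling rate
exceeds twice the upper band edge; nothing is resampled.

## Reflex detection

* **Background**: mean and SD of the *rectified* signal over −500…0 ms.
  The detection threshold is `T = mu_bg + k·sigma_bg` with `k = 2`.
  Including the mean makes `T` invariant to the positive offset that
  full-wave rectification introduces; the published criterion ("two
  standard deviations above background noise") does not say whether the
  background mean is added, so this is a declared choice.
* **Bursts**: a burst starts at the first of ≥ `min_burst_ms` (6 ms)
  consecutive samples at or above `T`, absorbs further activity until the
  signal stays below `T` for ≥ 50 ms (`offset_hold_ms`), and bursts closer
  than 50 ms (`merge_gap_ms`) are merged. Detection is restricted to
  `[0, 3000)` ms. The 6 ms minimum is the calibrated value at which the
  seeded synthetic suite reaches ≥ 95 % recall on planted bursts down to
  ~18 µV peaks while noise-only trials stay below a 5 % false-positive
  rate (measured 0/1000); single- or two-sample crossings are still
  rejected.
* **Polyphasia**: phases are counted on the signed (unrectified) signal
  inside the burst: lobes between zero crossings qualify as excursions when
  their peak magnitude reaches `0.5·T`, and the count is 1 + the sign
  changes between successive qualifying excursions. Events need ≥ 3 phases
  (`min_phases`), operationalizing "polyphasic activity" while suppressing
  monophasic artifacts.
* **Characterization**: onset = burst start; `AUC = Σ (rect − mu_bg)⁺ · Δt`
  in µV·s (baseline-corrected so that pure background integrates to ≈ 0);
  peak = max rectified value.
* **Windows**: TW1 `[90, 600)` ms, TW2 `[1000, 3000]` ms, the gap labelled
  `intermediate` and never silently dropped. The boundaries contain the
  published latency means ± 2 SD for each site. Multiple bursts in one
  window: the window latency is the earliest onset, the window AUC the sum.
* **Artifact guard**: a trial whose background SD exceeds 30 µV on either
  channel is flagged invalid and carries no events.
* **Co-activation**: a window is co-activated when TA and SO events there
  start within 100 ms of each other.

## Aggregation and conduction velocity

Response rates count *trials*, not muscles: a trial is one response in a
window as soon as either muscle shows a qualifying burst (so co-activation
cannot double-count). Invalid trials leave every denominator. A responder
is any participant with a rate > 0.

Conduction velocity uses the two-site latency shift: with the sole of the
foot (FS) distal and the fibula head (FH) proximal,
`CV = distance / (median latency(FS) − median latency(FH))`. Medians (not
means) make the estimate robust to occasional multi-burst or noise-seeded
trials; at least 3 responses per site are required, and a non-positive
shift yields an *undefined* estimate rather than an error or a clipped
value. Latencies are taken from the TA channel only, because co-activated
SO bursts carry their own onset scatter (up to ±40 ms) that would bias the
shift. TW2 shifts give C-fiber-range CVs (~0.5–2.5 m/s), TW1 shifts
A-delta-range CVs (~4–20 m/s).

## Synthetic cohorts

The generator's defaults encode the study conditions the analysis assumes;
they are fixed, not tuning knobs.

* **Noise**: band-limited (20–450 Hz) Gaussian noise, SD 5 µV. Surface EMG
  baseline noise has little energy below ~20 Hz; 5 µV is a typical resting
  baseline for well-prepared bipolar leg-muscle electrodes.
* **Response structure**: per participant and (site, window), a response
  propensity is drawn from `Beta(c·p, c·(1−p))` with concentration `c = 2`
  around the group/site mean rate `p` (SCI TW1: 9.6/14.4/14.3 % for
  FS/FD/FH; SCI TW2: 19.9/20.7/16.2 %; NDC TW1: 0; NDC TW2:
  2.5/4.3/3.1 %). The low concentration reproduces the strongly
  zero-inflated spread seen clinically (medians near zero, a responder
  subgroup carrying the mean) and per-site responder fractions around
  70–80 % in SCI. Trials are then independent Bernoulli draws of that
  propensity.
* **Latency model**: each participant has latent conduction velocities
  `CV_TW1 ~ N(10, 3)` m/s (truncated to [4, 20]) and
  `CV_TW2 ~ N(1.34, 0.46)` m/s for SCI / `N(1.08, 0.38)` for NDC
  (truncated to [0.6, 3]), and a per-window anchor latency at the proximal
  site FH drawn from the published per-site mean ± SD. Distal sites lag the
  anchor by `distance/CV`; per-trial jitter is `N(0, 15)` ms in TW1 and
  `N(0, 30)` ms in TW2 plus 5 % multiplicative CV jitter. The published
  per-site cross-sectional latency means are not mutually consistent with
  any single per-participant CV, so the generator prioritizes CV
  consistency (which the estimator tests) and treats the published per-site
  SDs as *between*-participant spread; the 30/15 ms trial jitter reflects
  within-participant onset variability. Parameter-recovery checks compare
  the detector to the planted truth, not to the published table.
* **Burst morphology**: a burst is a train of alternating-sign lobes of
  ~20 ms (at least `n_phases` of them) with peak amplitudes in
  `[0.6, 1]×A`, the largest scaled to `A` exactly; positive and negative
  lobe areas are width-balanced so each burst integrates to ~zero. Real
  EMG carries no DC and its deflections are 10–30 ms wide; wider lobes
  would put energy below the 1 Hz high-pass edge and produce artificial
  baseline tails. A `rect` envelope mode (all lobes at full amplitude,
  5 % cosine ramps) makes the rectified integral ≈ `A·d` for analytic AUC
  checks.
* **Amplitudes**: SCI TW2 1000 µV, TW1 300 µV, durations 150–400 ms /
  80–200 ms; NDC 25 µV and 60–160 ms throughout — a 40× amplitude and 2.5×
  duration contrast, i.e. roughly two orders of magnitude in AUC, matching
  the reported magnitude gap. Absolute published AUC values are
  unit-ambiguous and are not targets; only ratios and orderings are.
* **Muscle pattern**: an SCI response co-activates TA and SO with
  probability 0.7 (SO onset offset `N(0, 15)` ms clipped to ±40 ms),
  otherwise a single muscle; NDC responses are never co-activated and fall
  on TA with probability 0.78.
* **Pain ratings**: per-participant site means around the group/site
  published values; SCI participants are analgesic per site with
  probability 0.46/0.40/0.50 (FS/FD/FH), NDC never.
* **Clinical table**: CPG (central neuropathic pain grading) is Bernoulli
  `p = 8/15`; clinically relevant spasticity follows
  `logit P = log 6 + log(1/18)·1[CPG]`, reproducing 6/7 spasticity among
  CPG-negative and 2/8 among CPG-positive participants in expectation —
  the inverse association the battery tests. Joint scores (6 joints MAS
  0–5, SCAT 0–3) are drawn consistently with the relevance flag; SCIPI and
  NRS are drawn around the CPG-conditional published means.
* **Reproducibility**: one seed fans out through `SeedSequence` spawn keys
  per participant and per participant × site, so enlarging a cohort never
  reshuffles existing participants, and identical configs give
  byte-identical output files.

**What passing tests show — and don't.** The synthetic cohorts share the
*statistical* structure of real recordings (rates, latencies, contrasts,
co-activation, CV geometry) but not their physiology: no motor-unit
waveforms, no habituation across the 60-stimulus series, no
skin-temperature effects, no volitional-movement contamination, and noise
is stationary Gaussian rather than movement-artifact-laden. Passing
recovery tests therefore validates the *pipeline's* correctness under its
stated assumptions, not detector performance on arbitrary clinical data.

## Statistical battery

* **Wilcoxon rank-sum**: midrank ties; exact p by full enumeration of all
  `C(n, n1)` group assignments when `n1+n2 ≤ 12` (handles ties, unlike
  textbook tables), otherwise a normal approximation with tie correction
  and continuity correction. Effect size `r = |Z|/√N` in all cases.
  Two identical-value samples return `p = 1, r = 0` (flagged degenerate).
* **Fisher's exact test**: two-tailed p sums hypergeometric probabilities
  ≤ the observed table's; effect size is `φ = |ad−bc|/√(margins)` reported
  as a magnitude. An empty margin is an error, not a silent NaN.
* **Kendall tau-b** with tie corrections; one-tailed p is the directed
  half of the two-tailed value when the observed sign matches the stated
  alternative. Zero variance in either variable flags the result instead
  of fabricating a coefficient.
* **Eta**: `η = √(SS_between/SS_total)`, pairwise-complete. η has no
  standard sampling distribution of its own; its p-value is taken from the
  equivalent one-way ANOVA F-test (η² is that model's R²).
* **Tails policy**: one-tailed for the a-priori directional hypotheses
  (responders and response rates SCI > NDC; spasticity–reflex
  correlations), two-tailed otherwise. No multiple-testing correction is
  applied (matching common exploratory practice); the report states the
  number of tests run so a reader can apply their own.
* **Missing data**: pairwise-complete deletion per test, with n reported
  per result. Untestable combinations yield flagged rows, never silently
  dropped ones.
* **Clinical classification**: clinically relevant spasticity = any joint
  > 1 on MAS or SCAT when joint scores exist; with only score means
  available the fallback is mean > 1 (a mean cannot reveal a single high
  joint, so this under-detects borderline cases — flagged as missing only
  when no score exists at all). SCIPI ≥ 4/7 is a positive neuropathic-pain
  screen; NRS ≥ 4 is clinically relevant spontaneous pain.

### Type-I calibration

The null-simulation check runs each primitive 1000 times on null data at
moderate sample sizes chosen for test validity rather than to mirror the
study's n ≈ 15: Wilcoxon 25+25 (continuous), Fisher on 2×2 tables from 100
subjects with p = 0.5 margins, tau-b at n = 40, eta at 20+20. Exact tests
at n ≈ 15 are intrinsically conservative (attainable significance levels
are coarse), which would measure test discreteness, not implementation
correctness. All four land in 0.05 ± 0.02.

## Problem sizes

The shipped tests and the acceptance script use cohort sizes of 4–15
participants per group, 8–30 trials per site, 1000-replicate null
calibrations, 1000 noise-only trials for specificity and 40–50 seeded
cohort replicates for the group-contrast checks — sizes at which every
stochastic acceptance band holds with comfortable Monte-Carlo margins
while a full run stays around a minute on a single CPU.

## Known limitations

* The BrainVision adapter is untested against real recorder output (no
  shippable fixture exists); it is a thin `mne` wrapper.
* The fallback spasticity rule from score means cannot implement the
  any-joint criterion exactly (see above).
* The published per-site latency tables and the per-participant CV model
  cannot both hold; the generator chooses CV consistency (documented
  above), so simulated distal-site latency means deviate from the printed
  per-site values by the mean conduction delay.
* Absolute AUC values are reported in µV·s under the package's own
  definition; published AUC tables use unstated units and are comparable
  only as ratios.
* η for CPG × MAS computes to 0.62 on the packaged reference table
  (pairwise-complete n = 13); treat small-sample η values as descriptive.
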