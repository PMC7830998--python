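# Methods

## Signal model and what the generator emulates

The gastric slow wave is modelled phenomenologically as a sinusoid with
instantaneous frequency f(t) near 3 cpm and amplitude A·g(t), A ∈ 100–500 µV.
All three electrodes see one gastric source: they share f(t) and differ only
in a random phase offset and in independent additive white Gaussian noise
(optionally plus a 0.005 Hz baseline wander). The phase is accumulated as
φ(t) = 2π∫f dτ rather than 2π f(t)·t, so episode frequency shifts are
phase-continuous; a literal f(t)·t parameterisation would create phase jumps
at episode boundaries that the PSD would smear into broadband artifacts.

Nausea episodes multiply the amplitude by `amp_gain` and may add
`freq_shift_cpm` to the frequency, inside a window restricted to the driving
trial. Amplitude transitions use a 30-s linear ramp placed inside the
episode window; a step edge would be trivially detectable by the envelope
and would overstate detector performance.

Sessions default to the studied protocol: three 900-s trials at 2 Hz, the
driving trial split 420/60/420 s into part A, a transition, and part B.
Samples are quantized to 16 bits over a fixed ±1000 µV input-referred range
(the acquisition chain specifies gain and bit depth but not the range; ±1 V
at gain 1000 gives a concrete 0.031 µV step). Saturation is therefore a
representable failure mode: runs ≥1 s at the rails are auto-annotated.

Wristband channels are simple trend models at wearable-typical rates: GSR at
4 Hz with a tonic level drifting +0.5 µS per trial (arousal accumulates),
heart rate at 1 Hz elevated +8 bpm during the drive. Button presses encode
the observed report-leads-detection behaviour: the first press of an episode
is drawn at episode start − 60 s (SD 30 s jitter), further presses arrive as
a Poisson process at `press_rate_per_min` until the episode ends. A plain
inhomogeneous Poisson process on the widened window cannot put the *mean*
first press at the configured lead (it is biased late by 1/rate), so the
first press is placed explicitly.

What the generator does **not** emulate: mechanistic gastric
electrophysiology (no ICC network, no respiration or ECG bleed-through),
non-stationary baseline physiology, realistic motion-artifact morphology
(artifacts are windowed 0.25 Hz bursts), or between-channel amplitude
asymmetries. Passing tests therefore demonstrate that the analysis recovers
the statistical structure it assumes — sinusoidal band-limited rhythms with
episodic amplitude/frequency changes — not that it is robust to every
pathology of real abdominal recordings.

## Preprocessing

"6th order band-pass" is read as a 6-pole band-pass transfer function
(scipy `butter(3, ..., btype="bandpass")`), with single-pass −3 dB points at
1 and 10 cpm. Forward–backward application (`sosfiltfilt`, reflected edges)
cancels phase so event timing is preserved and squares the magnitude
response, leaving amplitude ≈0.5 at the nominal cutoffs; tests assert this
against the closed-form Butterworth band-pass magnitude. The first and last
60 s of a filtered recording are flagged as edge transients and excluded
from feature segments. Annotated samples are masked (NaN), never
interpolated: time-domain statistics pool clean samples, spectral estimation
uses clean contiguous stretches only. Channel selection minimises total
annotated artifact+saturation seconds, ties to the lowest index; edge flags
hit all channels equally and are ignored by the selection.

## Spectral indicators

PSD: averaged modified periodogram, Hann window, 512-sample (256 s)
segments, 50% overlap — ≈0.23 cpm resolution, comfortably under the 0.25 cpm
contract, on trials of ≥5 min of clean data (minimum 300 s enforced). Each
clean stretch long enough for a full window contributes periodograms
weighted by its window count; with no masking this reduces exactly to Welch.
The analysis band equals the filter band (1–10 cpm): bins outside the
passband are filter artifacts, not physiology.

Definitions (band-restricted): MFM = max PSD; DF = its frequency, ties to
the lowest bin; MF = first bin where cumulative power reaches half the band
total (a discrete, testable convention); CF = MFM / RMS of band PSD values
(so a flat PSD gives exactly 1, one nonzero bin among m gives √m); FSD =
100 × #(bins > MFM/4)/#bins. RMS is computed in the time domain over clean
samples. Indicators are exposed both from a signal (`compute_features`) and
from a PSD (`spectral_indicators`) so closed-form spectra can be tested
directly.

## Onset detection

The published rule compares an envelope sample against two means. Two
readings were genuinely open:

- *What is the envelope of a zero-mean signal?* A running median of the
  filtered signal itself would sit near zero; the minimal reading that makes
  the rule meaningful is a running median of the **rectified** signal
  (window 150 s = 300 samples ≈ 7–8 slow waves; even window = mean of the
  two central order statistics; reflected edges). For a stationary sinusoid
  of amplitude A this envelope sits near 0.707·A.
- *"Mean value of corresponding baseline signal"* — baseline envelope mean
  or rectified-signal mean? Both are implemented (`OnsetConfig.baseline_stat`,
  default `"envelope"`, same units as the compared sample); they differ by
  <10% for stationary signals.

A sample is flagged iff env > 2.0 × mean(baseline reference) AND env > 1.6 ×
mean(trial envelope); detection is run on the driving trial only, against
the baseline trial of the same channel. Flagged maximal runs become
half-open episodes; `duration_s` = flagged samples / fs;
`rel_rms_increase_pct` compares the RMS of the flagged source samples to the
clean baseline-trial RMS, and is *absent* (None), not zero, when nothing is
flagged.

Geometry of recovery: the median window erodes detections by up to ~one
window at episode edges (the envelope needs half a window inside the
plateau to reach it, and the 30-s generator ramps add to this), and the
trial-mean threshold tightens as the episode occupies more of the trial
(with gain g over fraction p of the trial, flagging requires
g > 1.6·(1 + p(g−1)); at g = 2.5 this caps p below ~0.37). Recovery tests
therefore assert coverage of the episode window shrunk by half a window per
edge and require flagged time to stay inside the true window — the honest
statement of what the published rule can localise.

## Statistical harness

Screening: post−pre differences of the 17 symptom ratings; fail iff any
difference > 5 or at least three differences > 3 (boundary values pass).

Test selection per indicator and comparison: Shapiro–Wilk at α = 0.05 on the
paired differences (two levels) or on each level's residuals (three levels;
all must pass). Normal → paired t, or RMANOVA with Mauchly's sphericity test
arming the Greenhouse–Geisser correction; non-normal → Wilcoxon signed-ranks
(exact when sample size and ties permit, else normal approximation) or
Friedman. Post-hocs (Bonferroni: pairwise p × number of comparisons, capped
at 1) are computed only when the omnibus null is rejected at the loosest
reported α; both α = 0.05 and α = 0.1 are reported. Constant data short-
circuits to p = 1 (nothing to test) rather than erroring inside Shapiro–Wilk.
RMANOVA and sphericity are delegated to pingouin and cross-checked against
statsmodels' AnovaRM in the suite; subjects missing a segment are dropped
from that comparison and listed in the report, never silently.

Sensitivity: minimal detectable effects by bisecting the analytic power
functions — noncentral F with df (k−1)ε, (n−1)(k−1)ε and noncentrality
λ = f²·n·k/(1−ρ)·ε (the G*Power "as in Cohen" convention; defaults ρ = 0.5,
ε = 1, recorded as this package's convention, not asserted as anyone
else's), converted via η²ₚ = f²/(1+f²); and noncentral t with ncp = dz·√n,
f = dz/2. Underflowed cdf values at extreme noncentrality are treated as
power 1. Each analytic value is cross-checked by an independent 5000-rep
Monte-Carlo simulation of the corresponding test (subject effect variance ρ,
error variance 1−ρ).

## Problem sizes and numerical choices

Simulation-backed tests use: 100 seeded sessions for the button-lead and
null-behaviour checks, 100 runs for the tachygastria direction check, 60
cohorts of 17 subjects on 10-min trials for the trial-comparison power
check, 1000 null cohorts for the type-I calibration, and 5000 reps for the
Monte-Carlo power oracles — sizes chosen so Monte-Carlo error is small
against each asserted margin. Intervals are half-open [start, end) in
seconds on a single session clock; sample indices 0-based (channel indices
0-based in code; prose counts channels from 1). Session CSVs are written
with `%.17g` and read with round-trip float parsing, making write∘read the
identity on float64 data.

## Known limitations

- The detector's thresholds are relative to trial means, so very long or
  very strong episodes raise their own threshold (see geometry above);
  quantifying sensitivity as a function of episode fraction is future work.
- Envelope samples whose median window touches masked data are NaN and never
  flagged; a guard band around artifacts is not applied (none was specified).
- GSR/HR are trend models only; their comparisons exercise the harness, not
  autonomic physiology.
- The group-level results of the original study are not reproducible here:
  the raw recordings were never deposited. The harness reproduces the
  *procedure* on synthetic cohorts with known ground truth instead.
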