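# Methods

This note records the models, conventions and numerical choices behind
`wavepac`, and what the synthetic tests do and do not demonstrate.

## Signal model of the generator

A non-sinusoidal oscillation is built from half-cosine arcs.  Within each
cycle a phase θ advances linearly from −π to 0 over the *rise* (a fraction
`rdsym` of the period) and from 0 to π over the *decay*; the base waveform
is cos θ, so `rdsym = 0.5` with unit exponents reproduces a pure sinusoid
(the cycle starts at a trough, i.e. −cos 2πft).  Sharpness is controlled by
raising the magnitude of the positive half to `peak_exp` and of the
negative half to `trough_exp` (both ≥ 1): this narrows the extremum while
preserving its value of ±1, so amplitude and sharpness stay decoupled.
The mean over an integer number of cycles is subtracted.

Consequences used throughout the tests: the maximum rise slope scales as
1/`rdsym` and the decay slope as 1/(1−`rdsym`), so the noiseless
rise-to-fall ratio is ln((1−rdsym)/rdsym) — negative (steeper decay) for
`rdsym > 0.5`; `peak_exp > trough_exp` gives a positive peak-to-trough
ratio.  A Q4 ("canonical sensorimotor") waveform is obtained with
`rdsym > 0.5` and `peak_exp > 1`.

The aperiodic background is white Gaussian noise whose spectrum is
multiplied by f^(−χ/2) (DC bin zeroed), then standardized; χ defaults to 2,
a typical EEG value.  Gamma coupling multiplies a `gamma_freq` carrier by
`amp·(1 + m·cos θ)`, so the envelope min/max ratio is (1−m)/(1+m) and
`m = 0` leaves a constant-amplitude carrier — the uncoupled control still
contains gamma power.  Artifact spans are overwritten with broadband bursts
ten times the oscillation amplitude and carried as ground-truth intervals.

Default conditions mirror a realistic resting-EEG study: 15 subjects,
channels C3 and C4, 180 s at 512 Hz, oscillation amplitude 1 with 1/f²
background at amplitude 0.5 ("moderate" noise: β-band noise power is small
relative to the rhythm, as in sensorimotor EEG with a clear beta peak), and
between-subject spread 0.02 on the rise fraction (additive) and on the
log-sharpening exponents.  Paired cohorts draw per-subject offsets once and
apply them to both conditions, so off/on differ only by the declared state
effect plus independent noise realizations.

## Preprocessing

Channels are demeaned and common-average referenced over good channels
(bad channels pass through but are excluded from the average and analyses);
bipolar derivations (e.g. C3−CP1) are available as an alternative montage.
The 0.5 Hz high-pass is a linear-phase FIR applied forward and backward
(zero net phase); its length follows the common three-cycles heuristic,
3·round(fs/cutoff) taps forced odd, capped at a third of the signal length
with a warning.  Channel means are removed exactly before filtering.
Artifact intervals are half-open, 0-based sample spans, normalized
(sorted/merged/clipped) on entry; second-based annotations are converted
conservatively (floor start, ceil end).  Filtering always runs on the
continuous data; masking is applied afterwards.

## Cycle features

Cycles are delimited by zerocrossings of a one-pass 13–30 Hz FIR
(Hamming-window design, order 231 ms ⇒ 119 taps at 512 Hz, group delay
compensated by centering so filtered and raw samples are index-aligned); a
sample exactly at zero counts as nonnegative.  Features are measured on the
raw signal: peak = argmax over [rising, falling), trough = argmin over
[falling, next rising), first index on ties.  Sharpness uses the two
differences at exactly ±`width` samples (default 3); steepness is the
maximum one-sample forward difference from the previous trough to the peak
(rise) and the maximum absolute difference from the peak to the trough
(decay).  A cycle is dropped when an extremum lies in an artifact interval
or within `width` samples of a boundary, or when a steepness segment
overlaps an interval.  Ratios are natural logs of quotients of means over
valid cycles; at least 5 valid cycles are required, otherwise the metric is
reported as undefined.  Both the vectorized path and a deliberately naive
loop-based reference (kept under `tests/`) are exercised against each other.

## PAC

Phase and amplitude come from the angle and magnitude of the Hilbert
analytic signal of the 13–30 Hz (order 231 ms) and 50–150 Hz (order 240 ms)
band-passed copies; the signal mean is removed first.  The default ordering
is filter → remove flagged regions → Hilbert (concatenating across gaps); a
switch transforms first and masks afterwards, widening every gap by one
filter length to keep transform edges out.  One filter length is discarded
at each end in either mode.  Amplitude is averaged in 18 equal phase bins
over (−π, π] (right-closed); the modulation index is KL(P‖uniform)/ln 18.
An empty bin raises an insufficient-data error rather than returning a
biased value.

## Spectral gate

Welch PSD with Hamming window, 256-sample segments, 128 overlap, 450-point
transform, constant detrend.  The oscillation-presence gate fits a log-log
line to the spectrum outside the candidate band (2–100 Hz) and requires a
local maximum inside the band exceeding that background by a factor
(default 2).  This replaces a visual inspection step and is intentionally
conservative and configurable.

## Group statistics

Paired comparisons use the Wilcoxon signed-rank test (zero differences
dropped, statistic = smaller rank sum, exact sign-flip null for n ≤ 25,
continuity-corrected normal approximation beyond); unpaired comparisons a
tie-corrected rank-sum z (computed directly, since the plain rank-sum
routine in scipy omits the tie correction).  Spearman correlations use the
t approximation with n−2 df.  Multiplicity is controlled by
Benjamini–Hochberg step-up FDR across all metrics passed in one family.
Cohen's d uses pooled unbiased SD for both paired and unpaired designs (one
formula keeps effect sizes comparable across tables); modulation-index
values are natural-log scaled first because they are strictly positive and
right-skewed.  The Q4 rule retains a channel only when it is in Q4 in both
conditions and a subject when at least one channel survives; composites
average over retained channels, a single retained channel contributing its
own value.  Topographic maps zero non-significant electrodes and rescale
significant ones to the percentage of the most significant statistic
(for signed-rank statistics smaller is more significant, so the score is
`critical − stat`; a flag handles larger-is-significant statistics).

## Cohort pipeline defaults

`analyze_cohort` demeans each channel and computes metrics directly,
without common-average re-referencing or the 0.5 Hz high-pass: synthetic
recordings are drift-free, and an average reference over the two synthetic
channels would subtract half of each channel from the other.  Both steps
remain available in `preprocess` for real multichannel EEG and are tested
independently.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted bands: the null-calibration study uses
cohorts of 15 paired subjects with 30 s recordings (null rejection does not
depend on duration; 800 replicates in the test suite, 200 in the
acceptance script), the power study 100 cohorts at the full 180 s, the MI
oracle 10⁶ samples (binning error ≪ 10⁻³), and the spectral-slope check
2¹⁶ samples.  Symmetric-null thresholds (shape ratios < 0.02, uncoupled
MI < 0.01) reflect the residual sampling asymmetry of a finite noiseless
record; exact identities (MI of a uniform profile = 0, envelope ratio
(1−m)/(1+m)) are asserted to machine precision.

## Limitations

The generator is phenomenological: no volume conduction, no ocular or
muscle artifact realism (artifacts are generic broadband bursts), one
oscillation per recording (a mu/alpha component is added manually where
needed), stationary shape parameters, and a sinusoidal gamma carrier rather
than broadband high-frequency activity.  Passing tests therefore establish
correctness of the measurement chain and the statistical layer under known
ground truth — not that the metrics behave identically on clinical EEG.
EDF export requires the optional `edfio` backend; the plain TSV+JSON format
is the primary on-disk representation.
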