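# Methods

## The estimator

Sample entropy of a window `x(1..N)` with embedding dimension `m` and
tolerance `t` is `−ln(A/B)`, where `B` is the number of unordered pairs of
length-`m` templates (starting points `i = 1..N−m`, the same template set
for both lengths) whose Chebyshev distance is at most `t`, self-matches
excluded, and `A` is the analogous count for length `m+1`. Natural
logarithm throughout, so values are in nats.

Fixed sample entropy differs from classical SampEn only in how `t` is set:
instead of `r · SD(window)`, the tolerance is `r · SD_ref` with a single
reference SD per subject (or cohort) and signal group, held constant across
every window, signal and recording condition. This single change makes the
statistic amplitude-sensitive: with a fixed yardstick, louder windows have
fewer template matches and higher entropy. Because cardiac transients are
highly self-similar, their contribution to the match counts is much less
amplitude-dependent than that of the stochastic EMG/MMG interference
pattern, which is what buys the cardiac robustness.

Degenerate windows are handled explicitly and deterministically:

- `B = 0` (no matches even at length `m`): the value is undefined; the
  estimator returns NaN with a warning, and downstream cross-covariance
  drops such windows pairwise per lag.
- `A = 0, B > 0`: the value is capped at `−ln(1/B) = ln B`, the largest
  entropy expressible with `B` denominator pairs, and flagged. This keeps
  the series numerically usable for correlation scoring.

These conventions are this implementation's declared choice; how undefined
windows were treated on the original recordings is not documented anywhere
we could follow.

The moving-window form uses `N = round(window_length_s · fs)` samples per
window and a hop of `max(1, round((1 − overlap) · N))` samples; the
trailing partial window is dropped, and timestamps are window centers.
Windows below 200 samples trigger a warning (not an error), following the
published minimum-length recommendation for this estimator family.

Implementation note: the pairwise Chebyshev template distances of a window
are computed once and compared against any number of tolerances by sorted
search, so evaluating the 12 × 2 tolerance grid costs barely more than a
single tolerance. The kernel is validated to 1e−12 against a naive
pair-counting oracle.

## Signal conditioning

EMG channels (oesophageal and surface): resample to 2000 Hz (polyphase,
rational ratio), 8th-order zero-phase Butterworth band-pass 10–600 Hz,
then a comb of second-order notches with 2 Hz bandwidth at 50 Hz and every
harmonic up to 1000 Hz. Recordings with known interference lines (the COPD
montage) additionally get 10th-order zero-phase band-stop filters at 64
and 192.5 Hz. MMG axes: resample to 500 Hz, band-pass 5–40 Hz, then the
per-sample Euclidean norm of the three axes of each accelerometer —
filtering strictly before the norm, since the norm is nonlinear.

"Nth-order zero-phase" is read as a designed Nth-order filter applied
forward–backward (the magnitude response is therefore effectively
2N-order). The alternative reading — the stated order already counting the
doubled response — is available via `order_is_effective`. All zero-phase
stages use reflective (odd) padding sized at ten time constants of the
narrowest spectral feature (band edge or notch bandwidth), which keeps
edge windows usable and makes the filters commute with time reversal to
~1e−9.

## Segmentation and tolerance calibration

Breath phases come from zero crossings of mouth pressure, with sub-sample
boundary timing by linear interpolation. Phases shorter than 0.5 s are
treated as spurious sign flips and absorbed into the preceding phase (the
two boundaries around the short phase are deleted, preserving label
alternation and the phase count); edge partials below the threshold are
dropped. Inspiration is the negative-pressure phase by default
(threshold-loaded inspiration pulls mouth pressure negative); the polarity
is configurable. Breath cycles can be excluded by index; exclusions
propagate to both SD calibration and evaluation (excluded spans are masked
out of the entropy series before scoring).

The reference SD of a signal group (oesEMGdi: the five oesophageal pairs;
sEMG: parasternal + lower-intercostal surface EMG; |sMMG|: the
accelerometer norms) is computed per subject by concatenating every kept
inspiratory sample of a channel across all conditions, taking one
population SD (ddof = 0 — fixed for bit-reproducibility; with thousands of
samples the ddof choice is immaterial), and averaging across the group's
channels. Cohort-level "global" SDs are the arithmetic mean of the
per-subject individual SDs. Excluded cycles are removed from the SD as
well as from evaluation; whether the original analysis did both is not
documented, so this implementation picks the stricter option.

## Scoring and the parameter grid

An fSampEn series is scored against a pressure signal by the maximum
normalized cross-covariance `c_max`: the pressure is oriented
effort-positive (mouth pressure negated; transdiaphragmatic pressure kept),
linearly interpolated onto the entropy timestamps (the coarser grid, so no
entropy values are invented), both series mean-removed, and the Pearson
correlation evaluated at every integer-step lag within ±5 s, nearest lags
first so ties at one breathing period resolve to the smallest |lag|.
Normalization puts values in [−1, 1] and makes them comparable across
subjects of very different signal amplitude, which is why it was chosen
over raw covariance (available behind `normalized=False`). The ±5 s bound
is a physiological-scale guard; on strictly periodic synthetic records a
multiple of the breathing period can still edge out lag 0 by noise, which
affects the reported lag but not `c_max`.

The grid spans window lengths 0.1–0.5 s in 0.05 s steps, tolerance
multipliers r = 0.05–0.6 in 0.05 steps, and individual vs global SD, with
m = 2 and 90 % overlap; per subject this is 14,256 entropy series for the
healthy montage (11 signals × 6 conditions × 9 × 12 × 2) and 5,184 for the
COPD montage (4 signals). c_max is averaged, unweighted, over a group's
member signals and over conditions; cohort matrices are elementwise means
over subjects with argmaxes recomputed on the mean. Argmax ties break
toward smaller r, then smaller window. The cost of cohort-global
parameters for a subject is `Δc_max = 100 · |c_glob − c_ind| / c_ind`,
with `c_ind` the subject's best c_max over r at the fixed window
(individual SD) and `c_glob` the value at the cohort-global r (global SD).

## The synthetic generator

No public recordings exist for this protocol, so every stage is exercised
on seeded synthetic subjects built to have the statistical structure the
method assumes — not detailed physiology:

- **Pressures.** Each condition (quiet rest, then loads at 12/24/36/48/60 %
  of a 100 cmH2O reference maximal inspiratory pressure) is a train of
  breaths: a negative inspiratory half-sine with peak proportional to the
  load fraction (5 % at rest), a small positive expiratory rebound (15 % of
  the inspiratory peak — gives the zero crossings the segmenter needs),
  plus white measurement noise (0.1 cmH2O SD). Default timing 1.2 s
  inspiration / 1.8 s expiration (free breathing, ~20 breaths/min), up to
  30 breaths per condition. Oesophageal pressure mirrors the negated
  effort; gastric pressure adds an independent slowly-modulated
  diaphragm-weighted component, so P_mo and P_di correlate differently.
- **Muscle activity.** Band-limited Gaussian noise (10–600 Hz EMG at the
  4000 Hz acquisition rate, 5–40 Hz MMG at 2000 Hz) multiplied per sample
  by the rectified inspiratory effort envelope, normalized by the
  heaviest-load amplitude so the load-dependent amplitude ratios survive,
  plus a 5 % tonic noise floor. Channel gains are spread lognormally
  (σ = 0.15) around the nominal group scales (0.0121 V, 0.0022 V, 0.0060 g
  split across MMG axes) and calibrated so the concatenated-inspiratory SD
  lands near the nominal scale.
- **Cardiac noise.** A transient train at 75 bpm with 20 ms timing jitter:
  biphasic ~80 ms spikes on EMG channels, damped ~250 ms 18 Hz
  oscillations on MMG axes, peak amplitude 3× the channel's
  resting-breathing SD — cardiac activity dominates the quiet baseline, as
  it does in real surface recordings.

What the generator does *not* emulate: motor-unit structure, non-Gaussian
EMG statistics, electrode artifacts, movement artifacts, powerline
interference (the comb filter is validated on pure tones instead), or
inter-subject variability in breathing pattern. Tests passing on this
surrogate therefore demonstrate the pipeline's correctness and the
estimator's cardiac robustness under the assumed generative model, not
clinical performance on human data.

## Scaled-down problem sizes

The test suite and the acceptance script run reduced versions of the full
protocol, chosen once as the smallest sizes with stable statistics:
subjects use 2 loads + rest and 3–6 breaths per condition; the cohort
parameter-recovery run uses 3 subjects, the accelerometer-norm group, the
full 9-point window axis and r ∈ {0.2, 0.4}. Breath timing is kept at the
default 1.2/1.8 s: with much shorter breaths the 0.5 s window smooths the
inspiratory bump enough that the 0.45 s and 0.5 s cells of the cohort-mean
c_max matrix tie within seed noise, whereas at free-breathing timing the
0.5 s optimum is stable across seeds. Grid cardinalities are verified by
enumeration (combinatorics, not compute). The cardiac-robustness check
compares fSampEn (general surface-EMG parameters) with a same-windowed RMS
on one ~15 s loaded-breathing channel with and without the spike train.

## Known limitations

- The entropy kernel is O(N²) per window in time and memory; at the 2000 Hz
  EMG rate a full-grid evaluation of a long recording is minutes per
  subject, not seconds. Distances are shared across the tolerance axis but
  not across overlapping windows.
- Exclusion masking drops entropy windows inside excluded cycles; the lag
  scan then correlates only co-valid pairs, which slightly reduces the
  effective n at large lags.
- File I/O covers the package's own delimited-text format only; recordings
  in vendor formats must be exported to it first.
- Raw (unnormalized) cross-covariance is implemented but untested against
  any reference, since all shipped analyses use the normalized form.
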