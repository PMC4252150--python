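# Methods

`swayrqa` analyses force-plate centre-of-pressure (CoP) recordings to ask
whether the way a person controls quiet standing predicts how strongly they
experience visually induced illusions of self-motion (vection). This note
documents the measures, the preprocessing chain, the synthetic-data model,
and the numerical choices, in enough detail to reproduce or audit any
number the package emits.

## Signals and conventions

A CoP trace is a uniformly sampled two-channel series: anterior-posterior
(AP, forward positive) and medial-lateral (ML, rightward positive)
position in millimetres, at a nominal 1000 Hz. Forward-positive AP is the
single internal convention; exports using the plotting convention
(negative = forward) are flipped at read time via the manifest flag
`ap_forward_sign: -1`, never downstream. Sampling must be uniform to
1 ns per step; resampling is deliberately unsupported (hardware-clocked
plates do not need it, and silently repairing gaps would be worse than
failing).

## Preprocessing

1. **Zero-phase Butterworth low-pass**, order 5, default cutoff 10 Hz,
   applied forward-backward (`sosfiltfilt`) to each channel. Quiet-stance
   CoP energy sits below a few Hz, so a 10 Hz cutoff removes measurement
   noise while leaving sway intact; zero-phase application preserves the
   temporal alignment of stimulus blocks (no group delay). The effective
   magnitude response is the squared Butterworth response, which the test
   suite checks analytically. The cutoff is configurable and recorded in
   every run report.
2. **Boxcar reduction** (recurrence branch only): non-overlapping means of
   10 consecutive samples, 1000 Hz → 100 Hz. Non-overlapping windows are
   true downsampling, so the embedding delay of 15 samples spans 150 ms at
   the reduced rate. A trailing remainder shorter than one window is
   discarded (and logged), never padded. A same-rate `moving` mode exists
   for diagnostics only.
3. **Segmentation**: block schedules (e.g. 30 s blank / 30 s flow / 30 s
   blank / 30 s fixation, repeated three times) are cut at
   `round(cumulative duration x rate)`, so segments tile the covered range
   with no gap or overlap.

Linear measures are computed on the filtered, full-rate trace (path length
is defined on the recorded CoP; reduction would shorten paths). Recurrence
measures are computed on the filtered-then-reduced AP series.

## Linear sway measures

* **Path length**: summed Euclidean inter-sample distances over both
  channels; translation-invariant, scales linearly with the trace.
* **Sway area**: area of the 95% prediction ellipse from the
  eigen-decomposition of the sample AP/ML covariance (n−1 denominator).
  Semi-axes are `sqrt(q * lambda_k)` with `q` the chi-square(2 dof)
  quantile at the coverage level (5.991 at 0.95), so
  `area = pi * q * sqrt(lambda1 * lambda2)`. A small-sample variant using
  `q = 2 (n-1)/(n-2) F_{0.95; 2, n-2}` is available behind a flag; at the
  60 000-sample scale of a 60 s trace the two are indistinguishable.
  Constant or collinear point clouds (covariance condition number above
  1e10) raise a degenerate-geometry error rather than returning a zero
  area.
* **Romberg ratio**: eyes-closed path over eyes-open path.
* **Sway-area ratio**: reported as the natural log of eyes-open over
  eyes-closed area, so equal areas give 0 and swapping conditions flips the
  sign. The log base only rescales correlations; natural log is used
  throughout.

## Recurrence quantification analysis

The scalar AP series is embedded by time delay: state
`v_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})`, giving
`N - (m-1) tau` states. Two states are recurrent when their distance is at
most the radius (boundary inclusive); the symmetric binary matrix of all
such pairs is summarised as:

* **RR** — `sum(R) / N^2`, the probability that any state recurs. The
  identity line is *included* when no Theiler window is set: this matches
  the plain density definition, and the default `theiler = 0` preserves
  it. A Theiler band (`|i-j| <= w` forced to zero) is available for users
  who want temporally adjacent states excluded.
* **DET** — fraction of off-identity recurrent points on diagonal lines of
  length ≥ `lmin`; **L** and **ENTR** — mean length and Shannon entropy
  (nats) of the diagonal line-length distribution at ≥ `lmin`.
* **LAM** and **TT** — the vertical-line analogues, with the denominator
  taken over all recurrent points counted down columns.
* **trend** — least-squares slope of per-diagonal recurrence density
  against distance from the identity line, fitted over diagonals up to
  90% of the matrix size (the corner-most diagonals carry too few points
  for a stable density estimate). Non-stationarity (drift) shows up as a
  negative trend.

Defaults are m=8, tau=15, radius=30 in absolute signal units, lmin=4,
Euclidean norm — the standard configuration for 60 s quiet-stance series
reduced to 100 Hz. A `fraction_of_mean_distance` radius mode and the
maximum norm are available; the mode used is recorded in output metadata.
Line histograms count both triangles of the symmetric matrix, consistent
with denominators that sum the full matrix; the identity line is always
excluded from the diagonal histogram. When no line reaches `lmin`, the
dependent measures are **NaN, never zero** — a matrix with no diagonal
structure has undefined mean line length, not a zero one (note this makes
DET/ENTR comparisons against structure-free shuffles meaningful only when
the shuffle retains some lines; the tests account for this).

The whole recurrence layer (embedding, matrix, histograms, measures) is
implemented in this package; SciPy supplies pairwise distances and the
k-d tree behind the fast recurrence-rate counter, which counts recurrent
pairs without materialising the N x N matrix and agrees exactly with the
matrix route (pinned by tests). The headline comparative statistic is the
**recurrence-rate difference**, eyes-open minus eyes-closed, computed only
between results with identical parameters.

## VEPRs and vection metrics

The visually-evoked postural response of a flow session is, for each flow
block, the mean AP position during the block minus the mean during the
block immediately preceding it (the whole preceding block; this controls
for slow postural drift), averaged over the three repeats and kept signed
(forward positive). Reports print direction words ("forward"/"backward")
alongside the sign.

Vection trials yield the throttle maximum (percent), the latency (first
time the throttle reaches 5%, a missing value — not an error — if it never
does), and the end-of-trial verbal rating. Per-subject summaries average
over trials; latencies average only over trials that crossed the cutoff,
with the missing count reported. Missing latencies propagate as NaN and
are deleted pairwise in correlations, never imputed.

## Statistics

Pearson correlations use pairwise-complete observations, with the
two-sided p from the t transform on n−2 degrees of freedom; paired
comparisons use the paired t-test (n−1 df). No multiple-comparison
adjustment is applied — the run report records the number of tests so
users can apply their own. Correlations can optionally be computed on
|feature| (`magnitude` mode), relevant for VEPRs whose expanding-flow
means sit near zero.

## Synthetic cohorts

The generator produces data with the statistical structure the analysis
assumes; it is explicitly *not* a biomechanical simulation. One latent
scalar per subject — visual dependence `v ~ Uniform(0, 1)` — drives every
condition contrast:

* Baseline sway on each axis is the exact AR(1) discretisation of an
  Ornstein-Uhlenbeck process with reversion time 1 s, which keeps 60 s
  traces stationary enough for recurrence analysis (a bounded drift-free
  process, unlike a random walk). The base scale is 7.5 mm stationary
  standard deviation; ML runs at 0.6 times the AP scale.
* Eyes-open AP scale is `7.5 * (0.65 + 0.85 v)` mm plus a slow sinusoid
  (0.3 Hz, amplitude `3 (1 - v)` mm); eyes-closed scale is a fixed
  `7.5 * 1.6` mm — above the eyes-open scale for every subject, so
  eyes-closed paths always exceed eyes-open paths. Under an absolute
  recurrence radius, larger sway is less recurrent; this single lever
  therefore makes eyes-open RR (and the open-minus-closed RR difference)
  decrease in `v`, leaves eyes-closed RR nearly flat, and makes the
  open/closed sway-area ratio grow with `v` — the qualitative pattern the
  analysis is designed to detect. An earlier design that reshaped the
  eyes-open signal at fixed variance (power reallocated into the sinusoid)
  produced recurrence effects an order of magnitude weaker than
  between-subject realisation noise and was discarded.
* Flow sessions shift the AP mean during flow blocks by `-gain * v`
  (expanding: backward) or `+7 * gain * v` (contracting: forward), gain
  2.5 mm, mirroring the forward/backward asymmetry of real responses.
* Verbal ratings rise linearly with `v` (baselines 15% expanding / 38%
  contracting, slope 45 percentage points over the `v` range, clipped to
  [0, 100]); the throttle rises sigmoidally towards a plateau below 0.85
  times the trial's verbal rating, scaled by a per-subject "usage" factor
  (subjects differ in how much of the throttle range they use), with onset
  earlier for high-`v` subjects — so latency falls with `v`, throttle and
  verbal measures correlate strongly without being collinear, and the
  throttle maximum never exceeds its verbal-linked ceiling.
* The cohort parameter `coupling` targets the correlation between the
  RR difference and mean verbal vection (the headline statistic). Its
  magnitude sets the between-subject rating noise
  (`sd = signal_sd * sqrt(1/rho^2 - 1)`); because the RR difference
  decreases in `v` by construction, negative coupling (the default, −0.7)
  corresponds to ratings increasing in `v`. Trial-to-trial verbal noise is
  a separate parameter (default sd 8 percentage points).

Every output is a pure function of parameters and seed; per-subject seeds
are spawned from the cohort master seed, and the on-disk cohort writer
records all of them, so a dataset is regenerable bit-exactly.

What the generator does *not* emulate: non-stationary drift and fatigue
across a session, the heavy-tailed and multi-timescale structure of real
CoP (rambling/trembling decomposition, long-range correlations), foot
geometry and biomechanics, adaptation across vection trials, and
measurement artefacts. Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind it assumes*, at realistic
magnitudes and sample sizes — not that real recordings satisfy those
assumptions.

## Problem sizes in tests and reports

Unit tests run on shortened traces (a few seconds) with the same machinery;
the acceptance-level checks run the full study scale: 60 s quiet stance at
1000 Hz, 30 s blocks, 13-subject cohorts for reported group statistics,
n=20 for direction contrasts, and 20 replicate n=50 cohorts for coupling
recovery. The oracle-equivalence checks use up to 500 embedded states,
where exhaustive pairwise reference implementations are cheap.

## Known limitations

* The recurrence radius is absolute by default; analyses of signals on
  different scales need the fractional mode or explicit rescaling.
* The Butterworth cutoff for published CoP datasets varies between labs;
  results depend on it at the few-percent level, so it is always logged.
* `trend` has several in-use definitions differing in the diagonal range
  and scaling; values are comparable within this package, not necessarily
  across toolboxes.
* The correlation layer reports raw p-values by design; with a dozen or
  more tests per table, users should apply their own multiplicity control.
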