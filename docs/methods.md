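# Methods

This note records the models, conventions and design choices behind
`rehabsense`, and what the synthetic tests do and do not establish about
real recordings.

## Movement velocity biomarker

Position streams from the head-mounted display and the two hand
controllers arrive as (t, x, y, z) samples at a nominal 30 Hz, grouped
into segments by the VR software's metadata tags. Speed between
consecutive samples is `sqrt(Δx² + Δy² + Δz²)/Δt`; a segment's biomarker
value is the arithmetic mean of its point speeds.

Conventions and guards:

* **Gap threshold** (default 0.5 s, ~15 nominal sample intervals): sample
  pairs further apart are treated as recording gaps — segments sometimes
  end abnormally (headset powered off mid-task) and one huge Δt would
  otherwise poison a segment mean. Skips are counted, never silent.
* **Velocity cap** (off by default, 10 m/s suggested): an optional guard
  against non-natural artifacts such as a dropped controller. The cap is
  configuration because no principled threshold exists; drops are counted.
* **Context classification**: a segment is *action* if its metadata tag is
  in the configured action-tag map (tags may carry a `:n` sequence
  suffix; the base before the colon is matched too). No-action segments
  before a day's first action segment are *start of day*, after the last
  *end of day*, otherwise *between*. Comparing action vs no-action speed
  distributions is the validity check on the segmentation itself.
* **Trend fit**: ordinary least squares of action-segment mean velocity on
  the 1-based VR study-day ordinal, one observation per segment. Study
  days can span multiple calendar days, so the ordinal — not calendar
  time — is the regressor, and the slope is a proxy for progression
  rather than a daily rate. The fit is deliberately unweighted and
  linear: the point is a single interpretable direction-of-change
  measure, not an optimal curve. The *change estimate* is slope ×
  (count of VR study days with data), in m/s over the study.

## Endpoint correlation

The per-sensor change estimates are correlated across participants with
the clinical endpoint changes (TSK, EQ-5D VAS, EQ-5D-5L index; end of
treatment minus baseline). Both Pearson and Spearman coefficients are
computed — with a dozen participants one observation can swing the
parametric value, so the rank version is the robustness companion.
Spearman is Pearson on midranks (average ranks for ties). Rows with any
missing value among the six variables are dropped listwise. Robustness to
the one participant with ~2/3 of study days missing is assessed by
computing every matrix with and without that row; the packaged reference
table carries a `short_participation` flag rather than a hard-coded
exclusion, and exclusion happens at analysis time.

Matrices are reported at 2 decimals (full precision kept internally).
Note that the packaged change table itself is printed at 3 decimals,
which ties two head-sensor values that were distinct in the unrounded
data; rank-based cells recomputed from the table can therefore differ
from values computed on unrounded data by up to ~0.02.

## Electrodermal phasic peaks

Skin conductance mixes a slow tonic drift with fast phasic responses.
First differencing (Δᵢ = xᵢ − xᵢ₋₁) removes the tonic component exactly
for constant and linear drifts (a constant offset vanishes; a linear
trend becomes a constant shift of Δ, which moves the band and the signal
together). Peaks are Δ strictly above `median(Δ) + 2·MAD(Δ)`.

Choices, where the convention was genuinely open:

* **Median-anchored band.** "Two MADs above the median" and "above
  2·MAD" differ when the Δ distribution is asymmetric; the median-anchored
  band is the robust-outlier convention and the default, with the
  zero-anchored variant available as `band="zero"`.
* **Band per segment**, not per day or participant: the peak count is a
  per-segment statistic, so the band uses that segment's own Δ.
* **Strict inequality, upper side only**; a MAD of zero (quantized flat
  signal) collapses the band to the bare median and is flagged
  `degenerate_band` rather than silently counted.
* **Duration from timestamps**, not sample count × nominal rate, so
  dropped samples do not bias peaks/minute.
* **Start-of-day filter**: treatment-arm segments before the day's first
  task are removed so the active phase is compared against comparator-arm
  data, which is all no-task by design.

A property worth knowing: the band is *relative*. On a signal whose
differences are approximately Gaussian noise, about 9% of samples exceed
median + 2·MAD regardless of the noise scale, so peaks/minute on a
noise-dominated recording reflects the sampling rate more than phasic
activity. This is inherent to a robust relative band and is why the
detector-recovery tests use a clean-pulse configuration (tonic and noise
off); on realistic noisy segments the statistic separates arms only
through the *difference* in pulse activity, and weakly.

## Activity trends

Weeks count from randomization (`week = ceil(study_day/7)`), keeping arms
aligned on study time; week means use only the days present, and the
week-1 mean is each participant's baseline (week-1 change is 0 by
construction). The trend model is two-stage — per-participant OLS of
steps on study day, then per-arm mean/SD of slopes and pairwise arm
differences. A mixed-effects fit would pool information across
participants, but the two-stage form is fully specified, keeps each
participant's own regression line, and is directly testable; it is a
stand-in, and reported as such. Heart rate and sleep are summarized
descriptively only: daily aggregates carry too little precision for more.

## Synthetic cohort generator

The generator exists to make every stage testable with known ground
truth, not to be biomechanically or physiologically realistic.

* **Motion**: participant p has latent daily mean velocity
  `v(p,s,d) = v0(s) + β(p)·d` with `β(p) ~ Normal(0.003, 0.001)` m/s per
  day shared across sensors; sensor baselines 0.10/0.20/0.22 m/s
  (head/left/right). Task segments move around `ratio·v0(s) + β(p)·d`
  (ratio 2.0): faster task movement, same improvement trend, so the
  action-only fit recovers β itself. Segment targets get Normal(0, 0.03)
  m/s segment-to-segment noise; trajectories are random walks whose
  per-step displacement is `speed·dt` in a uniform random 3-D direction,
  per-step speed = target × unit-mean gamma jitter (CV 0.3) — only speed
  statistics matter downstream, so no explicit kinematics. With all noise
  terms zero, fitted slope = β exactly.
* **Clinical link**: the standardized latent movement change z(p) is mixed
  as `ρ·z + sqrt(1−ρ²)·ε`, scaled and shifted per endpoint (TSK −6 ± 4,
  VAS +20 ± 25, EQ-5D −2 ± 2.5, signs matching the improvement
  directions), and rounded to the endpoints' integer scales. ρ
  (`clinical_link_strength`, default 0.6) is the dial whose recovery
  validates the correlation stage.
* **EDA**: baseline 1 µS + tonic sinusoid (amplitude 0.1 µS, period 60 s)
  + Poisson pulses (instant rise, exponential decay τ = 2 s, amplitude
  0.5 µS, default 3/min treatment vs 1/min comparator) + white noise
  (0.02 µS).
* **Activity**: steps = 5000 + weekly_trend/7 × (day−1) + Normal(0, 500),
  truncated at zero; default trend +200 steps/week in the treatment arm,
  flat elsewhere.

All generators are deterministic under a fixed seed, drawing from
independent child streams so each can be called alone.

**Problem sizes.** The default spec mirrors the study conditions: 12
treatment-arm participants, 30 study days, 10 action + 3 no-action
segments/day, 60 s segments at 30 Hz (plus 17 comparator and 10
standard-care participants for EDA/activity). Replicated Monte-Carlo
analyses (slope bias over 200 replicates, clinical link at n = 50,
step-trend recovery) run on reduced segment counts, durations and
sampling rates (e.g. 4 action segments/day, 3 s segments at 10 Hz, head
sensor only) — the quantities being recovered do not depend on
within-segment sample volume, and these sizes keep the full suite
seconds-to-minutes scale.

**What passing tests do not show.** The generator's trajectories share
none of the kinematic structure of real task movement (no posture, no
task repetition, no autocorrelated speed), its EDA has no skin-physiology
model (no temperature/humidity dependence, no sympathetic coupling), and
its noise is stationary Gaussian. Recovery results validate the
*pipeline's arithmetic and statistical behavior* under the assumed data
model, not the biomarker's clinical validity.

## Known limitations

* The linear trend is a crude summary of within-study progression;
  different phases of change are invisible to it.
* The record-stream schema is this package's own; the original trial's
  export format was not published.
* Correlations come with no p-values or intervals, matching the
  exploratory design; n = 11–12 supports direction and rough magnitude,
  nothing more.
* Peaks/minute on noisy electrodermal data is dominated by the relative
  band's false-positive floor (see above); arm comparisons should rest on
  distributional differences, not absolute rates.
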