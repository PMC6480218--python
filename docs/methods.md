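# Methods

## Signal model and assumptions

The analysis assumes a single IMU on the lower back (≈ L3–L4) whose onboard
fusion delivers orientation at 100 Hz; the package never re-fuses raw
inertial data. Two assumptions carry the whole method:

1. Rising from and lowering into a chair produce a forward trunk-lean bump
   in the sagittal inclination (pitch), visible even in subjects with
   reduced mobility, and these are the two largest pitch excursions in a
   TUG recording.
2. Each of the two turns rotates the transverse-plane heading (yaw) by
   roughly 180°, so the heading is a two-step staircase whose transitions
   are the turns.

Recordings with irregular timestamps are linearly resampled to the
configured rate (default 100 Hz) before any processing, because the stride
and window lengths of the detectors are defined in sample counts at 100 Hz.
All timestamps are seconds from recording start, intervals are closed, and
event times snap to the sample grid (so JSON reports, which round times to
3 decimals, are exact).

## Conditioning

Pitch: zero-reference (subtract the median of the first 0.5 s of quiet
sitting) → causal forward moving average of order N = 5 (the final N − 1
samples use a shrinking tail window so output length equals input length)
→ normalize by the absolute maximum.

Yaw: unwrap across the ±180° seam → zero-reference → orient so the largest
excursion is positive (subjects may turn either way; the detector assumes
the first turn is a positive rotation; a flip is recorded as a flag) →
moving average → normalize.

Zero-referencing precedes normalization deliberately: a constant mounting
offset (e.g. a 15° resting pitch) would otherwise dominate the absolute
maximum and crush the stand/sit excursions that the 0.05 threshold below
must resolve.

## Detectors

**Stand/sit.** The two most prominent local maxima of the normalized pitch
at least `peak_min_separation` (3 s) apart are the stand and sit peaks.
Prominence, not raw height, ranks candidates, rejecting gait oscillations;
peaks need a normalized prominence ≥ 0.1 to qualify. From each peak the
bounds are found by walking outward in `slope_stride` = 0.1-s steps until
the absolute difference between samples 0.1 s apart drops below
`slope_stop_threshold` = 0.05 — i.e. until the slope flattens to under
0.5 normalized units/s. Bounds clamp to the recording edges with a flag.
On bumps shallower than the threshold the walk stops at the first stride
and the bound collapses toward the peak; the event is then widened by one
sample and flagged rather than rejected.

**Turns.** The normalized yaw rate (central differences) attains its
maximum at the 3-m turn and its minimum at the pre-sitting turn; the
maximum must precede the minimum or detection fails with "turn order
violated". A 10-sample window slides outward from each extremum one sample
per step: a turn starts where the window mean reaches the flanking low
plateau (≤ `turn_low_level` = 0.02) and ends where it reaches the high
plateau (≥ `turn_high_level` = 0.9); mirrored for the descending turn. The
fixed levels presuppose plateaus at 0 and 1, which holds when the two
turns rotate in opposite directions. For same-direction turners (heading
0 → 180 → 360, plateau between turns at 0.5 after normalization) the
`robust_turns` mode instead locates the two largest disjoint rate
excursions and rescales the 2% / 90% levels to the span between each
turn's own flanking plateaus.

The rotation span of each detected turn, measured on the unwrapped
un-normalized heading, should be ≈180°; values outside (90°, 270°) are
flagged, not rejected, since pathological gait can produce legitimate
partial turns.

**Assembly.** The six sub-tasks tile the recording: walks are the spans
between consecutive events. Adjacent events overlapping by ≤ 0.2 s are
snapped to the midpoint with a flag; larger overlaps are an error. Any gap
between the pre-sitting turn's end and sitting's start is kept as a
labeled "pre-sit stance" rather than forced shut, because the two
detectors bound those events independently; total time runs from standing
start to sitting end and is unaffected.

**Features.** Step counting subtracts the segment median (gravity) from
the vertical acceleration and counts peaks with prominence ≥ 1 m/s²
separated by ≥ 0.3 s — a conservative cadence ceiling of ~3.3 steps/s.
Turn rates use the transverse gyroscope channel when present, otherwise
the differentiated unwrapped yaw (flagged). Missing channels make the
dependent features absent, never zero.

**Risk.** The category is a step function of total time with configurable
cutoffs, default 10 s and 20 s (no / low / high). The cutoffs are
deliberately configurable: published bands differ between health systems
and are sometimes age-adjusted, and the reference cohort contains one
subject (9.33 s video, labeled low-risk) inconsistent with any pure 10-s
cutoff.

## Synthetic generator

`simulate` builds a 100-Hz recording from a `TugScenario`: triangular pitch
bumps spanning exactly the standing and sitting intervals (triangles keep
the per-stride slope constant at 2·amplitude/duration, so the slope-stop
criterion fires at the bump edge, and make peak and edges exactly known);
cubic smoothstep heading transitions on the inner 90% of each labeled turn
interval (finite support makes true start/end exact; zero-slope ends keep
the window criteria inside the labeled interval); raised-cosine step
oscillations at the cadence inside walking/turn segments; raised-cosine
acceleration transients at stand/sit; the analytic heading derivative on
the transverse gyro channel; white Gaussian noise on everything, one seed
for the whole sample path.

Default noise is 0.1° SD on angles. This models the sample-to-sample
jitter of Kalman-fused orientation at rest, which is far below the ±1°
static accuracy of such sensors; fused orientation noise is low-pass and
small because the accelerometer anchors the attitude. The white-noise
model has no drift or motion-dependent artifacts, which real fused
orientation does show during fast turns — closure results on synthetic
data therefore bound the algorithmic error of the detectors, not the
sensor error of a field recording.

`random_scenario` draws sub-task durations, amplitudes, turn angle and
cadence from truncated normals matching the two validation cohorts
(young: e.g. standing 1.16 ± 0.15 s, first walk 2.51 ± 0.35 s; older:
1.41 ± 0.71 s, 3.49 ± 3.26 s). Young durations truncate at ±2σ
(symmetric, preserving the cohort means); older durations truncate at
physiological floors because the printed SDs exceed some means. Stand and
sit pitch amplitudes are drawn as one per-subject trunk-flexion magnitude
times phase factors (ratio ≈ 0.85 ± 0.1) rather than independently: the
joint normalization means a bump with normalized amplitude ≪ 1 falls
below the fixed 0.05 slope threshold and its bounds provably collapse to
the peak, and cohort tables show the two excursions tightly coupled
within subjects (5.35 ± 1.89° vs 6.25 ± 1.82° in the young cohort).

## Numerical choices and known limitations

- The slope-walk iterator advances in 0.1-s (10-sample) steps, reading the
  printed iterator "i = 0, 0.1, 0.2, …" as seconds; the window slide for
  turns advances 1 sample per step ("i = 0, 0.01, …"). Bound times
  therefore quantize to 0.1 s (posture) and 0.01 s (turns).
- The 0.9-level turn bounds carry a structural offset: any smooth
  monotone transition crosses 90% of its span strictly inside itself (for
  a smoothstep, at ~80% of the span), so the 3-m turn's detected end and
  the pre-sitting turn's detected start sit ~0.2 × duration inside the
  true interval even without noise. This inflates the apparent 3-m-turn
  duration and shortens the second walk by the same amount; boundary
  errors remain within ±0.5 s for turn durations up to ~2.3 s. The
  0.02-level bounds and the posture bounds are accurate to ~0.1–0.2 s.
- The fixed 0.05 slope threshold fails on normalized bump slopes below
  0.5/s (shallow or strongly unequal bumps): the bound collapses to the
  peak and is flagged. This is inherent to thresholding jointly-normalized
  signals, not repaired silently.
- Angle noise above ~0.5° SD (relative to ~5° bumps) makes the stride
  walk stop at random mid-flank points; the method presupposes the low
  noise of fused orientation, not raw gyro integration.
- Ties at exactly the window-mean stop level resolve by floating-point
  summation order (one sample at most).
- Measured at defaults over 100 seeded young scenarios: median absolute
  boundary error 0.07 s, maximum 0.45 s, no detection failures (recomputed
  by `scripts/acceptance.py` and the test suite; the benchmark example
  prints the per-boundary breakdown).

Problem sizes throughout (100-scenario batches, ~1200-sample recordings)
are the package's chosen benchmark scale; a batch runs in well under a
second.

## Validation statistics

`pearson` and `bland_altman` operate on the packaged per-subject cohort
tables (video total time as reference, IMU as test). Differences are
reference − test; limits of agreement are bias ± 1.96 × SD (n − 1). The
older-cohort correlation excludes the 43-s high-risk subject by default —
that leverage point alone would push r to 0.9997 and say nothing about
agreement in the clinical range — with inclusion available via the full
table. Risk concordance is integer-rounded percent agreement (11/12 →
92%). Against the printed 2-decimal tables the recomputed young-cohort
correlation is 0.977 and the bias 0.18 ± 0.19 s; the agreement statistics
a study computes from unrounded data can differ from table-derived values
by more than rounding alone when a table entry is itself in error, so the
package always reports what the shipped tables actually yield.
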