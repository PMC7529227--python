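# Methods

## The ε-regular graph transform

Given samples *p₁ … pₙ* and a threshold ε ≥ 0, vertex *i* and vertex *j*
(*i* ≠ *j*) are adjacent iff |*pᵢ* − *pⱼ*| ≤ ε.  The inequality is
inclusive: boundary ties are edges.  The graph is simple and undirected;
self-loops are excluded.  Comparisons use exact IEEE arithmetic on the
stored values with no tolerance — users who want fuzzier tie behaviour
should pre-round their data.

Because adjacency depends only on values, the transform is a unit
interval graph on the real line.  The implementation exploits this:
values are sorted once, each vertex's neighbourhood is a contiguous
sorted run found by bisection (with a local scan that repairs the rare
cases where the rounding of *v* ± ε disagrees with the defining
predicate), and connected components are maximal sorted runs whose
consecutive gaps are ≤ ε.  Degrees, edge counts, components and
complete-subgraph queries therefore cost O(n log n) and never
materialize the edge set, which for dense ε is Θ(n²); explicit edges are
only generated on demand for export.  A set of vertices is a complete
subgraph iff its value range is ≤ ε, so completeness checks are O(k).

Degrees are reported raw by default; normalization by *n* − 1 (degrees
on the unit interval) is an explicit option.  The early-warning pipeline
uses raw degrees throughout: against a 60-point window's ceiling of 59,
the magnitudes of the published difference-curve extrema (−2.12, 5.59)
are only consistent with unnormalized degrees.

## Visibility graphs (comparator)

The natural visibility graph joins (a, yₐ) and (b, y_b) iff every
intermediate sample lies strictly below the segment between them;
equality blocks (a collinear point obstructs), the standard convention.
Time stamps are the sample indices.  The construction sweeps rightward
from each vertex maintaining the running maximum slope — an edge exists
iff the slope to the candidate strictly exceeds every earlier slope —
which is O(n²) total; the test suite checks it against an independent
O(n³) all-intermediates oracle.  Consecutive samples always see each
other, so the graph contains the path on 1…n and is connected.
Visibility is invariant under positive affine maps of the values; the
ε-regular graph is not (its threshold is absolute), which is precisely
the quantitative/qualitative divide between the two transforms.

## Detrended fluctuation analysis (baseline)

First-order DFA: the mean-centred series is integrated into a profile;
for each box size *s* the profile is cut into ⌊N/s⌋ non-overlapping
boxes from the start (the tail remainder is discarded; a reversed-pass
option averages in boxes taken from the end instead), a least-squares
line is removed per box, and F(s) is the RMS residual over retained
points.  The default grid is ~20 approximately log-spaced integer sizes
in [4, N/4].  Natural logarithms are used for the fits; slopes are
base-invariant.  The exponent pair (α_short, α_long) comes from separate
OLS fits of log F vs log s on boxes ≤ 15 and > 15, the crossover
conventionally used for R-R series; each regime requires ≥ 2 sizes.
Constant input is rejected (F ≡ 0 has no log), as are box sizes below 4
or above N/2.

Calibration facts used in the tests: white noise has α ≈ 0.5 and
Brownian motion α ≈ 1.5 (its profile is doubly integrated noise).  The
*short-scale* slope of white noise under first-order DFA sits markedly
above 0.5 (≈ 0.63 at n = 10⁴) — the well-known small-box bias — so
calibration checks use the single overall slope, which lands within
±0.05 of 0.5; an exact power law F(s) = c·s^α is recovered to machine
precision.

## The early-warning pipeline

Inputs are paired records per subject: VT (the R-R series leading up to
a ventricular tachyarrhythmia, onset at the last sample) and CR (a
control recording from the same subject), plus optional healthy-subject
(HS) records.  Steps and defaults:

1. **Crop** VT/CR to the last 985 samples; HS records instead contribute
   a seeded uniformly-random contiguous 985-sample segment.
2. **Window** each record: length 60, stride 1 → 926 windows; window *i*
   (1-based) covers samples *i* … *i*+59, so window and sample indices
   coincide and a warning window is directly a position in the record.
3. **Transform** each window at ε = 0.04 s and record the raw mean
   degree.  0.04 s is about the mean absolute consecutive R-R gap of the
   clinical pre-VT records, i.e. the scale at which typical neighbouring
   values are "the same" to the graph.
4. **Average** curves within each group; **difference**: per subject
   pair VT − CR per window, then the mean over pairs (by linearity this
   equals the difference of group means; the identity is asserted in
   tests rather than relied on).  HS curves are reported but never enter
   detection.
5. **Detect**: the global minimum of the difference curve (first window
   on ties), then the first window *i* after it with y(i) > y(i−1) and
   y(i) ≥ y(i+1) — so the first index of a plateau after a rise counts —
   falling back to the final window if the curve never turns down.  An
   optional centred moving average can be applied first (default: none).
   The "first local maximum" rule is this package's construction; only
   its outcome, not the rule, is fixed by prior work.
6. **Lead time**: per VT record, the sum of R-R intervals from the
   warning window through the final sample inclusive; the inclusive
   convention is the one that reproduces the published 514.625 s mean on
   the clinical cohort.  The cross-subject mean is the headline number.
7. **ε sweep**: the difference curve recomputed at ε ∈ {0.01 … 0.06}
   by default, to show the warning location is threshold-stable.

R-R units are auto-detected per file (median > 10 ⇒ milliseconds,
divided by 1000) and overridable.  A sanity bound rejects intervals
≥ 5 s.  The pooled gap statistics (mean/min/max of |RR_{t+1} − RR_t|
across a cohort) support choosing ε; whether published gap statistics
pool consecutive differences or all pairs is ambiguous, and this package
documents and implements the pooled-consecutive reading.

## Synthetic cohorts: what they emulate and what they don't

The generator draws each R-R series as x_t = μ(t) + σ(t)·z_t with z_t a
stationary AR(1) process of unit marginal variance (coefficient 0.3 by
default), baseline μ = 0.8 s and σ = 0.03 s — a resting heart rate near
75 bpm with realistic short-range autocorrelation, so windowed degree
curves have window-to-window correlation as real HRV does.  Samples
≤ 0.2 s are redrawn (positivity).

The pre-event transition is modelled as a **transient**: from
`change_index`, a turbulence burst of `change_duration` samples (default
60 = one window) with σ scaled by `change_sd_scale` (default 3) and an
optional mean shift, followed by a stabilized phase with σ scaled by
`post_sd_scale` until the onset.  A *permanent* variance step was
rejected as the model: it makes the difference curve ramp down to a
noisy plateau whose argmin wanders over the entire post-change range, so
no change-point can be recovered from the minimum; a one-window burst
pins the minimum to the unique window fully inside the burst, and a
stabilized (post_sd_scale < 1) phase reproduces the characteristic
minimum-then-rebound shape of real pre-VT difference curves.  With
scale = 1, no shift and post scale = 1 the change is a no-op and VT ≡ CR
in distribution (the null case).

What the synthetic cohort does **not** emulate: inter-subject
heterogeneity of baseline rate and variability, ectopic beats and
artefacts, respiratory sinus arrhythmia and other oscillatory structure,
long-range (power-law) correlations, and the gradual, subject-specific
onset dynamics of real VT.  Passing the recovery test therefore shows
the pipeline localizes a known injected change under realistic noise and
autocorrelation — not that real pre-VT dynamics look like the injected
transient.  Synthetic difference-curve magnitudes (≈ −24/+17) are far
larger than the clinical ones (−2.12/+5.59) because every synthetic
subject carries an identical, aligned change while real subjects are
heterogeneous; locations, not magnitudes, are the tested quantity.

## Degree-distribution shape statistics

For 10⁴-sample series at ε ∈ {1, ½} (the unit standard deviation and
half of it): the normal series' normalized-degree distribution is
unimodal with its mode in the upper half of the support and a long left
tail — skewness robustly ≈ −1.1 — because degree is a monotone-decreasing
function of |value| and most mass sits near the centre.  The Brownian
series' degrees follow the path's occupation of ε-bands: broad, often
multimodal, closer to symmetric, with a support width relative to the
mean about twice the normal case's.  Claims about these shapes are
asserted in tests only as such reduced statistics (skewness sign and
ordering, relative width ordering); the distributions' family labels are
qualitative descriptions, not fitted models.

## Numerical and design choices

- **Windowed degrees** use a vectorized two-pointer sweep over
  bulk-sorted windows (O(m·w) amortized) that evaluates the literal
  |Δ| ≤ ε predicate, so pipeline curves agree bit-for-bit with
  per-window graph construction, boundary ties included.
- **Determinism**: every stochastic component takes a seed or NumPy
  Generator; a fixed cohort and seed give a bit-identical report.
- **Degenerate inputs** are errors, not silent results: constant curves
  for warning detection, constant series for DFA, normalized degree on a
  single vertex, empty cohorts, unpaired VT/CR subjects.
- **Problem sizes in the shipped tests**: the recovery study uses 81
  pairs × 985 samples × 20 seeded cohorts (≈ 1 minute); unit tests use
  cohorts of 4–12 pairs and series of 100–10⁴ samples, sized so the
  whole suite runs in about a minute while still exercising every stage
  at the full clinical geometry at least once.
- **Known limitations**: no streaming/real-time detection; no
  false-positive/false-negative protocol (none is defined for the
  retrospective design); WFDB binary files are not parsed (pre-convert
  to text); visibility graphs assume uniform time spacing; ε is global —
  per-subject or circadian adaptation is out of scope.
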