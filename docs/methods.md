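# Methods

This note documents the models, defaults, and numerical conventions behind
`punapipe`, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Isotope correction chains

All corrections are ordered linear steps `v ← slope·v + intercept`, applied
by `isotopes.apply_chain`. The empty chain is the identity and chains compose
associatively, which makes provenance easy to audit: a corrected value is a
fold of named steps.

The default carbonate→drinking-water δ18O chain is a canonical stand-in, not
a certified calibration (laboratories differ in their preferred regressions):

1. VPDB→VSMOW scale conversion: `v ← 1.03091·v + 30.91`;
2. structural carbonate → phosphate offset: `v ← v − 8.5` ‰;
3. phosphate–water fractionation inversion of `δ18Op = 0.78·δ18Ow + 22.7`.

Every step is replaceable by configuration, and the packaged burial table
carries already-corrected values, so nothing downstream depends on this
default. For δ13C the named constants are: Suess (post-industrial
fossil-fuel) +1.5 ‰, trophic enrichment +5 ‰, carbonization +1 ‰, and a
conventional apatite→diet enrichment of −9.4 ‰ (only the first three are
standard literature values; the last is a configurable default).

Collagen quality control passes exactly the closed rectangle: carbon ≥ 35
wt%, nitrogen ∈ [11, 16] wt%, atomic C:N = (C/12.011)/(N/14.007) ∈
[2.9, 3.6]; all boundaries inclusive. Zone classification is strictly
`value < −8 ‰ ⇒ highland`: the boundary value itself is consistent with
low-elevation water, and window membership elsewhere in the package is
inclusive — the two conventions are deliberate and tested.

The two-sample Kolmogorov–Smirnov statistic uses the asymptotic p-value with
effective size `n_a·n_b/(n_a+n_b)` (scipy's `method="asymp"`); exact
small-sample p-values are out of scope, and D is reported to two decimals
when printed.

## Expectation windows and their reconciliation

The published isotope windows exist in two printed variants that disagree
for δ13C: a summary-table version (logistical −29..−24, seasonal −28..−22,
permanent −28..−21 ‰) and a narrative version (−27..−22 / −27..−19 /
−27..−19 ‰). The summary-table permanent window does not contain the
observed human diet range (−24..−20 ‰) that the same source scores as
supporting permanent use — an internal inconsistency of the source data.

Because hypothesis support here is conjunctive and strict (*every* value
inside the window), the package ships three named presets:

* `table2` — the summary-table windows. These are also the generating
  windows of the synthetic population model, so simulations are evaluated
  against this preset (in simulation these windows *are* the truth).
* `text` — the narrative windows.
* `reconciled` (default for observed data) — summary-table δ18O windows;
  δ13C windows taken per model from whichever printed variant is consistent
  with the published per-cell support pattern (narrative for logistical and
  permanent, summary-table for seasonal). This is the unique assignment that
  reproduces the published scorecard under the strict containment rule.

Distance rules follow the narrative thresholds on round-trip distance —
logistical ≤ 80 km, seasonal ≤ 1000 km, permanent unbounded, inclusive — and
an alternative `one_way_strict` encoding (one-way < 40 / < 500 km) ships for
the summary-table reading; the two differ only exactly at a bound.
Hypotheses are labelled by section-style numbering (H3 = distance, H4 =
demography); the summary table's column order swaps those two.

## Radiocarbon calibration

The posterior over the calendar grid is
`w(t) ∝ exp(−(y−μ(t))²/2(σ²+s(t)²)) / √(σ²+s(t)²)`, normalized to unit mass
over the grid. The `1/√(total variance)` factor matches the common
calibration likelihood; implementations omitting it differ slightly where
the curve error varies steeply — documented so cross-comparisons are
interpretable. Computation is in log space; the curve's native grid is used
(linear-interpolation refinement is available via `CalibrationCurve.refine`);
descending input grids are normalized to ascending, making calibration
direction-invariant.

HPD intervals select the smallest number of grid cells reaching the level,
with probability ties broken toward older (larger cal BP) cells —
deterministic by construction — then merge contiguous cells. Reservoir
corrections and mixed-curve calibration are not implemented.

## Travel cost

Walking is modelled cell-centre to cell-centre on a directed graph
(8-connectivity default; 16 adds knight moves and is never slower). Edge
cost is `distance / speed(slope)` with slope = rise/run and Tobler's hiking
function `6·exp(−3.5·|s+0.05|)` km/h as the default (all three parameters
exposed: the field analysis this mirrors says only "terrain-adjusted", so
any supplementary cost function can be dropped in). Planar rasters use
Euclidean distances; geographic rasters use the spherical law of cosines on
the authalic radius (6 371 007.2 m) with east–west spacing narrowing by
latitude. Cells are addressed (row, col) with row 0 at the north edge; the
ASCII-grid origin is the lower-left corner.

Shortest paths are scipy's Dijkstra; the test suite cross-checks against an
independently built edge list run through networkx Bellman–Ford on grids up
to 30×30, plus analytic oracles: on uniform terrain the optimal route is a
straight lattice line for moderate grades (at grades ≳ 0.5 switchback
zig-zags become optimal under Tobler's function — oracle fixtures stay in
the straight-line regime), and flat-terrain time is the octagonal lattice
metric over the peak flat speed 6·e^(−0.175) ≈ 5.04 km/h. The cone fixture
uses 125 m cells so the lattice detour to the 2500 m ring stays under 2% of
the continuum closed form `r/6 km/h`.

One plausible-sounding monotonicity claim is *false* and deliberately not
asserted in general: raising a single cell can **decrease** other cells'
arrival times even when all slopes stay above −0.05, because the raise can
act as a ramp that moves a steep exit edge closer to the optimal −5% grade
(a flat-then-steep kink profile shows the effect numerically). On flat
terrain the no-benefit property is a theorem (convexity of the exponential
cost in the slope) and is tested there.

The published field figures (122 km / 41 h to the 2500 m contour) depend on
a specific 30 arc-second DEM tile and an unpublished cost function; the
package supports re-running them as an integration exercise on a real grid,
but its own verification is against synthetic terrains with closed-form
oracles. Only the *relation* round-trip = 2 × one-way is asserted for that
figure.

## Demography

Each individual's unit mass is spread uniformly over its [age_min, age_max]
interval and apportioned to 10-year bins by overlap (a midpoint mode is
available); total mass always equals the number of aged individuals.
Open-ended "50+" ages are encoded [50, 70] — a conventional osteological
cap. Young children are any interval intersecting [4, 8] years; old adults
any interval reaching 50. The parity test is a df=1 chi-square against a
50:50 expectation, no continuity correction, on determinate-sex individuals
only; the asymptotic p tracks exact binomial enumeration loosely at n ≲ 20
(documented gap ≤ 0.2 in the tests; at 8 vs 5 the asymptotic p is 0.41
against an exact 0.58). Burial-assemblage bias is not corrected.

## Provenance

Non-local fraction f = 1 − n_local/n_total (exact counts, not the rounded
percentage) classifies as absent (f ≤ 0.02), present, or abundant
(f > 0.20); exact threshold hits take the lower class. The thresholds are
package defaults chosen so a 0.9% non-local fraction reads "absent" while
remaining configurable — the underlying field judgement is qualitative.
Artefacts without a local match are counted non-local even though they may
be extremes of local material variation; the evaluation record carries that
caveat.

## Synthetic data and model recovery

The generator draws the study conditions, not free dials:

* isotopes uniform within the generating model's summary-table windows —
  hard bounds, so membership guarantees are exact (a truncated-normal option
  adds central tendency but is off by default for testability);
* full-spectrum demography cycles a stratified template of ten plausible age
  intervals (young children through 50–70), guaranteeing all cohorts are
  present in any camp of ≥ 10 — the operational meaning of "full spectrum";
  adult sexes are Bernoulli(1/2) and under-18s are recorded indeterminate,
  as juvenile skeletal sexing generally is;
* task-group demography draws 18–45 adults with a 0.85 majority-sex
  probability. 0.85 (rather than a milder skew) is a pre-registered power
  choice: at n = 16 the parity test rejects with probability
  P(majority ≥ 12 | Binomial(16, q)) ≈ 0.80 at q = 0.8 but ≈ 0.92 at
  q = 0.85, and the recovery targets below need the latter;
* assemblages are per-artefact Bernoulli non-local draws at 0.30 / 0.08 /
  0.005 for logistical / seasonal / permanent (539 artefacts);
* distance scenarios default to 42 / 400 / 244 km round-trip — an
  ethnographic-scale foray, a seasonal round, and the observed
  highland-interior case;
* `simulate_inputs_end_to_end` writes a byte-reproducible bundle including
  an inclined-plane DEM whose source-to-contour distance matches the
  scenario within one cell.

`pipeline.model_recovery` scores 200 seeded sites per generating model at
n = 16 against the `table2` preset and reports the confusion matrix. With
seed 1 the recovery rates are 96.5% (permanent), 90.0% (logistical), 92.5%
(seasonal); failures fall in the "none" column — the conjunctive test
declines to select rather than selecting wrongly. The binding error sources
are the parity test's false rejections (~6% at 11 sexed adults) for the
residential models and its finite power (~8% misses at 0.85 skew) for the
logistical model.

What the generator does **not** emulate: paleoclimate-driven isotope
seasonality, intra-individual serial variation, diagenetic scatter,
spatially structured lithic deposition, or realistic curve-shaped
calibration error. Passing recovery tests therefore show the inference
machinery is correct under the declared signal structure, not that real
assemblages of n = 16 always carry this much signal.

## Problem sizes

Default test and reproduction runs use grids up to 181×181 cells, 200
simulations per generating model, and ≤ 30×30 brute-force oracles — sizes
chosen so the full suite runs in seconds on a single core while leaving the
asymptotic regime of every approximation visible in the tests.
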