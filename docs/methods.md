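# Methods

This note documents the models, conventions and numerical choices behind
`gsphere`, in the spirit of a software methods appendix: what is
computed, under which assumptions, and where the genuinely open design
choices were settled.

## Signal model and axis conventions

A trace is a uniformly sampled tri-axial acceleration series in g with
the body-frame convention surge → x, heave → y, sway → z; an upright
stationary subject reads (0, 1, 0). Input in m/s² is divided by 9.81 on
read. Mildly irregular timestamps are tolerated on read (the rate is
taken as 1/median Δt), but the smoothing stage requires spacing jitter
below 1% of the median and raises rather than silently resampling.

Measured acceleration is modelled as static (gravity, orientation-
dependent) plus dynamic (movement) components. The static estimate is a
**centred running mean** per axis. Two details matter:

- *Window span.* `window_samples` is the total span; an even span is
  widened by one sample so the window is exactly centred. The
  recommended span is about twice the dominant stroke period
  (`suggest_window` returns `round(2 · period · rate)`).
- *Mean, not fixed divisor.* The mean divides by the number of samples
  actually summed. A fixed divisor equal to the nominal span would scale
  constants by (span+1)/span — a running *mean* must preserve constants,
  and this implementation does, exactly. At the trace boundaries the
  window shrinks to the samples in view, keeping the output aligned
  sample-for-sample with the input (no padding, no truncation), which
  downstream per-sample binning relies on.

Dynamic acceleration is raw minus static, reconstructing the raw signal
to machine precision (one ulp; the identity is not bitwise because
`(a−s)+s` rounds). VeDBA and ODBA follow their standard definitions and
satisfy V ≤ O ≤ √3·V elementwise.

Posture is the static vector normalised to unit length. Samples whose
static magnitude falls below `min_length_g` (default 1e-6 g — free fall
or degenerate smoothing output) are *excluded*, not raised; only an
entirely empty result raises. Spherical angles use inclination θ from
the +y pole (upright posture = North pole) and rotation φ = atan2(z, x)
in the x–z plane.

## Geodesic tessellation

The sphere is tessellated by subdividing an icosahedron `level` times
(each triangle into four, midpoints projected back onto the sphere):
20·4^level facets, 10·4^level + 2 vertices, facet areas summing to 4π
with a max/min spherical-area ratio ≈ 1.30 at level 3 (uniform enough
that frequency plots are not biased, unlike latitude–longitude grids).
The icosahedron is oriented with one vertex at (0, 1, 0) so the upright-
posture convention lands on a vertex; the level cap is 7 (memory guard).
Default level 3 (1,280 facets, ~4° facet radius) balances angular
resolution against per-facet sample counts for traces of minutes to
days.

**Facet assignment.** A sample belongs to the facet it *intersects* —
the spherical triangle containing its unit vector, with points on a
shared edge or vertex assigned to the smallest facet id among the tied
facets (determinant tolerance 1e-12). Three independent routes compute
this partition:

1. `locate_facet` — hierarchical descent: at each subdivision level a
   beam of the 3 best parents is kept and their 12 children scored by
   the cosine between the sample and the facet-centre direction
   (argmax of cosine = smallest angle); at the leaf, an exact
   point-in-spherical-triangle test (three edge-plane determinants) over
   the winner's vertex neighbourhood settles the assignment. The
   refinement exists because the nearest-centre rule and containment
   genuinely differ in a narrow band along facet boundaries (a few
   percent of the sphere at level 3 — the facets are not perfectly
   equilateral, so centre-Voronoi cells are not the triangles).
2. `locate_facet_brute` — exhaustive containment scan (the reference).
3. `locate_facet_winding` — the classical winding test: vertices of the
   containing facet, projected into the tangent plane at the sample,
   subtend angles summing to 2π (tolerance 1e-6). The facet *antipodal*
   to the sample also winds to 2π when viewed "through" the sphere, so
   the scan is restricted to the hemisphere facing the sample. Points
   numerically on a boundary fall back to the containment/nearest-centre
   reference with a warning.

The three routes agree on 100% of 10,000 uniform random directions in
the shipped tests; disagreement is confined, by construction, to
determinant ties on facet boundaries.

## Facet statistics, normalisation and sphere algebra

Binning accumulates, per facet: (i) the sample count, (ii) the mean of
each channel (unit-vector components and the chosen attribute), and
(iii) a fixed-width frequency distribution of the attribute. Default
histogram: VeDBA on [0, 4] g in 20 bins (0.2 g width); bins are
half-open and out-of-range values clamp into the end bins so no sample
is silently lost. Binning conserves samples exactly (integer check in
tests).

Two normalisations: **global** (counts and histogram mass as percent of
all retained samples — the whole sphere totals 100) and **per-facet**
(each populated facet's histogram rescaled to total 100 on its own,
making the energetics of rare postures visible). Under per-facet mode
the counts layer is still expressed as global percentages so the same
object can drive a spherical histogram. Re-normalising under a
different mode raises.

Differential spheres require identical tessellation level and bin
layout, and both inputs normalised (percentages remove data-volume
bias); inputs are normalised first, then combined. `difference` stores
|GA − GB| per facet and bin as the primary layer *and* the signed
GA − GB alongside, because the magnitude alone cannot colour a plot by
which input was larger. `summation` is the elementwise sum. Both
operate on the counts layer (Dubai differential) and the histogram
layer (urchin differential) simultaneously.

**Lifestyle curves** rank facets by occupancy (descending count, ties by
facet id — the ranking rule is a package choice; any fixed rule gives
monotone curves) and accumulate, step by step, the share of samples
(time) and of count × mean-DBA (DBA allocation) against the percentage
of all facets covered. Both curves start at 0 and end at 100; coverage
ends at the occupied fraction of the sphere. The cumulative-share
reading of the DBA axis is one of two defensible constructions (the
alternative being per-facet mean DBA); it is the one implemented because
it makes curves comparable across subjects regardless of scale.

## Scenes

Visualisation is split into scene construction (pure geometry, tested)
and rendering (matplotlib PNG, OBJ mesh export, JSON primitive dumps).
Dubai prisms extrude from populated facets along the facet-centre
direction with length a linear map of the normalised value (fullest
facet = `max_length`, default 0.5 radii). Urchin spines start
`spine_offset` (default 0.05 radii) above the surface with a connector
line to the facet centre; each non-empty bin becomes a disc whose radial
position increases with the bin's attribute value, whose thickness is
the bin width, and whose diameter is proportional to the bin frequency
(diameter-linear by default; an area-linear mode is available). Colour
is metadata (low → blue, high → red by default) and never asserted on.

## Synthetic traces

The generator emulates multi-state biologging data:
`raw(t) = gravity(pitch, roll) + amp · sin(2πft + phase) + N(0, σ²)` per
axis, with exponentially distributed state dwells (quantised to ≥ 1
sample) switched by a row-stochastic transition matrix. The gravity
vector for a posture is u = (sin p, cos p·cos r, cos p·sin r): pitch
tilts heave toward surge (nose-up 90° → (1, 0, 0)), roll then rotates
the remaining heave component toward sway. Defaults: 40 Hz sampling,
5 s mean dwell, scalar amplitudes applied to the heave (stroking) axis,
i.i.d. Gaussian noise; each bout draws fresh phases so repeated visits
to a state are not phase-locked. Everything is driven by one seed;
identical seeds give bitwise-identical traces.

What the generator does *not* emulate: autocorrelated sensor noise,
gait harmonics and asymmetric stroke waveforms, gradual posture
transitions, sensor drift and miscalibration, and centripetal
acceleration during turns. Tests passing on synthetic data therefore
demonstrate the pipeline's correctness (separation, binning, algebra,
recovery), not that a 2 s running mean is the right separation filter
for any particular species — the smoothing window remains a
user-supplied, species-specific choice.

Two geometric facts matter when designing recovery experiments (and
real deployments near the poles of the tessellation): the upright
posture (0, 1, 0) sits exactly on a tessellation *vertex*, and the
whole roll-0 pitch arc down to ±63.4° lies exactly on icosahedron
*edges*. Postures on these loci split their samples between adjacent
facets. The recovery demonstrations therefore use postures placed in
facet interiors (pitch −16°/44°, roll 18°, ≥ 2° from any boundary) and
state dwells (30 s) long compared with the smoothing window (1 s), so
that posture blending at state switches stays a small fraction of each
bout. Under those conditions a 60° posture separation recovers distinct
modal facets with purity ≥ 0.95, and a 0.1 g vs 0.6 g amplitude contrast
at one posture produces separated modal DBA bins on a single spine (the
multi-modal signature). Mean VeDBA of a single-axis sinusoid of
amplitude a approaches the rectified-sine mean 2a/π when the smoothing
window covers many cycles (within 0.3% at f = 5 Hz with an 80-sample
window; leakage grows as the window approaches the period).

## Problem sizes and determinism

The shipped tests and the acceptance script use 60 s–10 min traces at
40 Hz (2,400–24,000 samples), tessellation levels 0–5 for geometry
checks and level 3 for binning, and 10,000 random directions for the
locator cross-checks — sizes chosen so the full suite completes in well
under a minute while every property is exercised at meaningful scale.
All stochastic stages take explicit seeds; the acceptance script derives
every seed from its `--seed` argument.

## Known limitations

- No resampling/interpolation: irregular traces must be regularised
  upstream before smoothing.
- The running mean is the only separation filter (no Butterworth or
  spline option).
- Facet statistics assume enough samples per facet to be meaningful;
  very short traces at high tessellation levels produce sparse,
  noise-dominated histograms.
- Scene rendering aims at inspection, not publication aesthetics; the
  OBJ/JSON exports exist for external renderers.
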