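# Methods

## Overview

`axonmetrics` quantifies myelinated white-matter fiber ultrastructure from
two-dimensional cross-sections. The pipeline takes per-pixel semantic class
scores (background / axon / myelin), converts them into per-fiber instance
labels, measures each fiber with moment-equivalent ellipses, models the
diameter population with a Bayesian generalized extreme value (GEV) fit,
and converts diameters and g-ratios into conduction-velocity estimates.
Because the package ships no electron-microscopy data, every stage is
exercised against a synthetic phantom generator with exact ground truth.

## Fiber geometry and the minor-axis rule

A myelinated fiber is idealized as a circular cylinder (axon radius *r*)
inside a concentric sheath (thickness *t*). A planar section at angle θ
from the cylinder normal intersects it in two concentric ellipses with

- minor semi-axis = true radius (*r* for the axon, *r + t* for the outer
  fiber), independent of θ;
- major semi-axis = radius / cos θ.

The minor axis of a moment-fit ellipse is therefore a cut-angle-invariant
diameter estimator, and the g-ratio is defined as the ratio of the axon
ellipse's minor axis to the outer ellipse's minor axis. The
equivalent-circle diameter 2·√(area/π) is provided as an alternative
estimator; it coincides with the minor axis for orthogonal cuts and
exceeds it increasingly with eccentricity, which is why it is not the
primary estimator for obliquely sectioned material.

Ellipse fitting uses the region's area-normalized second central moments
(scikit-image `regionprops`). The outer-fiber ellipse is fitted on the
**hole-filled union** of the axon and myelin regions, not on the annulus
alone: the second-moment ellipse of an ideal annulus has semi-axis
√(R_out² + R_in²) > R_out, so an annulus fit would systematically inflate
the outer diameter. An annulus-mode fit can still be obtained by passing
the bare myelin mask to `fit_ellipse` directly. The skeleton-based myelin
thickness (twice the mean Euclidean-distance-transform value along the
sheath skeleton) is reported per fiber as a cross-check; on circular
undegraded fibers, axon equivalent diameter + 2 × skeleton thickness
agrees with the outer minor axis within a few percent.

Regions below `min_region_px = 10` pixels are flagged degenerate rather
than measured; moment fits on smaller regions are numerically meaningless
at the default resolution. Orientations are reported in (−90°, 90°]
relative to the raster x-axis.

## Instance segmentation

The semantic map is thresholded by per-pixel argmax (the class scores sum
to 1, so argmax is equivalent to a 0.5 threshold for confident one-hot
predictions). Clean-up: opening-by-reconstruction of the axon mask
(erosion with a 1 px disk followed by propagation under the original
mask, which removes sub-element debris without altering surviving
components), closing plus hole-filling of the myelin mask, removal of
objects below `min_object_px = 10`. Holes inside a sheath not claimed by
an axon become sheath, which repairs thin background gaps between axon
and myelin.

To separate touching ("kissing") sheaths, the two masks are joined and the
Euclidean distance transform (EDT) of the union is computed. The watershed
of the inverted EDT, seeded at EDT local maxima at least
`peak_min_distance = 10` px apart within each connected component,
partitions the union into one basin per fiber. The EDT is smoothed with a
Gaussian (σ = 1 px) before peak detection: on elongated oblique-cut
ellipses the raw EDT has near-plateau ridges whose quantized maxima would
otherwise split single fibers. Each basin is split back into axon and
myelin compartments with the binary masks; ids are dense from 1.

Measured instances pass a plausibility filter with machine-readable
rejection reasons. Defaults: axon minor diameter 0.1–15 µm, outer minor
diameter 0.2–20 µm, g-ratio in (0, 1], fibers touching the image border
dropped (their ellipses are truncated), axon basins with no sheath pixels
rejected as `no_myelin`. The bounds are deliberately wide — they catch
segmentation failures, not population tails — and are configurable.

## Synthetic phantom generator

The generator emulates the population statistics reported for human
white-matter fibers and the degradations typical of aged post-mortem
electron micrographs:

| parameter | default | rationale |
|---|---|---|
| pixel size | 17.28 nm | 4.32 nm acquisition downsampled ×4 per axis |
| axon diameter law | GEV(µ = 0.5 µm, σ = 0.15 µm, ξ = 0.1) | documented placeholder with realistic location/spread; the published fits are shown only graphically, so recovery is always judged against the generator's own settings |
| g-ratio law | truncated normal, mean 0.54, sd 0.05 | measured population means are 0.538/0.537 |
| cut angles | uniform [0°, 60°] | beyond ~60° the rasterized annulus becomes unreliably thin at this resolution |
| degradation | off | artifact rates are not published; a `realistic()` preset (10% myelin gaps of 60°, 10% kissing fibers, 0.5 px boundary noise and blur) is used in robustness tests |

Diameter draws below a 0.1 µm physical floor are redrawn (sub-resolution
fibers cannot be rasterized meaningfully). Myelin thickness is derived
from the sampled g-ratio as *t* = *r*(1/g − 1), so the truth-table
g-ratio identity g = d/(d + 2t) holds exactly. Fibers are placed by
rejection sampling so that outer bounding circles (semi-major axis plus a
2 px gap) do not overlap; kissing pairs share the anchor's orientation and
are placed along the minor-axis direction at 1 px less than tangency, so
their sheaths share a boundary while keeping distinct instance ids.
Degradation order: myelin-sector gaps (carved around connected-component
centroids of the myelin channel), smooth random boundary displacement
(Gaussian random field, σ = 8 px, scaled to the requested RMS amplitude),
Gaussian score blur, renormalization to per-pixel sum 1. With the same
seed the generator is byte-identical.

What the phantom does **not** emulate: electron-optical texture and
staining contrast, non-elliptical (crenellated or collapsed) fiber
profiles, organelles inside axons, unmyelinated axons, and spatially
correlated damage. Passing phantom tests therefore demonstrates the
correctness of the measurement chain on idealized geometry, not
performance on real micrographs — on real data the semantic predictor
(out of scope here) dominates the error budget.

## GEV diameter model

Diameters are modeled with the three-parameter GEV density
G(x) = (1/σ)·t(x)^(ξ+1)·e^(−t(x)), t(x) = (1 + ξ(x−µ)/σ)^(−1/ξ),
with the Gumbel limit t(x) = e^(−(x−µ)/σ) taken for |ξ| < 1e−8 to avoid
catastrophic cancellation. Sampling is by inverse CDF. The density, CDF
and quantile functions are validated against `scipy.stats.genextreme`
(shape convention c = −ξ) in the test suite.

The Bayesian fit uses weakly informative priors on the diameter scale:
µ ~ Normal(0.5, 0.5) truncated positive (µm), σ ~ HalfNormal(0.5) (µm),
ξ ~ Normal(0, 0.3). Sampling is affine-invariant ensemble MCMC (emcee)
with 80% differential-evolution and 20% snooker moves, which mix markedly
better than stretch moves on this correlated three-parameter posterior.
By default 4 **independent** ensembles of 16 walkers each run 1000
warm-up + 500 kept steps; each ensemble's walkers are interleaved into
one chain, so the split-R̂ computed by arviz compares genuinely
independent runs (walkers within one ensemble interact and would
understate between-chain variance if treated as chains themselves).
Likelihood points outside the support contribute −∞, so the posterior
support adapts to the data. 99% highest-posterior-density intervals are
computed by the narrowest-window scan over sorted pooled draws. Recovery
is verified at n = 10,000 for ξ ∈ {−0.1, 0, 0.2} with split-R̂ < 1.01 and
ESS > 400. Prior and posterior predictive checks simulate datasets of the
observed size and overlay their pointwise-mean density.

## Conduction velocity

Velocities use the generalized Rushton relation
v = s · d · (−ln g)^α with d = g·D, s = 7.5 µs⁻¹ (absolute scale
calibrated against biophysical simulation) and α = 0.68
(simulation-optimized). Because µm·µs⁻¹ = m/s, diameters in µm give m/s
directly. Reversing the optimal-g argument — if the observed mean g is
optimal, then g·(−ln g)^α is maximal there — yields α = −ln(g), i.e.
α = 0.62 at g = 0.54, which raises velocity estimates by ≈3% relative to
α = 0.68. The internode-length relation L ∝ d·(−ln g)^0.5 and the travel
time L/v are provided as companions; per-fiber velocities use each
fiber's own measured g by default (a fixed population g can be passed
instead).

## Validation protocol

Per-pixel: IoU, Dice (the identity Dice = 2·IoU/(1+IoU) is enforced in
tests) and HD95, the 95th percentile of symmetric boundary-to-boundary
nearest distances in µm (boundaries = mask minus its erosion; distances
via the EDT of each boundary's complement). Two empty masks agree
perfectly by convention; one empty mask scores 0 with infinite HD95.

Instance matching is greedy one-to-one by descending overlap fraction with
a 40% threshold. The threshold is applied **two-sided** — intersection
over ground-truth area and intersection over prediction area must both
exceed 0.40 — which prevents one giant predicted blob from matching every
ground-truth fiber; a single-sided mode is available. Ties (one
ground-truth fiber overlapping two predictions above threshold) are
resolved in favor of the larger overlap; the loser becomes a false
positive. Agreement of matched measurements is Bland-Altman on the raw
scale: deltas (validation − prediction), mean, ±1.96 sd limits of
agreement, mean absolute error, and deltas keyed by ground-truth axon
diameter for size-stratified error analysis.

## Problem sizes and numerical choices

The shipped analysis uses a 300-fiber phantom on a 3600² px canvas with
moderate degradation; the heaviest acceptance check runs 2000 fibers on
7600² px (the placement algorithm needs roughly 24,000 px² per fiber at
the default laws). MCMC defaults (4 × 16 walkers, 1000 + 500 steps) put
split-R̂ near 1.003 on 10,000-point datasets in ~15 s on one core.
Degenerate inputs are handled explicitly: zero fibers produce an empty
population report; empty masks produce empty instance maps; sub-minimum
regions, missing sheaths and border contact become QC flags rather than
crashes; 16-bit label overflow raises an error advising 32-bit mode.

## Known limitations

- The phantom's cylindrical-fiber assumption means the minor-axis rule is
  exact by construction; real fibers that are genuinely oval are
  underestimated, and this method cannot distinguish an oblique circular
  cut from an orthogonal oval cut.
- The semantic predictor is a pluggable interface; no network is included,
  so end-to-end accuracy on real micrographs is not claimed.
- The velocity scale s and exponent α are literature-calibrated constants,
  not fitted to data in this package; velocities are estimates, not
  measurements.
- Watershed seeds at EDT maxima can oversegment strongly concave fused
  objects and undersegment deeply overlapping pairs; the phantom's
  tangent-contact kissing model is the regime the defaults are tuned for.
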