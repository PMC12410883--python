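# axonmetrics

Quantitative morphometry of myelinated white-matter fibers in
two-dimensional cross-sections: from semantic axon/myelin class maps to
per-fiber instance labels, ellipse-based diameters and g-ratios, Bayesian
generalized-extreme-value (GEV) models of diameter distributions, and
conduction-velocity estimates.

The package is aimed at researchers analyzing electron micrographs of
white matter (e.g., corpus callosum or superficial white matter), where
fibers are sectioned at unknown oblique angles and sheaths are often
damaged or touching. It implements the measurement chain downstream of a
semantic predictor, and ships a synthetic phantom generator with exact
ground truth so that every stage is testable end-to-end.

## The core ideas

**Minor-axis diameter rule.** An oblique planar cut of a cylindrical
fiber is an ellipse whose *minor* axis equals the true diameter for any
cut angle. Each fiber compartment is therefore summarized by the ellipse
with the same area-normalized second moments as its pixel region, and

    g = axon ellipse minor axis / outer ellipse minor axis.

**Instance separation.** Binary axon and myelin masks are joined; the
watershed of the inverted Euclidean distance transform, seeded at the
transform's local maxima, assigns one basin per fiber and splits kissing
sheaths. Each basin is then split back into its compartments.

**Diameter model.** Axon and outer-fiber diameter populations follow a
GEV(µ, σ, ξ) law, fitted by ensemble MCMC under weakly informative
priors, summarized with 99% highest-posterior-density intervals.

**Conduction velocity.** The generalized Rushton relation

    v = s · (g·D) · (−ln g)^α ,   s = 7.5 µs⁻¹, α = 0.68

maps outer diameter D (µm) and g-ratio to speed in m/s. Treating the
observed mean g as optimal gives the data-derived exponent α = −ln(g).

## Worked example

The numbered scripts under `analysis/` run the full study on a 300-fiber
phantom (GEV diameters µ = 0.5 µm, σ = 0.15 µm, ξ = 0.1; g-ratios
0.54 ± 0.05; cut angles up to 60°; myelin gaps, kissing pairs, boundary
noise), writing all tables under `results/pipeline/`:

```
$ python analysis/01_generate_phantom.py
phantom: 300 fibers on (3600, 3600) px at 17.28 nm/px
  axon diameter   median 0.554 µm (law µ=0.5, σ=0.15, ξ=0.1)
  true g-ratio    mean 0.539 (law 0.54 ± 0.05)

$ python analysis/02_segment_instances.py
segmentation: 300 instances from 300 generated fibers

$ python analysis/03_measure_morphometry.py
morphometry: kept 299 fibers, rejected 1
  rejection reasons: {'touches_border': 1}
  axon minor axis  median 0.553 µm
  outer minor axis median 1.032 µm
  g-ratio          mean 0.542

$ python analysis/04_fit_gev.py
GEV fit to 299 measured axon diameters:
  mu    mean 0.5062  99% HPD [0.4833, 0.5306]  -> covers truth 0.5
  sigma mean 0.1558  99% HPD [0.1369, 0.1743]  -> covers truth 0.15
  xi    mean 0.1131  99% HPD [0.0410, 0.2053]  -> covers truth 0.1

$ python analysis/05_estimate_velocity.py
velocity (s = 7.5 µs⁻¹, α = 0.68):
  median v            2.97 m/s over 299 fibers
  derived exponent    α = -ln(0.542) = 0.61
  switching exponents changes v by +3.4%

$ python analysis/06_validate_segmentation.py
axon   IoU 0.971  Dice 0.985  HD95 0.017 µm
myelin IoU 0.946  Dice 0.972  HD95 0.017 µm
instances: 300 matched, 0 FP, 0 FN
g-ratio agreement on 300 matched fibers: mean Δ -0.0029, MAE 0.0122
```

Reading the numbers: the measured axon-diameter median matches the
generated population to a fraction of a pixel; the GEV posterior covers
all three generator parameters in its 99% HPD; despite 10% of fibers
having missing myelin sectors and 10% placed in contact, the watershed
recovers every instance with no false positives or negatives, and the
g-ratio error stays near 0.01.

A command-line interface mirrors the scripts
(`axonmetrics phantom|segment|measure|fit-gev|velocity|validate|run`),
and everything is importable:

```python
from axonmetrics import (PopulationConfig, generate_phantom, segment,
                         measure_instances, records_to_frame)
smap, truth_labels, truth = generate_phantom(PopulationConfig(fiber_count=50, seed=7))
df = records_to_frame(measure_instances(segment(smap)))
print(df[["axon_minor_um", "g_ratio"]].median())
```

## Layout

```
src/axonmetrics/    library: phantom, segmentation, morphometry, gev,
                    velocity, validation, containers, io, pipeline, cli
analysis/           numbered study drivers (write results/pipeline/)
tests/              pytest suite, incl. end-to-end acceptance checks
docs/methods.md     model assumptions, parameter defaults, limitations
```
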