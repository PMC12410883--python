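"""Shared study conditions for the analysis scripts.

One 300-fiber phantom emulating a superficial-white-matter-like
population: GEV axon diameters (µ = 0.5 µm, σ = 0.15 µm, ξ = 0.1),
g-ratios truncated-normal around 0.54, cut angles uniform on [0°, 60°],
17.28 nm pixels, moderate degradation artifacts. All scripts read and
write under results/pipeline/.
"""

from pathlib import Path

from axonmetrics.phantom import DegradationParams, PopulationConfig

RESULTS = Path(__file__).resolve().parents[1] / "results" / "pipeline"
SEED = 20

POPULATION = PopulationConfig(
    fiber_count=300,
    canvas_px=(3600, 3600),
    seed=SEED,
    degradation=DegradationParams(
        myelin_gap_probability=0.1,
        gap_arc_deg=60.0,
        kissing_fraction=0.1,
        boundary_noise_amplitude_px=0.5,
        semantic_blur_px=0.5,
    ),
)
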