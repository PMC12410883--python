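"""End-to-end orchestration: phantom → segment → measure → fit → velocity → validate.

A :class:`RunConfig` bundles every stage's parameters and seeds; under a
fixed config the whole run is deterministic. :func:`run_pipeline` executes
the stages, optionally writes every intermediate artifact, and aggregates
the population summaries (diameter medians, mean g-ratio, GEV posterior,
velocity median) plus — because phantom ground truth is available —
the segmentation-validation metrics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as amio
from .containers import AXON, MYELIN
from .gev import GEVPriors, fit_gev_mcmc
from .morphometry import measure_instances, records_to_frame
from .phantom import PopulationConfig, generate_phantom
from .segmentation import FilterRule, filter_instances, segment
from .validation import match_instances, paired_agreement, pixel_metrics
from .velocity import VelocityModel, conduction_velocity

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    filter_rule: FilterRule = field(default_factory=FilterRule)
    min_object_px: int = 10
    peak_min_distance: int = 10
    priors: GEVPriors = field(default_factory=GEVPriors)
    mcmc_chains: int = 4
    mcmc_draws: int = 250
    mcmc_warmup: int = 500
    mcmc_seed: int = 1
    velocity_model: VelocityModel = field(default_factory=VelocityModel)
    fit_column: str = "axon_minor_um"

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages on a freshly generated phantom and aggregate a report.

    Returns a JSON-serializable report; when ``out_dir`` is given, all
    intermediate artifacts (semantic map, labels, truth and measurement
    tables, posterior draws, report) are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    report: dict = {"config": config.to_dict()}

    smap, truth_inst, truth = generate_phantom(config.population)
    if config.population.fiber_count == 0:
        report["status"] = "no fibers"
        report["population"] = {"n_fibers": 0}
        if out:
            amio.write_json(report, out / "report.json")
        return report

    inst = segment(
        smap,
        min_object_px=config.min_object_px,
        peak_min_distance=config.peak_min_distance,
    )
    records = measure_instances(inst)
    kept, rejected = filter_instances(records, config.filter_rule)
    measurements = records_to_frame(kept)

    med = measurements.median(numeric_only=True)
    report["population"] = {
        "n_instances": int(len(records)),
        "n_kept": int(len(kept)),
        "n_rejected": int(len(rejected)),
        "axon_minor_median_um": float(med["axon_minor_um"]),
        "outer_minor_median_um": float(med["outer_minor_um"]),
        "g_ratio_mean": float(measurements["g_ratio"].mean()),
        "g_ratio_median": float(med["g_ratio"]),
    }

    data = measurements[config.fit_column].dropna().to_numpy()
    if data.size >= 10:
        post = fit_gev_mcmc(
            data,
            priors=config.priors,
            chains=config.mcmc_chains,
            draws=config.mcmc_draws,
            warmup=config.mcmc_warmup,
            seed=config.mcmc_seed,
        )
        report["gev_posterior"] = post.summary()
    else:
        post = None
        report["gev_posterior"] = None

    v = conduction_velocity(
        measurements["outer_minor_um"].to_numpy(),
        measurements["g_ratio"].clip(1e-6, 1 - 1e-9).to_numpy(),
        config.velocity_model,
    )
    measurements = measurements.assign(v_mps=v)
    report["velocity"] = {
        "median_mps": float(np.median(v)),
        "scaling_s_per_us": config.velocity_model.scaling_s,
        "alpha": config.velocity_model.alpha,
    }

    # validation against the generator's ground truth
    px = smap.pixel_size_nm
    per_class = {}
    for name, cls in (("axon", AXON), ("myelin", MYELIN)):
        pm = pixel_metrics(
            (inst.axon_labels if cls == AXON else inst.myelin_labels) > 0,
            (truth_inst.axon_labels if cls == AXON else truth_inst.myelin_labels) > 0,
            px,
        )
        per_class[name] = {
            "iou": pm.iou, "dice": pm.dice, "hausdorff95_um": pm.hausdorff95_um,
        }
    match = match_instances(inst, truth_inst)
    truth_by_id = truth.set_index("fiber_id")
    rec_by_id = {r.fiber_id: r for r in records}
    pred_g, true_g, true_d = [], [], []
    for gid, pid, _ in match.matches:
        r = rec_by_id.get(pid)
        if r is None or not np.isfinite(r.g_ratio):
            continue
        pred_g.append(r.g_ratio)
        true_g.append(truth_by_id.loc[gid, "g_ratio_true"])
        true_d.append(2 * truth_by_id.loc[gid, "axon_radius_um"])
    validation = {
        "pixel_metrics": per_class,
        "n_matched": len(match.matches),
        "false_positives": len(match.false_positives),
        "false_negatives": len(match.false_negatives),
    }
    if pred_g:
        agr = paired_agreement(
            np.array(pred_g), np.array(true_g), "g_ratio", np.array(true_d)
        )
        validation["g_ratio_agreement"] = agr.summary()
    report["validation"] = validation
    report["status"] = "ok"

    if out:
        amio.write_semantic(smap, out / "semantic.tif")
        amio.write_instances(inst, out / "instances")
        amio.write_instances(truth_inst, out / "truth_instances")
        amio.write_table(truth, out / "truth.csv")
        amio.write_table(measurements, out / "measurements.csv")
        amio.write_table(
            records_to_frame([r for r, _ in rejected]).assign(
                reason=[reason for _, reason in rejected]
            ),
            out / "rejected.csv",
        )
        if post is not None:
            amio.write_posterior(post, out / "posterior.csv")
        amio.write_json(report, out / "report.json")
    return report
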