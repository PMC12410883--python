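"""Validate the predicted instances against the phantom's ground truth.

Per-class IoU/Dice/HD95, >40%-overlap instance matching with FP/FN
accounting, and Bland-Altman agreement of the g-ratio on matched fibers.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS  # noqa: E402

from axonmetrics import io as amio
from axonmetrics.morphometry import measure_instances
from axonmetrics.validation import match_instances, paired_agreement, pixel_metrics


def main() -> None:
    pred = amio.read_instances(RESULTS / "instances")
    gt = amio.read_instances(RESULTS / "phantom" / "truth_instances")
    truth = amio.read_table(RESULTS / "phantom" / "truth.csv").set_index("fiber_id")

    report = {}
    for name, p_arr, g_arr in (
        ("axon", pred.axon_labels, gt.axon_labels),
        ("myelin", pred.myelin_labels, gt.myelin_labels),
    ):
        pm = pixel_metrics(p_arr > 0, g_arr > 0, pred.pixel_size_nm)
        report[name] = {"iou": pm.iou, "dice": pm.dice,
                        "hausdorff95_um": pm.hausdorff95_um}
        print(f"{name:6s} IoU {pm.iou:.3f}  Dice {pm.dice:.3f}  "
              f"HD95 {pm.hausdorff95_um:.3f} µm")

    res = match_instances(pred, gt)
    print(f"instances: {len(res.matches)} matched, "
          f"{len(res.false_positives)} FP, {len(res.false_negatives)} FN")
    report["instances"] = {
        "matched": len(res.matches),
        "false_positives": len(res.false_positives),
        "false_negatives": len(res.false_negatives),
    }

    rec_by_id = {r.fiber_id: r for r in measure_instances(pred)}
    pred_g, true_g, true_d = [], [], []
    for gid, pid, _ in res.matches:
        r = rec_by_id.get(pid)
        if r is not None and np.isfinite(r.g_ratio):
            pred_g.append(r.g_ratio)
            true_g.append(truth.loc[gid, "g_ratio_true"])
            true_d.append(2 * truth.loc[gid, "axon_radius_um"])
    agr = paired_agreement(np.array(pred_g), np.array(true_g), "g_ratio",
                           np.array(true_d))
    print(f"g-ratio agreement on {len(pred_g)} matched fibers: "
          f"mean Δ {agr.mean_difference:+.4f}, "
          f"LoA [{agr.loa_low:+.4f}, {agr.loa_high:+.4f}], MAE {agr.mae:.4f}")
    report["g_ratio_agreement"] = agr.summary()
    amio.write_table(agr.by_size, RESULTS / "g_ratio_deltas.csv")
    amio.write_json(report, RESULTS / "validation.json")
    print(f"wrote {RESULTS / 'validation.json'}")


if __name__ == "__main__":
    main()
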