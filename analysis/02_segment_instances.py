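"""Segment the phantom's semantic map into fiber instances.

Threshold → binary clean-up → distance-transform watershed → split; writes
the predicted instance labels and reports how many fibers were found
versus generated.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS  # noqa: E402

from axonmetrics import io as amio
from axonmetrics.segmentation import segment


def main() -> None:
    smap = amio.read_semantic(RESULTS / "phantom" / "semantic.tif")
    truth = amio.read_table(RESULTS / "phantom" / "truth.csv")
    inst = segment(smap)
    amio.write_instances(inst, RESULTS / "instances")
    n_pred, n_true = len(inst.ids()), len(truth)
    print(f"segmentation: {n_pred} instances from {n_true} generated fibers")
    if n_pred != n_true:
        print("  (differences arise from degradation artifacts: myelin gaps,"
              " kissing sheaths, boundary noise)")
    print(f"wrote {RESULTS / 'instances'}")


if __name__ == "__main__":
    main()
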