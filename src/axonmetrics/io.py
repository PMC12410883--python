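"""On-disk formats: TIFF rasters, CSV tables, JSON summaries.

Semantic maps are 3-channel float32 TIFFs (channel order background,
axon, myelin) with the pixel size recorded in a JSON sidecar; instance
labels are 16-bit single-channel TIFFs (0 = background); all tables are
CSV with lengths in µm. Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import InstanceMaps, SemanticMap
from .gev import GEVPosterior

__all__ = [
    "write_semantic",
    "read_semantic",
    "write_instances",
    "read_instances",
    "write_table",
    "read_table",
    "write_posterior",
    "read_posterior",
    "write_json",
    "read_json",
]

_SIDE_CAR = "{stem}.meta.json"


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_name(_SIDE_CAR.format(stem=tiff_path.stem))


def write_semantic(smap: SemanticMap, path) -> Path:
    """Write scores as float32 TIFF plus a pixel-size sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, smap.scores.astype(np.float32), photometric="rgb")
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size_nm": smap.pixel_size_nm, "channels": [
            "background", "axon", "myelin"]}, indent=1)
    )
    return path


def read_semantic(path, pixel_size_nm: float | None = None) -> SemanticMap:
    path = Path(path)
    scores = tifffile.imread(path)
    if pixel_size_nm is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no pixel size given and no sidecar found at {sidecar}"
            )
        pixel_size_nm = json.loads(sidecar.read_text())["pixel_size_nm"]
    return SemanticMap(scores, pixel_size_nm)


def write_instances(inst: InstanceMaps, out_dir, allow_32bit: bool = False) -> tuple[Path, Path]:
    """Write axon/myelin label TIFFs (16-bit unless ``allow_32bit``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    max_label = max(
        int(inst.axon_labels.max(initial=0)), int(inst.myelin_labels.max(initial=0))
    )
    if max_label > 65535 and not allow_32bit:
        raise ValueError(
            f"{max_label} labels exceed the 16-bit range; pass allow_32bit=True "
            "to write 32-bit label TIFFs"
        )
    dtype = np.uint32 if max_label > 65535 else np.uint16
    paths = []
    for name, arr in (("axon_labels", inst.axon_labels), ("myelin_labels", inst.myelin_labels)):
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(dtype))
        paths.append(p)
    _sidecar_path(out_dir / "labels.tif").write_text(
        json.dumps({"pixel_size_nm": inst.pixel_size_nm}, indent=1)
    )
    return tuple(paths)


def read_instances(in_dir, pixel_size_nm: float | None = None) -> InstanceMaps:
    in_dir = Path(in_dir)
    axon = tifffile.imread(in_dir / "axon_labels.tif")
    myelin = tifffile.imread(in_dir / "myelin_labels.tif")
    if pixel_size_nm is None:
        sidecar = _sidecar_path(in_dir / "labels.tif")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no pixel size given and no sidecar found at {sidecar}"
            )
        pixel_size_nm = json.loads(sidecar.read_text())["pixel_size_nm"]
    return InstanceMaps(axon, myelin, pixel_size_nm)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise KeyError(
                f"{path} is missing required column(s): {', '.join(missing)}"
            )
    return df


def write_posterior(post: GEVPosterior, path) -> Path:
    """Posterior draws as a long CSV: chain, draw, mu, sigma, xi."""
    rows = {
        "chain": np.repeat(np.arange(post.chain_count), post.draw_count),
        "draw": np.tile(np.arange(post.draw_count), post.chain_count),
    }
    for name in ("mu", "sigma", "xi"):
        rows[name] = post.samples[name].reshape(-1)
    return write_table(pd.DataFrame(rows), path)


def read_posterior(path) -> pd.DataFrame:
    return read_table(path, required_columns=["chain", "draw", "mu", "sigma", "xi"])


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
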