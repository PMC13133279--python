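"""Reading and writing the on-disk interchange formats.

Images travel as multi-page TIFF with a fixed page order (DAPI, ACKR1,
CD34, CD36, KDR, LAMB1, MADCAM1, KRT) plus a JSON sidecar carrying the
pixel size and ids; ground truth as JSON (per-vessel records) plus an
integer label TIFF; tables as CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from vesselphen.preprocess import CHANNELS, BinaryMask, ChannelStack
from vesselphen.simulate.core import GroundTruth


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Multi-page TIFF (fixed page order) + ``<path>.json`` sidecar."""
    path = Path(path)
    pages = np.stack([stack.channels[c] for c in CHANNELS])
    tifffile.imwrite(
        path,
        pages,
        resolution=(1e4 / stack.pixel_size, 1e4 / stack.pixel_size),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX", "channels": list(CHANNELS)},
    )
    sidecar = {
        "core_id": stack.core_id,
        "batch_id": stack.batch_id,
        "pixel_size_um": stack.pixel_size,
        "channels": list(CHANNELS),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    channels = {c: pages[i] for i, c in enumerate(sidecar["channels"])}
    return ChannelStack(
        channels=channels,
        pixel_size=sidecar["pixel_size_um"],
        core_id=sidecar["core_id"],
        batch_id=sidecar["batch_id"],
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Single-page 8-bit TIFF + JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.data.astype(np.uint8) * 255)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"provenance": list(mask.provenance)}, indent=1)
    )


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    data = tifffile.imread(path) > 0
    prov: tuple[str, ...] = ()
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        prov = tuple(json.loads(sidecar.read_text())["provenance"])
    return BinaryMask(data, prov)


def write_ground_truth(truth: GroundTruth, stem: str | Path) -> None:
    """``<stem>.json`` per-vessel records + ``<stem>_labels.tif`` ids."""
    stem = Path(stem)
    records = [
        {
            "vessel_id": int(v.vessel_id),
            "class_label": v.class_label,
            "marker_flags": {k: bool(f) for k, f in v.marker_flags.items()},
            "bbox": [int(b) for b in v.bbox],
        }
        for v in truth.vessels
    ]
    payload = {
        "vessels": records,
        "config": _config_dict(truth.config),
    }
    Path(f"{stem}.json").write_text(json.dumps(payload, indent=1))
    tifffile.imwrite(f"{stem}_labels.tif", truth.label_image.astype(np.int32))


def _config_dict(config) -> dict:
    d = asdict(config)
    return {k: v for k, v in d.items() if not isinstance(v, np.ndarray)}


def write_config(config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_config_dict(config), indent=1, default=str))
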