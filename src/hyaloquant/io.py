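"""File I/O: multi-channel TIFF images with YAML channel maps, object
tables, and simple JSON/CSV export helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import FlatmountImage, NucleusRecord, PunctumRecord
from .vessel_topology import SegmentCall

__all__ = [
    "read_channel_config",
    "read_flatmount",
    "write_flatmount",
    "nuclei_table",
    "puncta_table",
    "segment_table",
    "write_json",
]


def read_channel_config(path) -> dict:
    """Read a YAML config mapping channel index → name plus ``pixel_size_um``."""
    cfg = yaml.safe_load(Path(path).read_text())
    if "channels" not in cfg or "pixel_size_um" not in cfg:
        raise ValueError("channel config needs 'channels' and 'pixel_size_um' keys")
    return cfg


def read_flatmount(image_path, config) -> FlatmountImage:
    """Load a multi-channel TIFF as a :class:`FlatmountImage`.

    ``config`` is a path to, or dict from, :func:`read_channel_config`;
    its ``channels`` map assigns semantic names to channel indices of the
    first TIFF axis (a single-channel image may omit the axis).
    """
    if not isinstance(config, dict):
        config = read_channel_config(config)
    arr = tifffile.imread(str(image_path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, Y, X) image, got shape {arr.shape}")
    channels = {}
    for idx, name in config["channels"].items():
        idx = int(idx)
        if idx >= arr.shape[0]:
            raise ValueError(
                f"channel index {idx} ({name!r}) out of range for image with "
                f"{arr.shape[0]} channels"
            )
        channels[str(name)] = arr[idx].astype(float)
    return FlatmountImage(
        channels=channels,
        pixel_size=float(config["pixel_size_um"]),
        metadata={"source": str(image_path)},
    )


def write_flatmount(image: FlatmountImage, path) -> list[str]:
    """Write channels as a (C, Y, X) TIFF; returns the channel order."""
    names = sorted(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    return names


def nuclei_table(nuclei: Sequence[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for n in nuclei:
        row = {
            "nucleus_id": n.nucleus_id,
            "centroid_row": n.centroid[0],
            "centroid_col": n.centroid[1],
            "area_um2": n.area_um2,
            "perimeter_um": n.perimeter_um,
            "circularity": n.circularity,
            "cell_class": n.cell_class,
        }
        for marker, value in n.marker_intensities.items():
            row[f"intensity_{marker}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def puncta_table(puncta: Sequence[PunctumRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "punctum_id": p.punctum_id,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "area_um2": p.area_um2,
                "location_class": p.location_class,
                "segment_id": p.segment_id,
            }
            for p in puncta
        ]
    )


def segment_table(calls: Sequence[SegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "edge_id": c.edge_id,
                "status": c.status,
                "puncta_count": c.puncta_count,
                "cd31_continuity": c.cd31_continuity,
                "cluster_linearity": c.cluster_linearity,
            }
            for c in calls
        ]
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
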