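"""Disk formats: multi-page TIFF stacks with YAML channel sidecars, 16-bit
label TIFFs, and CSV tables for puncta / truth / summaries."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, PunctaRecord, puncta_to_frame
from .roi import load_label_mask, write_label_mask  # noqa: F401 (re-export)
from .scenes import SceneTruth


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".channels.yaml")


def write_stack(stack: ImageStack, path) -> Path:
    """Write one stack as a multi-page TIFF (one page per channel) plus a
    YAML sidecar recording channel order and pixel calibration."""
    path = Path(path)
    names = list(stack.channels)
    pages = np.stack([np.asarray(stack.channels[n], dtype=np.float32)
                      for n in names])
    tifffile.imwrite(str(path), pages)
    sidecar = {
        "channels": names,
        "pixel_size_um": float(stack.pixel_size),
        "metadata": {k: v for k, v in stack.metadata.items()
                     if isinstance(v, (str, int, float, bool))},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_stack(path, channel_map: dict | list | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Channel names come from the YAML sidecar written by :func:`write_stack`
    or, failing that, from ``channel_map`` (list of names in page order, or
    a dict with ``channels`` / ``pixel_size_um`` keys). Page count must
    match the channel list.
    """
    path = Path(path)
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    names = None
    pixel_size = None
    metadata: dict = {"source": str(path)}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = yaml.safe_load(sidecar.read_text())
        names = info.get("channels")
        pixel_size = info.get("pixel_size_um")
        metadata.update(info.get("metadata") or {})
    if channel_map is not None:
        if isinstance(channel_map, dict):
            names = channel_map.get("channels", names)
            pixel_size = channel_map.get("pixel_size_um", pixel_size)
        else:
            names = list(channel_map)
    if names is None:
        raise ValueError(f"{path}: no channel map (sidecar missing)")
    if len(names) != pages.shape[0]:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages but {len(names)} channels mapped"
        )
    if pixel_size is None:
        raise ValueError(f"{path}: pixel_size_um not provided")
    channels = {n: pages[i].astype(np.float64) for i, n in enumerate(names)}
    return ImageStack(channels=channels, pixel_size=float(pixel_size),
                      metadata=metadata)


def write_truth(truth: SceneTruth, csv_path, roi_tiff_path=None) -> Path:
    """Write ground-truth puncta as CSV (one row per punctum) and optionally
    the ROI label mask as 16-bit TIFF."""
    csv_path = Path(csv_path)
    truth.puncta.to_csv(csv_path, index=False)
    if roi_tiff_path is not None:
        write_label_mask(truth.roi_labels, roi_tiff_path)
    return csv_path


def write_puncta_csv(records: list[PunctaRecord], path) -> Path:
    path = Path(path)
    puncta_to_frame(records).to_csv(path, index=False)
    return path


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
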