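"""Shared data containers for reporter-image quantitation.

The tandem mCherry-GFP reporter marks mitochondria (mito-QC) or
autophagosomes (auto-QC) in two channels; lysosomal acidification quenches
GFP, so acidified mitolysosomes/autolysosomes appear as mCherry-only
("red-not-green") puncta. These containers carry one field of view
(:class:`ImageStack`), binary/labelled masks, and per-punctum measurements
(:class:`PunctaRecord`) through the detection chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: channel names understood by the pipeline
CHANNEL_NAMES = ("mCherry", "GFP", "marker", "nuclei")

#: punctum classes: acidified (red-only), differentially acidified lysosome
#: (double-positive), and LAMP1-confirmed DAL (triple-positive)
PUNCTA_CLASSES = ("red_only", "double_positive", "triple_positive")


@dataclass
class ImageStack:
    """Named channels of one field of view plus pixel calibration.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D intensity array. All channels must share
        one shape; names must come from :data:`CHANNEL_NAMES`.
    pixel_size
        Lateral calibration in µm per pixel (> 0).
    metadata
        Free-form provenance (source path, field id, condition ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name in self.channels:
            if name not in CHANNEL_NAMES:
                raise ValueError(
                    f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}"
                )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def field_area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size**2


@dataclass
class BinaryMask:
    """Boolean foreground mask with thresholding provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def __array__(self, dtype=None, copy=None):
        a = self.mask
        return a.astype(dtype) if dtype is not None else a


@dataclass
class LabelMask:
    """Integer-labelled ROI image; 0 is background.

    Labels need not be contiguous. ``names`` optionally maps a label to a
    human-readable ROI name (cell id, anatomical region).
    """

    labels: np.ndarray
    pixel_size: float
    names: dict[int, str] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if np.issubdtype(labels.dtype, np.bool_):
                labels = labels.astype(np.int32)
            else:
                raise ValueError("label mask must be integer-valued")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def labels_present(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def area_table(self) -> pd.DataFrame:
        """Per-label area in µm² (pixel count x pixel_size²)."""
        labs = self.labels_present()
        counts = np.array(
            [int((self.labels == lab).sum()) for lab in labs], dtype=float
        )
        return pd.DataFrame(
            {
                "label": labs.astype(int),
                "area_um2": counts * self.pixel_size**2,
                "name": [self.names.get(int(lab), "") for lab in labs],
            }
        )

    def total_area_um2(self) -> float:
        return float((self.labels > 0).sum()) * self.pixel_size**2

    def as_bool(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class PunctaRecord:
    """One detected punctum.

    ``coords`` holds the footprint as an (n, 2) array of (row, col) pixel
    indices; coordinates are 0-based and pixel-centred. Morphometry is in
    physical units (µm / µm²); ``form_factor`` is 4πA/P² (1 for a disk).
    """

    id: int
    centroid: tuple[float, float]  # (row, col), pixels
    area_um2: float
    equivalent_diameter_um: float
    eccentricity: float
    form_factor: float
    coords: np.ndarray
    mean_intensity: dict[str, float] = field(default_factory=dict)
    gfp_overlap_fraction: float = 0.0
    marker_overlap_fraction: float = 0.0
    cls: Optional[str] = None
    roi_label: int = 0


def puncta_to_frame(records: list[PunctaRecord]) -> pd.DataFrame:
    """Tabulate puncta records (one row per punctum; footprints dropped)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area_um2": r.area_um2,
            "equivalent_diameter_um": r.equivalent_diameter_um,
            "eccentricity": r.eccentricity,
            "form_factor": r.form_factor,
            "gfp_overlap_fraction": r.gfp_overlap_fraction,
            "marker_overlap_fraction": r.marker_overlap_fraction,
            "class": r.cls,
            "roi_label": r.roi_label,
        }
        for ch, v in r.mean_intensity.items():
            row[f"mean_intensity_{ch}"] = v
        rows.append(row)
    columns = [
        "id", "centroid_row", "centroid_col", "area_um2",
        "equivalent_diameter_um", "eccentricity", "form_factor",
        "gfp_overlap_fraction", "marker_overlap_fraction", "class",
        "roi_label",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)
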