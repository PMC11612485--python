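"""ROI label masks: import, hole filling, and an intensity-based fallback.

Cell-type quantitation normalizes puncta counts to cell area, so a labelled
ROI mask is needed per field. Externally produced masks (e.g. from a pixel
classifier or manual outlines) are imported verbatim; when none exists, a
simple threshold of the summed reporter signal provides a fallback
segmentation. Imported masks take precedence over the fallback.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure

from .detect import otsu_threshold
from .core import ImageStack, LabelMask

MIN_CELL_AREA_UM2 = 20.0


def load_label_mask(path, calibration: float) -> LabelMask:
    """Read an integer label image (TIFF) as a :class:`LabelMask`."""
    arr = tifffile.imread(str(path))
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int32)
        else:
            raise ValueError(f"{path}: non-integer pixel values in label mask")
    return LabelMask(arr.astype(np.int32), pixel_size=calibration)


def write_label_mask(mask: LabelMask, path) -> Path:
    """Write labels as a single-page 16-bit TIFF."""
    path = Path(path)
    labels = mask.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))
    return path


def fill_holes(mask: LabelMask) -> LabelMask:
    """Assign enclosed background holes to their single surrounding label.

    A background component that does not touch the image border and whose
    entire boundary neighbourhood carries one label is filled with that
    label; holes bordered by two or more labels are ambiguous and left
    unfilled. Idempotent.
    """
    labels = mask.labels.copy()
    bg = labels == 0
    bg_comp = measure.label(bg, connectivity=1)
    h, w = labels.shape
    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_comps = set(np.unique(bg_comp[border & bg]))
    for comp in np.unique(bg_comp):
        if comp == 0 or comp in border_comps:
            continue
        hole = bg_comp == comp
        ring = ndi.binary_dilation(hole, structure=np.ones((3, 3))) & ~hole
        owners = np.unique(labels[ring])
        owners = owners[owners > 0]
        if owners.size == 1:
            labels[hole] = owners[0]
    return LabelMask(labels, pixel_size=mask.pixel_size,
                     names=dict(mask.names))


def segment_rois_intensity(stack: ImageStack, mode: str = "cell_body") -> LabelMask:
    """Fallback ROI segmentation from the summed reporter signal.

    ``cell_body``: Otsu-threshold mCherry+GFP (smoothed), fill holes, drop
    objects below 20 µm², label each remaining object. ``tissue_region``:
    the whole thresholded region becomes one label.
    """
    if mode not in ("cell_body", "tissue_region"):
        raise ValueError(f"unknown mode {mode!r}")
    for ch in ("mCherry", "GFP"):
        if ch not in stack.channels:
            raise ValueError(f"stack lacks required channel {ch!r}")
    s = stack.pixel_size
    total = stack.channels["mCherry"].astype(float) + stack.channels["GFP"]
    sm = ndi.gaussian_filter(total, 2.0)
    if np.all(sm == sm.flat[0]):
        warnings.warn("no foreground separable", stacklevel=2)
        return LabelMask(np.zeros(sm.shape, dtype=np.int32), pixel_size=s)
    thr = otsu_threshold(sm)
    fg = ndi.binary_fill_holes(sm > thr)
    if not fg.any():
        warnings.warn("no foreground above threshold", stacklevel=2)
        return LabelMask(np.zeros(sm.shape, dtype=np.int32), pixel_size=s)
    if mode == "tissue_region":
        return LabelMask(fg.astype(np.int32), pixel_size=s)
    labels = measure.label(fg, connectivity=2)
    min_px = MIN_CELL_AREA_UM2 / s**2
    out = np.zeros_like(labels)
    next_label = 1
    for props in measure.regionprops(labels):
        if props.num_pixels >= min_px:
            out[labels == props.label] = next_label
            next_label += 1
    if next_label == 1:
        warnings.warn("no object above minimum cell area", stacklevel=2)
    return LabelMask(out.astype(np.int32), pixel_size=s)
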