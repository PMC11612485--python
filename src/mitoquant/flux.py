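"""In vitro flux assay: per-cell red-not-green spot counting.

High-content pipeline for cultured reporter cells: segment nuclei from the
Hoechst channel, grow each nucleus into the surrounding GFP-background
cytoplasm, detect spots per channel with a Laplacian-of-Gaussian blob
response, classify red-not-green spots by masking against the green spot
response, and express per-cell counts as a ratio to the control-condition
mean. Treatment with a V-ATPase inhibitor (bafilomycin A1) blocks
acidification and hence red-only spot formation — the flux control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, segmentation
from skimage.feature import peak_local_max

from .detect import otsu_threshold
from .core import ImageStack, LabelMask

MIN_NUCLEUS_AREA_UM2 = 10.0


@dataclass
class CellRecord:
    """Per-cell spot counts and control-normalized ratio."""

    cell_id: int
    nucleus_label: int
    cytoplasm_area_um2: float
    red_only: int
    double_positive: int
    condition: str = ""
    field_id: int = 0
    ratio_to_control: float | None = None


@dataclass(frozen=True)
class SpotConfig:
    """Spot-detection parameters (LoG response + robust threshold)."""

    spot_sigma_um: float = 0.35  # ~ punctum radius
    k_mad: float = 5.0  # response threshold in MADs
    overlap_cutoff: float = 0.5
    smoothing_sigma_px: float = 1.0


def segment_nuclei(nuclei_channel: np.ndarray, pixel_size: float) -> LabelMask:
    """Label nuclei; touching nuclei are split by distance-transform watershed."""
    img = ndi.gaussian_filter(np.asarray(nuclei_channel, dtype=float), 2.0)
    if np.all(img == img.flat[0]):
        warnings.warn("blank nuclei channel: no nuclei found", stacklevel=2)
        return LabelMask(np.zeros(img.shape, dtype=np.int32),
                         pixel_size=pixel_size)
    fg = ndi.binary_fill_holes(img > otsu_threshold(img))
    min_px = MIN_NUCLEUS_AREA_UM2 / pixel_size**2
    lab = measure.label(fg, connectivity=2)
    keep = np.zeros_like(fg)
    for props in measure.regionprops(lab):
        if props.num_pixels >= min_px:
            keep[lab == props.label] = True
    if not keep.any():
        warnings.warn("no nucleus above minimum area", stacklevel=2)
        return LabelMask(np.zeros(img.shape, dtype=np.int32),
                         pixel_size=pixel_size)
    dist = ndi.distance_transform_edt(keep)
    min_sep = max(1, int(round(3.0 / pixel_size)))  # 3 µm between centres
    peaks = peak_local_max(dist, min_distance=min_sep, labels=keep,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = segmentation.watershed(-dist, markers, mask=keep)
    return LabelMask(labels.astype(np.int32), pixel_size=pixel_size)


def cytoplasm_regions(nuclei: LabelMask, gfp_channel: np.ndarray) -> LabelMask:
    """Grow nuclei into the thresholded GFP background, split by nearest nucleus.

    The cytoplasm of each cell is the smoothed-GFP foreground assigned to its
    nearest nucleus, minus the nucleus footprint itself. Nuclei with no
    surrounding signal get an empty cytoplasm and are listed in
    ``result.info['empty_cytoplasm']``.
    """
    img = ndi.gaussian_filter(np.asarray(gfp_channel, dtype=float), 2.0)
    nuc = nuclei.labels
    if np.all(img == img.flat[0]):
        fg = np.zeros(img.shape, dtype=bool)
    else:
        fg = img > otsu_threshold(img)
    fg = ndi.binary_fill_holes(fg | (nuc > 0))
    # nearest-nucleus partition of the foreground
    _, (ir, ic) = ndi.distance_transform_edt(nuc == 0, return_indices=True)
    partition = nuc[ir, ic]
    cyt = np.where(fg & (nuc == 0), partition, 0).astype(np.int32)
    present = set(np.unique(cyt)) - {0}
    empty = [int(lab) for lab in np.unique(nuc) if lab > 0 and lab not in present]
    return LabelMask(cyt, pixel_size=nuclei.pixel_size,
                     info={"empty_cytoplasm": empty})


def _log_response(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negative LoG: bright blobs give positive peaks."""
    return -(sigma_px**2) * ndi.gaussian_laplace(
        np.asarray(img, dtype=float), sigma_px
    )


def _mad_threshold(resp: np.ndarray, k: float) -> float:
    med = np.median(resp)
    mad = np.median(np.abs(resp - med)) * 1.4826
    return float(med + k * mad)


def detect_spots(
    channel: np.ndarray,
    pixel_size: float,
    config: SpotConfig = SpotConfig(),
    stats_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """LoG spot detection on one channel.

    Returns (peak coordinates (n, 2), boolean response mask, threshold).
    Peaks are local maxima of the blob response above k MADs of the
    response distribution; ``stats_mask`` restricts the threshold statistics
    to a region (e.g. the cell foreground, where shot noise is higher than
    in the empty background).
    """
    sigma_px = max(config.spot_sigma_um / pixel_size, 1.0)
    resp = _log_response(channel, sigma_px)
    stat_vals = resp if stats_mask is None else resp[np.asarray(stats_mask, bool)]
    thr = _mad_threshold(stat_vals, config.k_mad)
    min_dist = max(1, int(round(2 * sigma_px)))
    peaks = peak_local_max(resp, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    return peaks, resp > thr, thr


def spots_per_cell(
    stack: ImageStack,
    cells: LabelMask,
    config: SpotConfig = SpotConfig(),
) -> list[CellRecord]:
    """Count red-only and double-positive spots inside each cytoplasm label.

    A red-channel spot is red-only when the green spot-response mask covers
    less than ``overlap_cutoff`` of a small disk around it; otherwise it is
    double-positive. Spots outside every cytoplasm label are discarded; each
    spot is assigned to exactly one cell (the label under its peak).
    """
    if not cells.labels_present().size:
        raise ValueError("cells label mask is empty")
    s = stack.pixel_size
    red = stack.channels["mCherry"]
    green = stack.channels["GFP"]
    fg = cells.labels > 0
    peaks, _, _ = detect_spots(red, s, config, stats_mask=fg)
    _, gmask, _ = detect_spots(green, s, config, stats_mask=fg)
    rad = max(1, int(round(config.spot_sigma_um / s)))
    dd = np.arange(-rad, rad + 1)
    dy, dx = np.meshgrid(dd, dd, indexing="ij")
    disk = (dy**2 + dx**2) <= rad**2
    dy, dx = dy[disk], dx[disk]
    h, w = red.shape
    counts: dict[int, list[int]] = {
        int(lab): [0, 0] for lab in cells.labels_present()
    }
    for r, c in peaks:
        lab = int(cells.labels[r, c])
        if lab == 0:
            continue
        rr = np.clip(r + dy, 0, h - 1)
        cc = np.clip(c + dx, 0, w - 1)
        gfrac = float(gmask[rr, cc].mean())
        if gfrac < config.overlap_cutoff:
            counts[lab][0] += 1
        else:
            counts[lab][1] += 1
    areas = {
        int(row.label): row.area_um2
        for row in cells.area_table().itertuples()
    }
    condition = stack.metadata.get("condition", "")
    field_id = stack.metadata.get("field", 0)
    return [
        CellRecord(
            cell_id=lab,
            nucleus_label=lab,
            cytoplasm_area_um2=areas[lab],
            red_only=counts[lab][0],
            double_positive=counts[lab][1],
            condition=condition,
            field_id=field_id,
        )
        for lab in sorted(counts)
    ]


def normalize_to_control(
    records: list[CellRecord],
    control_condition: str,
    measure_attr: str = "red_only",
) -> list[CellRecord]:
    """Fill ``ratio_to_control`` = per-cell count / mean control count."""
    control = [getattr(r, measure_attr) for r in records
               if r.condition == control_condition]
    if not control:
        raise ValueError(
            f"control condition {control_condition!r} has no cells"
        )
    mean = float(np.mean(control))
    if mean == 0:
        raise ValueError("control mean is zero; ratio undefined")
    out = []
    for r in records:
        rec = CellRecord(**{**r.__dict__})
        rec.ratio_to_control = getattr(r, measure_attr) / mean
        out.append(rec)
    return out


def cells_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
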