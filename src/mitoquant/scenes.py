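"""Synthetic tandem-reporter scenes with ground truth.

Emulates single-plane two-channel (mCherry / GFP, optional LAMP1-like marker
and nuclei) fluorescence fields from mito-QC / auto-QC style reporter
imaging:

* a "yellow" mitochondrial background network rendered identically into both
  reporter channels (outside acidic compartments the tandem tag fluoresces
  in both),
* red-only puncta — acidified mitolysosomes / autolysosomes, whose GFP is
  quenched — placed as a spatial Poisson process at a prescribed density per
  µm² of ROI,
* double-positive puncta — differentially acidified lysosomes (DALs), fused
  but not acidic enough to quench GFP — in both channels,
* Gaussian PSF blur, Poisson shot noise and Gaussian read noise.

Every scene is a pure function of (spec, seed) and returns the rendered
:class:`~mitoquant.core.ImageStack` together with a :class:`SceneTruth`
carrying the exact puncta list and ROI geometry, so the whole detection
chain is testable without any acquired data. Cohort presets calibrated to
published group-mean densities live in :func:`preset_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

from .core import ImageStack, LabelMask

ROI_KINDS = ("full_field", "soma", "soma_with_processes")

#: default intensity levels (arbitrary units on a 12-bit-like scale)
DEFAULT_INTENSITY = {
    "red_only": 500.0,
    "double_positive": 500.0,
    "network": 120.0,
    "marker": 300.0,
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic reporter field.

    Densities are in puncta per µm² of ROI; sizes in µm. A punctum is an
    isotropic Gaussian spot whose quoted ``diameter`` is the 1/e² width
    (sigma = diameter / 4); diameters are lognormal with the given mean and
    sd of the distribution.
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.108  # µm/px; 60x water-immersion scale
    roi_kind: str = "full_field"
    roi_area_target: Optional[float] = None  # µm²; None = whole field
    network_density: float = 0.08  # fill fraction of ROI
    red_only_density: float = 0.0  # puncta/µm²
    double_positive_density: float = 0.0  # puncta/µm² (DALs)
    marker_channel: bool = False
    nuclei_channel: bool = False
    punctum_diameter_mean: float = 0.8  # µm
    punctum_diameter_sd: float = 0.3  # µm
    soma_fill_level: float = 60.0  # diffuse cytosolic signal in soma ROIs
    intensity: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    psf_sigma: float = 0.12  # µm
    background_level: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        h, w = self.field_shape
        if h <= 0 or w <= 0:
            raise ValueError("field_shape: dimensions must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size: must be > 0")
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"roi_kind: {self.roi_kind!r} not in {ROI_KINDS}")
        for name in ("network_density", "red_only_density",
                     "double_positive_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.network_density > 1:
            raise ValueError("network_density: fill fraction must be <= 1")
        if not self.punctum_diameter_mean > 0:
            raise ValueError("punctum_diameter_mean: must be > 0")
        if self.punctum_diameter_sd < 0:
            raise ValueError("punctum_diameter_sd: must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma: must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd: must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level: must be >= 0")
        if self.roi_area_target is not None:
            if not self.roi_area_target > 0:
                raise ValueError("roi_area_target: must be > 0")
            if self.roi_area_target > self.field_area_um2 + 1e-9:
                raise ValueError(
                    "roi_area_target: exceeds field area "
                    f"({self.roi_area_target:.1f} > {self.field_area_um2:.1f} µm²)"
                )

    @property
    def field_area_um2(self) -> float:
        h, w = self.field_shape
        return h * w * self.pixel_size**2


@dataclass
class SceneTruth:
    """Ground truth of one rendered scene.

    ``puncta`` has one row per punctum (x_um/y_um image coordinates,
    diameter_um, class). ``densities`` are realized count / realized ROI
    area, exactly.
    """

    puncta: pd.DataFrame
    roi_labels: LabelMask
    roi_area_um2: float
    counts: dict[str, int]
    densities: dict[str, float]


# ---------------------------------------------------------------------------
# geometry helpers


def _smooth_circular(x: np.ndarray, passes: int = 3) -> np.ndarray:
    for _ in range(passes):
        x = (np.roll(x, 1) + x + np.roll(x, -1)) / 3.0
    return x


def _soma_polygon_mask(shape, pixel_size, area_um2, rng, n_vertices=48):
    """Star-convex blob of approximately ``area_um2`` centred in the field."""
    h, w = shape
    area_px = area_um2 / pixel_size**2
    base_r = math.sqrt(area_px / math.pi)
    wobble = _smooth_circular(rng.normal(0.0, 1.0, n_vertices))
    wobble = wobble / (np.abs(wobble).max() + 1e-12) * 0.25
    radii = base_r * (1.0 + wobble)
    max_r = radii.max()
    if max_r > min(h, w) / 2 - 2:
        raise ValueError(
            "roi_area_target: soma of this area does not fit in the field"
        )
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)

    def rasterize(scale):
        rr = cy + scale * radii * np.sin(ang)
        cc = cx + scale * radii * np.cos(ang)
        pr, pc = skdraw.polygon(rr, cc, shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[pr, pc] = True
        return m

    mask = rasterize(1.0)
    got = mask.sum()
    if got > 0:  # one area-correcting redraw
        mask = rasterize(math.sqrt(area_px / got))
    return mask, (cy, cx), base_r


def _add_processes(mask, center, base_r, shape, pixel_size, rng):
    """Append 2-5 tapering branches radiating from the soma."""
    h, w = shape
    n_branches = int(rng.integers(2, 6))
    out = mask.copy()
    for _ in range(n_branches):
        theta = rng.uniform(0, 2 * math.pi)
        r, c = center
        r += base_r * math.sin(theta)
        c += base_r * math.cos(theta)
        length_um = rng.uniform(5.0, 15.0)
        n_seg = 3
        seg_len = length_um / pixel_size / n_seg
        for k, rad in enumerate([2, 1, 0][:n_seg]):
            theta += rng.normal(0, 0.3)
            r2 = r + seg_len * math.sin(theta)
            c2 = c + seg_len * math.cos(theta)
            rr, cc = skdraw.line(
                int(round(np.clip(r, 0, h - 1))),
                int(round(np.clip(c, 0, w - 1))),
                int(round(np.clip(r2, 0, h - 1))),
                int(round(np.clip(c2, 0, w - 1))),
            )
            seg = np.zeros(shape, dtype=bool)
            seg[rr, cc] = True
            if rad > 0:
                seg = ndi.binary_dilation(seg, structure=morphology.disk(rad))
            out |= seg
            r, c = r2, c2
    return out


def _make_roi(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.field_shape
    if spec.roi_kind == "full_field":
        return np.ones((h, w), dtype=bool)
    area = spec.roi_area_target
    if area is None:
        area = 0.2 * spec.field_area_um2
    mask, center, base_r = _soma_polygon_mask(
        (h, w), spec.pixel_size, area, rng
    )
    if spec.roi_kind == "soma_with_processes":
        mask = _add_processes(mask, center, base_r, (h, w), spec.pixel_size, rng)
    if not mask.any():
        raise ValueError("roi_area_target: ROI rasterized to zero pixels")
    return mask


def _network_mask(roi, pixel_size, fill_fraction, rng):
    """Random-walk filaments dilated to ~0.2 µm half-width, clipped to ROI.

    Walks are parameterized in µm so network geometry is approximately
    resolution-independent.
    """
    h, w = roi.shape
    if fill_fraction <= 0:
        return np.zeros_like(roi)
    target_px = fill_fraction * roi.sum()
    rad_px = max(1, int(round(0.12 / pixel_size)))
    # a dilated walk covers roughly (2*rad+1) px per unit length
    target_centerline = target_px / (2 * rad_px + 1)
    roi_idx = np.flatnonzero(roi)
    net = np.zeros((h, w), dtype=bool)
    step_um = 0.5
    step_px = step_um / pixel_size
    guard = 0
    while net.sum() < target_centerline and guard < 400:
        guard += 1
        start = roi_idx[rng.integers(0, roi_idx.size)]
        r, c = np.unravel_index(start, (h, w))
        r, c = float(r), float(c)
        theta = rng.uniform(0, 2 * math.pi)
        for _ in range(40):
            theta += rng.normal(0, 0.4)
            r2 = r + step_px * math.sin(theta)
            c2 = c + step_px * math.cos(theta)
            rr, cc = skdraw.line(
                int(round(np.clip(r, 0, h - 1))),
                int(round(np.clip(c, 0, w - 1))),
                int(round(np.clip(r2, 0, h - 1))),
                int(round(np.clip(c2, 0, w - 1))),
            )
            net[rr, cc] = True
            r, c = r2, c2
            if not (0 <= r < h and 0 <= c < w):
                break
    net = ndi.binary_dilation(net, structure=morphology.disk(rad_px))
    return net & roi


def _sample_positions_um(roi, pixel_size, n, rng, max_tries=200):
    """Uniform positions (in µm) over the ROI by rejection sampling."""
    h, w = roi.shape
    out = np.empty((n, 2), dtype=float)  # (y_um, x_um)
    filled = 0
    full = roi.all()
    for _ in range(max_tries):
        if filled >= n:
            break
        m = n - filled
        ys = rng.uniform(0, h * pixel_size, m)
        xs = rng.uniform(0, w * pixel_size, m)
        if full:
            keep = np.ones(m, dtype=bool)
        else:
            ri = np.minimum((ys / pixel_size).astype(int), h - 1)
            ci = np.minimum((xs / pixel_size).astype(int), w - 1)
            keep = roi[ri, ci]
        k = int(keep.sum())
        out[filled : filled + k, 0] = ys[keep]
        out[filled : filled + k, 1] = xs[keep]
        filled += k
    if filled < n:
        raise RuntimeError("could not place puncta inside ROI")
    return out


def _sample_diameters(mean_um, sd_um, n, rng):
    if n == 0:
        return np.empty(0)
    if sd_um == 0:
        return np.full(n, mean_um)
    sigma2 = math.log(1.0 + (sd_um / mean_um) ** 2)
    mu = math.log(mean_um) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _add_spots(img, positions_um, diameters_um, amplitude, pixel_size):
    """Accumulate Gaussian spots (sigma = diameter/4) into ``img`` in place."""
    h, w = img.shape
    for (y_um, x_um), d in zip(positions_um, diameters_um):
        sigma = max(d / 4.0 / pixel_size, 0.5)
        r = y_um / pixel_size - 0.5  # pixel-centred coordinates
        c = x_um / pixel_size - 0.5
        ext = int(math.ceil(4 * sigma))
        r0, r1 = max(0, int(r) - ext), min(h, int(r) + ext + 1)
        c0, c1 = max(0, int(c) - ext), min(w, int(c) + ext + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - r
        xx = np.arange(c0, c1)[None, :] - c
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -(yy**2 + xx**2) / (2 * sigma**2)
        )


# ---------------------------------------------------------------------------
# scene rendering


def render_scene(spec: SceneSpec, seed: int) -> tuple[ImageStack, SceneTruth]:
    """Render one synthetic reporter field.

    Deterministic: identical (spec, seed) yields bit-identical arrays. The
    number of puncta of each class is Poisson(density x ROI area); positions
    are uniform over the ROI.
    """
    if not isinstance(spec, SceneSpec):
        raise TypeError("spec must be a SceneSpec")
    rng = np.random.default_rng(seed)
    h, w = spec.field_shape
    s = spec.pixel_size

    roi = _make_roi(spec, rng)
    roi_area = float(roi.sum()) * s**2

    net = _network_mask(roi, s, spec.network_density, rng)

    n_red = int(rng.poisson(spec.red_only_density * roi_area))
    n_dp = int(rng.poisson(spec.double_positive_density * roi_area))
    pos_red = _sample_positions_um(roi, s, n_red, rng)
    pos_dp = _sample_positions_um(roi, s, n_dp, rng)
    dia_red = _sample_diameters(
        spec.punctum_diameter_mean, spec.punctum_diameter_sd, n_red, rng
    )
    dia_dp = _sample_diameters(
        spec.punctum_diameter_mean, spec.punctum_diameter_sd, n_dp, rng
    )

    inten = {**DEFAULT_INTENSITY, **spec.intensity}
    # diffuse cytosolic reporter signal fills soma-like ROIs in both channels
    fill = np.zeros((h, w))
    if spec.roi_kind != "full_field" and spec.soma_fill_level > 0:
        fill = roi.astype(float) * spec.soma_fill_level
    struct_mc = net.astype(float) * inten["network"] + fill
    struct_gfp = net.astype(float) * inten["network"] + fill
    _add_spots(struct_mc, pos_red, dia_red, inten["red_only"], s)
    _add_spots(struct_mc, pos_dp, dia_dp, inten["double_positive"], s)
    _add_spots(struct_gfp, pos_dp, dia_dp, inten["double_positive"], s)

    channels: dict[str, np.ndarray] = {}
    structures = [("mCherry", struct_mc), ("GFP", struct_gfp)]
    if spec.marker_channel:
        struct_mk = np.zeros((h, w))
        _add_spots(struct_mk, pos_red, dia_red, inten["marker"], s)
        _add_spots(struct_mk, pos_dp, dia_dp, inten["marker"], s)
        structures.append(("marker", struct_mk))

    psf_px = spec.psf_sigma / s
    for name, struct in structures:
        expected = spec.background_level + (
            ndi.gaussian_filter(struct, psf_px) if psf_px > 0 else struct
        )
        img = (
            rng.poisson(expected).astype(float)
            if spec.shot_noise
            else expected.copy()
        )
        if spec.read_noise_sd > 0:
            img += rng.normal(0.0, spec.read_noise_sd, img.shape)
        channels[name] = img

    rows = []
    for (y, x), d in zip(pos_red, dia_red):
        rows.append((x, y, d, "red_only"))
    for (y, x), d in zip(pos_dp, dia_dp):
        rows.append((x, y, d, "double_positive"))
    puncta = pd.DataFrame(rows, columns=["x_um", "y_um", "diameter_um", "class"])

    counts = {"red_only": n_red, "double_positive": n_dp}
    truth = SceneTruth(
        puncta=puncta,
        roi_labels=LabelMask(roi.astype(np.int32), pixel_size=s),
        roi_area_um2=roi_area,
        counts=counts,
        densities={k: v / roi_area for k, v in counts.items()},
    )
    stack = ImageStack(channels=channels, pixel_size=s, metadata={"seed": seed})
    return stack, truth


# ---------------------------------------------------------------------------
# cohort presets


@dataclass(frozen=True)
class GroupLevels:
    """Per-age-group generator levels for one preset."""

    red_only_density: float  # puncta/µm² (the published quantity)
    double_positive_density: float  # DALs/µm² (unpublished; see methods note)
    punctum_diameter_mean: float  # µm


@dataclass(frozen=True)
class CohortPreset:
    """Named cohort condition: reporter, age groups and their densities.

    Attribute access by group name returns the group's red-only density, the
    published ratiometric index (e.g. ``preset.young`` -> 0.005).
    """

    name: str
    reporter: str  # "mito" or "auto"
    groups: dict[str, GroupLevels]
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance note must be non-empty")
        if not self.groups:
            raise ValueError("preset must define at least one group")

    def __getattr__(self, item: str) -> float:
        groups = object.__getattribute__(self, "groups")
        if item in groups:
            return groups[item].red_only_density
        raise AttributeError(item)

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)


def _levels(density, dal, diam=0.8):
    return GroupLevels(density, dal, diam)


def preset_table() -> dict[str, CohortPreset]:
    """Cohort presets calibrated to published group-mean densities.

    Red-only densities for the dopaminergic (A9/A10) and choroid-plexus
    presets are the printed group means in mitolysosomes or autolysosomes
    per µm². The Purkinje-cell, cerebellar-microglia and prefrontal-cortex
    presets were published as ratios only (2.3-fold, 5.4-fold, -40%); their
    young baselines are fixed generator choices and only the ratios are
    meaningful. Presets whose source reports an age-dependent mitolysosome
    size increase use a 1.5x geriatric diameter.
    """
    t = {}
    t["a9_mito"] = CohortPreset(
        "a9_mito", "mito",
        {"young": _levels(0.005, 0.002), "geriatric": _levels(0.018, 0.006)},
        "published A9 dopaminergic mitolysosome densities: young 0.005, "
        "geriatric 0.018 per µm²",
    )
    t["a10_mito"] = CohortPreset(
        "a10_mito", "mito",
        {"young": _levels(0.007, 0.002), "geriatric": _levels(0.008, 0.006)},
        "published A10 dopaminergic mitolysosome densities: young 0.007, "
        "geriatric 0.008 per µm²",
    )
    t["a9_auto"] = CohortPreset(
        "a9_auto", "auto",
        {"young": _levels(0.003, 0.002), "geriatric": _levels(0.002, 0.006)},
        "published A9 dopaminergic autolysosome densities: young 0.003, "
        "geriatric 0.002 per µm²",
    )
    t["a10_auto"] = CohortPreset(
        "a10_auto", "auto",
        {"young": _levels(0.005, 0.002), "geriatric": _levels(0.002, 0.006)},
        "published A10 dopaminergic autolysosome densities: young 0.005, "
        "geriatric 0.002 per µm²",
    )
    t["chp_auto"] = CohortPreset(
        "chp_auto", "auto",
        {"young": _levels(0.031, 0.002), "geriatric": _levels(0.027, 0.006)},
        "published choroid-plexus autolysosome densities: young 0.031, "
        "geriatric 0.027 per µm²",
    )
    t["pc_mito"] = CohortPreset(
        "pc_mito", "mito",
        {"young": _levels(0.010, 0.002),
         "geriatric": _levels(0.023, 0.006, diam=1.2)},
        "published 2.3-fold geriatric increase in Purkinje-cell mitolysosome "
        "density; young baseline 0.010 per µm² is a generator choice",
    )
    t["cb_microglia_mito"] = CohortPreset(
        "cb_microglia_mito", "mito",
        {"young": _levels(0.005, 0.002),
         "geriatric": _levels(0.027, 0.006, diam=1.2)},
        "published 5.4-fold geriatric enhancement of cerebellar-microglia "
        "mitophagy; young baseline 0.005 per µm² is a generator choice",
    )
    t["pfc_auto"] = CohortPreset(
        "pfc_auto", "auto",
        {"young": _levels(0.010, 0.002), "adult": _levels(0.006, 0.004)},
        "published 40% decrease of prefrontal-cortex autolysosome density "
        "between young and adult; young baseline 0.010 per µm² is a "
        "generator choice",
    )
    return t


#: between-subject lognormal coefficient of variation on densities
SUBJECT_CV = 0.10


@dataclass
class CohortBundle:
    """Rendered cohort: scenes plus subject/group bookkeeping."""

    scenes: list[tuple[ImageStack, SceneTruth]]
    metadata: pd.DataFrame  # image_id, group, subject, seed
    preset: CohortPreset


def _subject_multiplier(rng: np.random.Generator) -> float:
    """Mean-one lognormal subject effect with CV = SUBJECT_CV."""
    sigma2 = math.log(1.0 + SUBJECT_CV**2)
    return float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))


def make_cohort(
    preset: CohortPreset | str,
    n_subjects_per_group: int,
    images_per_subject: int,
    base_seed: int,
    scene_spec: SceneSpec | None = None,
) -> CohortBundle:
    """Simulate a cohort: groups x subjects x images of one preset.

    Per-image seeds derive deterministically from
    (base_seed, group index, subject index, image index) via numpy
    ``SeedSequence``; two calls with the same arguments return identical
    bundles. Each subject carries a mean-one lognormal density multiplier
    (between-animal variability).
    """
    if isinstance(preset, str):
        table = preset_table()
        if preset not in table:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(table)}"
            )
        preset = table[preset]
    if n_subjects_per_group < 2:
        raise ValueError("n_subjects_per_group must be >= 2")
    if images_per_subject < 1:
        raise ValueError("images_per_subject must be >= 1")
    if base_seed < 0:
        raise ValueError("base_seed must be non-negative")
    base = scene_spec if scene_spec is not None else SceneSpec()

    scenes = []
    meta = []
    image_id = 0
    for gi, (gname, levels) in enumerate(preset.groups.items()):
        for si in range(n_subjects_per_group):
            subj_rng = np.random.default_rng(
                np.random.SeedSequence([base_seed, gi, si])
            )
            mult = _subject_multiplier(subj_rng)
            spec = replace(
                base,
                red_only_density=levels.red_only_density * mult,
                double_positive_density=levels.double_positive_density * mult,
                punctum_diameter_mean=levels.punctum_diameter_mean,
            )
            for ii in range(images_per_subject):
                seed = int(
                    np.random.SeedSequence(
                        [base_seed, gi, si, ii]
                    ).generate_state(1)[0]
                )
                scenes.append(render_scene(spec, seed))
                meta.append(
                    {
                        "image_id": image_id,
                        "group": gname,
                        "subject": f"{gname}_s{si}",
                        "image_index": ii,
                        "seed": seed,
                        "reporter": preset.reporter,
                        "preset": preset.name,
                    }
                )
                image_id += 1
    return CohortBundle(
        scenes=scenes, metadata=pd.DataFrame(meta), preset=preset
    )


# ---------------------------------------------------------------------------
# flux-assay plates


@dataclass(frozen=True)
class FluxCondition:
    """One in vitro flux condition (cultured reporter cells)."""

    name: str
    cells_per_field: int = 9
    red_only_mean: float = 0.0  # per-cell mean count
    double_positive_mean: float = 0.0
    nuclei_channel: bool = True

    def __post_init__(self) -> None:
        if self.cells_per_field < 1:
            raise ValueError("cells_per_field must be >= 1")
        if self.red_only_mean < 0 or self.double_positive_mean < 0:
            raise ValueError("spot means must be >= 0")


def flux_condition_table() -> dict[str, FluxCondition]:
    """Flux-assay presets.

    DFP induces mitophagy and AZD8055 (mTORC1 inhibition) macroautophagy;
    adding bafilomycin A1 blocks lysosomal acidification, so red-only counts
    are exactly zero under +BafA1 while fused double-positive structures
    accumulate.
    """
    return {
        "vehicle": FluxCondition("vehicle", 9, 2.0, 6.0),
        "DFP": FluxCondition("DFP", 9, 10.0, 6.0),
        "DFP+BafA1": FluxCondition("DFP+BafA1", 9, 0.0, 14.0),
        "AZD8055": FluxCondition("AZD8055", 9, 8.0, 6.0),
        "AZD8055+BafA1": FluxCondition("AZD8055+BafA1", 9, 0.0, 12.0),
    }


#: flux-plate rendering constants (40x objective scale)
FLUX_FIELD_SHAPE = (512, 512)
FLUX_PIXEL_SIZE = 0.216  # µm/px
_CELL_GRID = 3
_CELL_RADIUS_PX = (36, 46)
_NUCLEUS_RADIUS_PX = 15
_CYTO_LEVEL = 140.0
_NUCLEUS_LEVEL = 500.0
_SPOT_LEVEL = 500.0
_SPOT_DIAMETER_UM = 0.9


def render_flux_plate(
    condition: FluxCondition | str,
    n_fields: int,
    seed: int,
    shot_noise: bool = True,
    read_noise_sd: float = 2.0,
) -> tuple[list[ImageStack], pd.DataFrame]:
    """Render flux-assay fields of non-overlapping cells with ground truth.

    Each field holds ``cells_per_field`` cells on a jittered grid; every
    cell has a Hoechst-like nucleus, a diffuse cytoplasmic reporter signal
    in both channels, and per-cell spot counts drawn Poisson from the
    condition means (exactly zero red-only under +BafA1 conditions).
    Returns the stacks (mCherry, GFP, nuclei channels) and a per-cell truth
    table (field, cell, center, radius, true counts).
    """
    if isinstance(condition, str):
        table = flux_condition_table()
        if condition not in table:
            raise KeyError(
                f"unknown condition {condition!r}; available: {sorted(table)}"
            )
        condition = table[condition]
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")

    h, w = FLUX_FIELD_SHAPE
    s = FLUX_PIXEL_SIZE
    rng = np.random.default_rng(seed)
    pitch = h // _CELL_GRID
    stacks = []
    truth_rows = []
    for fi in range(n_fields):
        cyto = np.zeros((h, w))
        nuc_img = np.zeros((h, w))
        red_spots = np.zeros((h, w))
        dp_spots = np.zeros((h, w))
        cells = []
        for gy in range(_CELL_GRID):
            for gx in range(_CELL_GRID):
                if len(cells) >= condition.cells_per_field:
                    break
                cy = pitch * gy + pitch / 2 + rng.uniform(-10, 10)
                cx = pitch * gx + pitch / 2 + rng.uniform(-10, 10)
                rad = rng.uniform(*_CELL_RADIUS_PX)
                cells.append((cy, cx, rad))
        yy, xx = np.mgrid[0:h, 0:w]
        for ci, (cy, cx, rad) in enumerate(cells):
            dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
            body = dist2 <= rad**2
            nucleus = dist2 <= _NUCLEUS_RADIUS_PX**2
            cyto[body] = _CYTO_LEVEL
            nuc_img[nucleus] = _NUCLEUS_LEVEL
            n_red = (
                0
                if condition.red_only_mean == 0
                else int(rng.poisson(condition.red_only_mean))
            )
            n_dp = int(rng.poisson(condition.double_positive_mean))
            for n_spots, img in ((n_red, red_spots), (n_dp, dp_spots)):
                if n_spots == 0:
                    continue
                ang = rng.uniform(0, 2 * math.pi, n_spots)
                rr = rng.uniform(
                    _NUCLEUS_RADIUS_PX + 4, rad - 4, n_spots
                )
                pos_um = np.column_stack(
                    [(cy + rr * np.sin(ang)) * s, (cx + rr * np.cos(ang)) * s]
                ) + 0.5 * s  # pixel-centre convention of _add_spots
                _add_spots(
                    img, pos_um, np.full(n_spots, _SPOT_DIAMETER_UM),
                    _SPOT_LEVEL, s,
                )
            truth_rows.append(
                {
                    "field": fi,
                    "cell": ci,
                    "center_row": cy,
                    "center_col": cx,
                    "radius_px": rad,
                    "n_red_only": n_red,
                    "n_double_positive": n_dp,
                    "condition": condition.name,
                }
            )
        psf_px = 0.12 / s
        # cytosolic reporter and nuclear stain fall off smoothly (~1 µm),
        # unlike the diffraction-limited puncta
        body_sigma_px = 1.0 / s
        cyto = ndi.gaussian_filter(cyto, body_sigma_px)
        nuc_img = ndi.gaussian_filter(nuc_img, body_sigma_px)
        channels = {}
        for name, struct in (
            ("mCherry", cyto + red_spots + dp_spots),
            ("GFP", cyto + dp_spots),
            ("nuclei", nuc_img),
        ):
            expected = 100.0 + ndi.gaussian_filter(struct, psf_px)
            img = (
                rng.poisson(expected).astype(float)
                if shot_noise
                else expected
            )
            if read_noise_sd > 0:
                img += rng.normal(0.0, read_noise_sd, img.shape)
            channels[name] = img
        if not condition.nuclei_channel:
            channels.pop("nuclei")
        stacks.append(
            ImageStack(
                channels=channels,
                pixel_size=s,
                metadata={"condition": condition.name, "field": fi},
            )
        )
    return stacks, pd.DataFrame(truth_rows)
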