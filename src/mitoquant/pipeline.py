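"""End-to-end pipelines: analyze one stack, run a cohort, run from config.

``analyze_stack`` applies the full detection chain to one field of view and
returns puncta records plus a per-ROI summary. ``run_cohort`` simulates a
preset cohort and measures every scene, yielding the per-image table that
feeds subject aggregation and group statistics. ``run_end_to_end`` ties a
validated :class:`~mitoquant.config.RunConfig` into a results directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import detect
from .config import DetectionParams, RunConfig
from .core import ImageStack, LabelMask, PunctaRecord, puncta_to_frame
from .io import read_stack, write_stack, write_table, write_truth
from .roi import load_label_mask
from .scenes import CohortBundle, make_cohort
from .stats import aggregate_subjects, one_way_anova_bonferroni, percent_of_youngest

logger = logging.getLogger("mitoquant")


def analyze_stack(
    stack: ImageStack,
    roi: LabelMask | np.ndarray | None = None,
    params: DetectionParams | None = None,
) -> tuple[list[PunctaRecord], pd.DataFrame]:
    """Run the detection chain on one field of view.

    Red-only puncta are segmented from the GFP-subtracted mCherry mask (the
    counting route); double/triple-positive puncta come from the unsubtracted
    mCherry objects classified by mask overlap, so DALs are not erased by the
    pixel subtraction. Returns all records (classes filled) and a per-ROI
    summary with densities by class.
    """
    params = params or DetectionParams()
    s = stack.pixel_size
    if roi is None:
        roi = LabelMask(
            np.ones(stack.shape, dtype=np.int32), pixel_size=s
        )
    elif not isinstance(roi, LabelMask):
        roi = LabelMask(np.asarray(roi).astype(np.int32), pixel_size=s)
    roi_bool = roi.as_bool()
    if not roi_bool.any():
        raise ValueError("ROI is empty")

    mch = detect.preprocess(stack.channels["mCherry"], params.smoothing_sigma_px)
    gfp = detect.preprocess(stack.channels["GFP"], params.smoothing_sigma_px)
    kw = dict(
        method=params.threshold_method,
        offset_factor=params.offset_factor,
        fixed_threshold=params.fixed_threshold,
    )
    m_mask = detect.threshold_channel(mch, roi_bool, **kw)
    g_mask = detect.threshold_channel(gfp, roi_bool, **kw)
    marker_mask = None
    if "marker" in stack.channels:
        mk = detect.preprocess(stack.channels["marker"], params.smoothing_sigma_px)
        marker_mask = detect.threshold_channel(mk, roi_bool, **kw).mask

    seg_kw = dict(
        min_area_um2=params.min_area_um2,
        max_area_um2=params.max_area_um2,
        connectivity=params.connectivity,
        intensity_channels={"mCherry": mch, "GFP": gfp},
    )
    # counting route: subtraction with fragment bridging + declumping; the
    # GFP mask is dilated slightly so that only unambiguously red-not-green
    # pixels survive (tolerance for threshold/registration mismatch)
    g_sub = g_mask.mask
    if params.gfp_dilate_px > 0:
        g_sub = ndi.binary_dilation(
            g_sub, structure=ndi.generate_binary_structure(2, 2),
            iterations=params.gfp_dilate_px,
        )
    red_mask = detect.subtract_gfp(m_mask, g_sub)
    red = detect.segment_subtracted(
        red_mask.mask, mch, m_mask.mask, g_sub, s,
        bridge_radius_um=params.bridge_radius_um,
        declump_min_distance_um=params.declump_min_distance_um,
        **seg_kw,
    )
    red = detect.classify_puncta(
        red, g_mask.mask, marker_mask, params.overlap_cutoff
    )
    red = [r for r in red if r.cls == "red_only"]
    # classification route: unsubtracted objects for DAL counting
    objs = detect.segment_puncta(m_mask.mask, s, **seg_kw)
    objs = detect.classify_puncta(
        objs, g_mask.mask, marker_mask, params.overlap_cutoff
    )
    dal = [o for o in objs if o.cls in ("double_positive", "triple_positive")]

    red = detect.assign_roi_labels(red, roi)
    dal = detect.assign_roi_labels(dal, roi)

    rows = []
    for row in roi.area_table().itertuples():
        lab = int(row.label)
        n_red = sum(1 for r in red if r.roi_label == lab)
        n_dal = sum(1 for r in dal if r.roi_label == lab)
        red_areas = [r.area_um2 for r in red if r.roi_label == lab]
        rows.append(
            {
                "roi_label": lab,
                "roi_area_um2": row.area_um2,
                "n_red_only": n_red,
                "n_double_positive": n_dal,
                "red_only_density": n_red / row.area_um2,
                "double_positive_density": n_dal / row.area_um2,
                "mean_red_area_um2": float(np.mean(red_areas))
                if red_areas
                else np.nan,
            }
        )
    return red + dal, pd.DataFrame(rows)


def measure_cohort(
    bundle: CohortBundle, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Detect every scene of a cohort bundle against its true ROI mask.

    The generator's ROI label mask plays the role of an imported
    (externally segmented) mask. Returns one row per image with per-class
    densities joined to the subject/group metadata.
    """
    rows = []
    for (stack, truth), meta in zip(
        bundle.scenes, bundle.metadata.to_dict("records")
    ):
        _, summary = analyze_stack(stack, truth.roi_labels, params)
        total_area = summary["roi_area_um2"].sum()
        rows.append(
            {
                **meta,
                "roi_area_um2": total_area,
                "red_only_density": summary["n_red_only"].sum() / total_area,
                "double_positive_density": summary["n_double_positive"].sum()
                / total_area,
                "mean_red_area_um2": summary["mean_red_area_um2"].mean(),
                "true_red_only_density": truth.densities["red_only"],
                "true_double_positive_density": truth.densities[
                    "double_positive"
                ],
            }
        )
    return pd.DataFrame(rows)


def run_cohort(
    preset: str,
    n_subjects_per_group: int,
    images_per_subject: int,
    base_seed: int,
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Simulate + detect one preset cohort; per-image density table."""
    bundle = make_cohort(
        preset, n_subjects_per_group, images_per_subject, base_seed
    )
    return measure_cohort(bundle, params)


def run_end_to_end(config: RunConfig) -> Path:
    """Execute a full run (simulate or read -> detect -> stats) to disk.

    The results directory receives the per-punctum CSV, per-image CSV,
    per-subject CSV, stats CSV, a log file, and the resolved config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        all_puncta = []
        if config.simulate is not None:
            sim = config.simulate
            logger.info("simulating preset %s", sim.preset)
            bundle = make_cohort(
                sim.preset, sim.n_subjects_per_group,
                sim.images_per_subject, sim.base_seed,
            )
            per_image = measure_cohort(bundle, config.detection)
            for (stack, truth), meta in zip(
                bundle.scenes, bundle.metadata.to_dict("records")
            ):
                records, _ = analyze_stack(
                    stack, truth.roi_labels, config.detection
                )
                frame = puncta_to_frame(records)
                frame.insert(0, "image_id", meta["image_id"])
                all_puncta.append(frame)
        else:
            paths = [
                p for p in sorted(Path(config.input_dir).glob("*.tif*"))
                if not p.stem.endswith(("_roi", "_truth"))
            ]
            if not paths:
                raise ValueError(f"no TIFF files in {config.input_dir}")
            rows = []
            for i, p in enumerate(paths):
                stack = read_stack(
                    p,
                    {"channels": config.channels,
                     "pixel_size_um": config.pixel_size_um}
                    if config.channels
                    else None,
                )
                for ch in ("mCherry", "GFP"):
                    if ch not in stack.channels:
                        raise ValueError(f"{p}: missing channel {ch!r}")
                # an externally produced label mask beside the image wins
                # over the whole-frame default
                roi_path = p.with_name(p.stem + "_roi.tif")
                roi = (
                    load_label_mask(roi_path, stack.pixel_size)
                    if roi_path.exists()
                    else None
                )
                records, summary = analyze_stack(
                    stack, roi, config.detection
                )
                frame = puncta_to_frame(records)
                frame.insert(0, "image_id", i)
                all_puncta.append(frame)
                total_area = summary["roi_area_um2"].sum()
                rows.append(
                    {
                        "image_id": i,
                        "source": str(p),
                        "group": stack.metadata.get("group", ""),
                        "subject": stack.metadata.get("subject", str(p)),
                        "roi_area_um2": total_area,
                        "n_red_only": summary["n_red_only"].sum(),
                        "n_double_positive": summary["n_double_positive"].sum(),
                        "red_only_density": summary["n_red_only"].sum()
                        / total_area,
                        "double_positive_density": summary[
                            "n_double_positive"
                        ].sum() / total_area,
                    }
                )
            per_image = pd.DataFrame(rows)
        write_table(
            pd.concat(all_puncta, ignore_index=True)
            if all_puncta
            else pd.DataFrame(),
            out / "puncta.csv",
        )
        write_table(per_image, out / "per_image.csv")
        measure = config.stats.measure
        subjects = aggregate_subjects(
            per_image[["group", "subject", measure]], [measure]
        )
        write_table(subjects, out / "per_subject.csv")
        if subjects["group"].nunique() >= 2 and (
            subjects.groupby("group").size().min() >= 2
        ):
            res = one_way_anova_bonferroni(
                subjects, measure, config.stats.comparisons
            )
            stats_frame = res.pairwise.copy()
            stats_frame.insert(0, "measure", measure)
            stats_frame["omnibus_F"] = res.F
            stats_frame["omnibus_p"] = res.p
            write_table(stats_frame, out / "stats.csv")
            logger.info("ANOVA F=%.4f p=%.3g", res.F, res.p)
            if config.stats.youngest_group:
                pct = percent_of_youngest(
                    subjects, measure, config.stats.youngest_group
                )
                write_table(pct, out / "per_subject_percent.csv")
        config.to_yaml(out / "config.yaml")
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "n_images": int(len(per_image)),
                    "group_means": subjects.groupby("group")[measure]
                    .mean()
                    .to_dict(),
                },
                indent=2,
            )
        )
        logger.info("run complete: %d images", len(per_image))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def export_cohort(bundle: CohortBundle, out_dir) -> Path:
    """Write a simulated cohort to disk (TIFF + sidecars + truth CSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (stack, truth), meta in zip(
        bundle.scenes, bundle.metadata.to_dict("records")
    ):
        stem = f"img{meta['image_id']:04d}"
        stack.metadata.update(
            {"group": meta["group"], "subject": meta["subject"]}
        )
        write_stack(stack, out / f"{stem}.tif")
        write_truth(truth, out / f"{stem}_truth.csv",
                    out / f"{stem}_roi.tif")
    write_table(bundle.metadata, out / "metadata.csv")
    return out
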