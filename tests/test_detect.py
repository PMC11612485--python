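"""Detection chain: thresholding, subtraction, segmentation, morphometry."""

import numpy as np
import pytest

from mitoquant import (DetectionParams, analyze_stack, classify_puncta,
                       density, measure_morphometry, preprocess,
                       render_scene, segment_puncta, subtract_gfp,
                       threshold_channel)
from mitoquant.core import LabelMask, PunctaRecord
from skimage.draw import disk as draw_disk

from oracles import brute_force_otsu_mask, flood_fill_components


class TestPreprocess:
    def test_sigma_zero_identity(self, rng):
        img = rng.normal(size=(32, 32))
        np.testing.assert_array_equal(preprocess(img, 0.0), img)

    def test_constant_preserved(self):
        img = np.full((16, 16), 3.5)
        assert np.allclose(preprocess(img, 2.0), 3.5)

    def test_kernel_normalized(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        assert preprocess(img, 1.0).sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((4, 4)), -1.0)


class TestThreshold:
    def test_two_valued_image_exact(self):
        img = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 10.0, 200.0)
        roi = np.ones_like(img, dtype=bool)
        mask = threshold_channel(img, roi, "otsu", 1.0)
        np.testing.assert_array_equal(mask.mask, img == 200.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            img = rng.integers(0, 40, size=(24, 24)).astype(float)
            img[rng.random(img.shape) < 0.2] += 60
            roi = np.ones(img.shape, dtype=bool)
            ours = threshold_channel(img, roi, "otsu", 1.0).mask
            oracle = brute_force_otsu_mask(img, roi)
            np.testing.assert_array_equal(ours, oracle)

    def test_scale_invariance(self, rng):
        img = rng.integers(0, 100, size=(32, 32)).astype(float)
        roi = np.ones(img.shape, dtype=bool)
        a = threshold_channel(img, roi).mask
        b = threshold_channel(img * 2.0, roi).mask
        np.testing.assert_array_equal(a, b)

    def test_computed_inside_roi_only(self):
        img = np.zeros((10, 10))
        img[:5] = 1000.0  # bright half outside ROI
        img[5:, :5] = 10.0
        img[5:, 5:] = 200.0
        roi = np.zeros_like(img, dtype=bool)
        roi[5:] = True
        mask = threshold_channel(img, roi).mask
        assert not mask[:5].any()
        np.testing.assert_array_equal(mask[5:], img[5:] == 200.0)

    def test_constant_roi_warns_empty(self):
        img = np.ones((8, 8))
        roi = np.ones_like(img, dtype=bool)
        with pytest.warns(UserWarning, match="no foreground"):
            mask = threshold_channel(img, roi)
        assert not mask.mask.any()

    def test_all_zero_roi_empty_mask(self):
        img = np.zeros((8, 8))
        roi = np.ones_like(img, dtype=bool)
        with pytest.warns(UserWarning):
            assert not threshold_channel(img, roi).mask.any()


class TestSubtract:
    def test_empty_gfp_identity(self, rng):
        m = rng.random((16, 16)) > 0.5
        out = subtract_gfp(m, np.zeros_like(m))
        np.testing.assert_array_equal(out.mask, m)

    def test_superset_gfp_annihilates(self, rng):
        m = rng.random((16, 16)) > 0.5
        out = subtract_gfp(m, np.ones_like(m, dtype=bool))
        assert not out.mask.any()

    def test_partial_overlap_pixel_count(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:4, 2:7] = True  # 10 px blob
        g = np.zeros_like(m)
        g[2:4, 2:4] = True  # 4 px overlap
        assert subtract_gfp(m, g).mask.sum() == 6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_gfp(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestSegment:
    def test_three_disjoint_blobs(self):
        mask = np.zeros((32, 32), dtype=bool)
        for r in (5, 15, 25):
            mask[r:r + 2, 5:8]
            mask[r:r + 2, 5:8] = True
        recs = segment_puncta(mask, 0.1, min_area_um2=0.01)
        assert len(recs) == 3

    def test_min_area_filter(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        assert segment_puncta(mask, 0.1, min_area_um2=0.02) == []

    def test_diagonal_connectivity(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only at corner
        assert len(segment_puncta(mask, 0.1, min_area_um2=0.01,
                                  connectivity=8)) == 1
        assert len(segment_puncta(mask, 0.1, min_area_um2=0.01,
                                  connectivity=4)) == 2

    def test_components_match_flood_fill_oracle(self, rng):
        for trial in range(20):
            mask = rng.random((64, 64)) < 0.3
            for connectivity in (4, 8):
                recs = segment_puncta(mask, 1.0, min_area_um2=0.5,
                                      max_area_um2=1e9,
                                      connectivity=connectivity)
                ours = {frozenset(map(tuple, r.coords)) for r in recs}
                oracle = flood_fill_components(mask, connectivity)
                assert ours == oracle

    def test_deterministic_id_order(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[10:12, 2:4] = True
        mask[2:4, 10:12] = True
        recs = segment_puncta(mask, 0.1, min_area_um2=0.01)
        # id 0 is the component whose first pixel comes first row-major
        assert recs[0].centroid[0] < recs[1].centroid[0]

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            segment_puncta(np.zeros((4, 4), bool), 0.1, min_area_um2=2.0,
                           max_area_um2=1.0)
        with pytest.raises(ValueError):
            segment_puncta(np.zeros((4, 4), bool), 0.1, connectivity=6)


def _record_with_coords(coords):
    coords = np.asarray(coords)
    return PunctaRecord(
        id=0, centroid=tuple(coords.mean(axis=0)), area_um2=1.0,
        equivalent_diameter_um=1.0, eccentricity=0.0, form_factor=1.0,
        coords=coords,
    )


class TestClassify:
    def test_zero_overlap_red_only(self):
        rec = _record_with_coords([(1, 1), (1, 2)])
        out = classify_puncta([rec], np.zeros((4, 4), bool))
        assert out[0].cls == "red_only"

    def test_full_overlap_with_marker_triple(self):
        rec = _record_with_coords([(1, 1), (1, 2)])
        full = np.ones((4, 4), bool)
        out = classify_puncta([rec], full, full, overlap_cutoff=0.5)
        assert out[0].cls == "triple_positive"

    def test_fraction_below_cutoff(self):
        coords = [(0, c) for c in range(10)]
        gfp = np.zeros((2, 10), bool)
        gfp[0, :4] = True  # 4 of 10 px
        out = classify_puncta([_record_with_coords(coords)], gfp,
                              overlap_cutoff=0.5)
        assert out[0].gfp_overlap_fraction == pytest.approx(0.4)
        assert out[0].cls == "red_only"

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            classify_puncta([], np.zeros((2, 2), bool), overlap_cutoff=0.0)
        with pytest.raises(ValueError):
            classify_puncta([], np.zeros((2, 2), bool), overlap_cutoff=1.5)


class TestMorphometry:
    def test_single_pixel_closed_form(self):
        area, eq, ecc, ff = measure_morphometry(np.array([[3, 3]]), 0.1)
        assert area == pytest.approx(0.01)
        assert eq == pytest.approx(2 * np.sqrt(0.01 / np.pi), abs=1e-6)
        assert eq == pytest.approx(0.1128, abs=1e-3)

    def test_digital_disk(self):
        mask = np.zeros((25, 25), dtype=bool)
        rr, cc = draw_disk((12, 12), 10.5)
        mask[rr, cc] = True
        area, eq, ecc, ff = measure_morphometry(mask, 1.0)
        assert ecc == pytest.approx(0.0, abs=0.1)
        assert 0.85 <= ff <= 1.05

    def test_bar_eccentricity(self):
        coords = np.array([(0, c) for c in range(20)])
        _, _, ecc, _ = measure_morphometry(coords, 1.0)
        assert ecc > 0.99

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            measure_morphometry(np.zeros((4, 4), dtype=bool), 0.1)


class TestDensity:
    def test_arithmetic(self):
        roi = np.zeros((40, 40), dtype=bool)
        roi[:25] = True  # 1000 px at 0.1 µm/px -> 10 µm²
        recs = [_record_with_coords([(r, 5)]) for r in range(5)]
        assert density(recs, roi, 0.1) == pytest.approx(0.5)

    def test_no_puncta_zero(self):
        roi = np.ones((10, 10), dtype=bool)
        assert density([], roi, 0.1) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            density([], np.zeros((4, 4), bool), 0.1)

    def test_per_label_densities(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :5] = 1
        labels[:, 5:] = 2
        lm = LabelMask(labels, pixel_size=1.0)
        recs = [_record_with_coords([(2, 2)]),
                _record_with_coords([(2, 7)]),
                _record_with_coords([(7, 7)])]
        d = density(recs, lm, 1.0)
        assert d[1] == pytest.approx(1 / 50)
        assert d[2] == pytest.approx(2 / 50)

    def test_centroid_membership_counts_once(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :5] = 1
        labels[:, 5:] = 2
        lm = LabelMask(labels, pixel_size=1.0)
        rec = _record_with_coords([(5, 4), (5, 5), (5, 6)])  # straddles
        d = density([rec], lm, 1.0)
        assert d[1] + d[2] == pytest.approx(1 / 50)


class TestCleanSceneEndToEnd:
    def test_red_count_matches_truth(self, clean_scene):
        stack, truth = clean_scene
        _, summary = analyze_stack(stack, truth.roi_labels)
        assert summary["n_red_only"].sum() == truth.counts["red_only"]
        assert summary["red_only_density"].iloc[0] == pytest.approx(
            truth.densities["red_only"]
        )

    def test_classification_route_matches_subtraction_route(self, clean_scene):
        stack, truth = clean_scene
        recs, summary = analyze_stack(stack, truth.roi_labels)
        n_red = sum(1 for r in recs if r.cls == "red_only")
        assert n_red == summary["n_red_only"].sum()

    def test_dal_count_matches_truth(self, clean_scene):
        stack, truth = clean_scene
        _, summary = analyze_stack(stack, truth.roi_labels)
        assert summary["n_double_positive"].sum() == \
            truth.counts["double_positive"]

    def test_bafa1_emulation_zero_red(self, clean_spec):
        """Converting all red puncta to double-positive kills red density."""
        from dataclasses import replace
        spec = replace(clean_spec, red_only_density=0.0,
                       double_positive_density=0.0085)
        stack, truth = render_scene(spec, seed=6)
        _, summary = analyze_stack(stack, truth.roi_labels)
        assert summary["n_red_only"].sum() == 0
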