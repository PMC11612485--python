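"""Synthetic-scene generator: determinism, Poisson placement, presets."""

import numpy as np
import pandas as pd
import pytest

from mitoquant import (SceneSpec, flux_condition_table, make_cohort,
                       preset_table, render_flux_plate, render_scene)


class TestRenderScene:
    def test_empty_scene_is_background_plus_network_only(self):
        spec = SceneSpec(field_shape=(128, 128), red_only_density=0.0,
                         double_positive_density=0.0, network_density=0.0,
                         shot_noise=False, read_noise_sd=0.0)
        stack, truth = render_scene(spec, seed=0)
        assert np.allclose(stack.channels["mCherry"], spec.background_level)
        assert np.allclose(stack.channels["GFP"], spec.background_level)
        assert len(truth.puncta) == 0
        assert truth.counts == {"red_only": 0, "double_positive": 0}

    def test_network_is_dual_channel(self):
        spec = SceneSpec(field_shape=(128, 128), network_density=0.1,
                         shot_noise=False, read_noise_sd=0.0)
        stack, _ = render_scene(spec, seed=1)
        # identical structure in both channels when no puncta are present
        np.testing.assert_array_equal(
            stack.channels["mCherry"], stack.channels["GFP"]
        )
        assert stack.channels["mCherry"].max() > spec.background_level

    def test_determinism_same_seed_bit_identical(self):
        spec = SceneSpec(field_shape=(128, 128), red_only_density=0.02)
        a, _ = render_scene(spec, seed=7)
        b, _ = render_scene(spec, seed=7)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_different_seed_different_positions(self):
        spec = SceneSpec(field_shape=(128, 128), red_only_density=0.05)
        _, ta = render_scene(spec, seed=7)
        _, tb = render_scene(spec, seed=8)
        assert not ta.puncta[["x_um", "y_um"]].equals(
            tb.puncta[["x_um", "y_um"]]
        )

    def test_poisson_placement_mean(self):
        """Realized counts across seeds match the Poisson mean d*A."""
        spec = SceneSpec(field_shape=(128, 128), red_only_density=0.05,
                         network_density=0.0, shot_noise=False,
                         read_noise_sd=0.0)
        area = 128 * 128 * spec.pixel_size**2
        lam = spec.red_only_density * area
        n_rep = 200
        counts = [render_scene(spec, seed)[1].counts["red_only"]
                  for seed in range(n_rep)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / n_rep)

    def test_red_only_absent_from_gfp(self, clean_scene):
        """GFP at red-only punctum positions equals local background."""
        stack, truth = clean_scene
        gfp = stack.channels["GFP"]
        s = stack.pixel_size
        red = truth.puncta[truth.puncta["class"] == "red_only"]
        for _, p in red.iterrows():
            r = int(p.y_um / s)
            c = int(p.x_um / s)
            val = gfp[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2].max()
            # may legitimately sit on network or a DAL; never below bg
            assert val >= 100.0 - 1e-9

    def test_double_positive_raises_both_channels(self):
        spec = SceneSpec(field_shape=(128, 128), network_density=0.0,
                         double_positive_density=0.02, shot_noise=False,
                         read_noise_sd=0.0)
        stack, truth = render_scene(spec, seed=2)
        s = spec.pixel_size
        for _, p in truth.puncta.iterrows():
            r, c = int(p.y_um / s), int(p.x_um / s)
            for ch in ("mCherry", "GFP"):
                assert stack.channels[ch][r, c] > 150.0

    def test_truth_density_is_count_over_area(self, clean_scene):
        _, truth = clean_scene
        for cls, n in truth.counts.items():
            assert truth.densities[cls] == n / truth.roi_area_um2

    def test_marker_channel_covers_all_puncta(self):
        spec = SceneSpec(field_shape=(128, 128), red_only_density=0.02,
                         double_positive_density=0.01, marker_channel=True,
                         network_density=0.0, shot_noise=False,
                         read_noise_sd=0.0)
        stack, truth = render_scene(spec, seed=4)
        mk = stack.channels["marker"]
        s = spec.pixel_size
        for _, p in truth.puncta.iterrows():
            assert mk[int(p.y_um / s), int(p.x_um / s)] > 150.0

    @pytest.mark.parametrize(
        "field,msg",
        [
            (dict(pixel_size=0.0), "pixel_size"),
            (dict(red_only_density=-1.0), "red_only_density"),
            (dict(punctum_diameter_mean=0.0), "punctum_diameter_mean"),
            (dict(roi_kind="banana"), "roi_kind"),
            (dict(roi_area_target=1e9), "roi_area_target"),
        ],
    )
    def test_invalid_spec_names_field(self, field, msg):
        with pytest.raises(ValueError, match=msg):
            SceneSpec(**field)

    def test_soma_roi_hits_area_target(self):
        spec = SceneSpec(roi_kind="soma", roi_area_target=600.0)
        _, truth = render_scene(spec, seed=5)
        assert truth.roi_area_um2 == pytest.approx(600.0, rel=0.05)

    def test_soma_with_processes_contains_soma(self):
        spec = SceneSpec(roi_kind="soma_with_processes", roi_area_target=500.0)
        _, truth = render_scene(spec, seed=5)
        assert truth.roi_area_um2 >= 500.0 * 0.95


class TestPresets:
    def test_published_group_means(self):
        t = preset_table()
        assert t["a9_mito"].young == 0.005
        assert t["a9_mito"].geriatric == 0.018
        assert t["a10_mito"].young == 0.007
        assert t["a10_mito"].geriatric == 0.008
        assert t["a9_auto"].young == 0.003
        assert t["a9_auto"].geriatric == 0.002
        assert t["a10_auto"].young == 0.005
        assert t["a10_auto"].geriatric == 0.002
        assert t["chp_auto"].young == 0.031
        assert t["chp_auto"].geriatric == 0.027

    def test_published_ratios(self):
        t = preset_table()
        assert t["pc_mito"].geriatric / t["pc_mito"].young == pytest.approx(2.3)
        assert t["cb_microglia_mito"].geriatric / t[
            "cb_microglia_mito"
        ].young == pytest.approx(5.4)
        assert t["pfc_auto"].adult / t["pfc_auto"].young == pytest.approx(0.6)

    def test_provenance_nonempty(self):
        for preset in preset_table().values():
            assert preset.provenance


class TestMakeCohort:
    SPEC = SceneSpec(field_shape=(128, 128), network_density=0.05)

    def test_bookkeeping(self):
        bundle = make_cohort("a9_mito", 2, 2, base_seed=1, scene_spec=self.SPEC)
        n_groups = len(preset_table()["a9_mito"].groups)
        assert len(bundle.scenes) == 2 * 2 * n_groups
        assert len(bundle.metadata) == len(bundle.scenes)
        per_subj = bundle.metadata.groupby("subject").size()
        assert (per_subj == 2).all()

    def test_determinism(self):
        a = make_cohort("a9_mito", 2, 1, base_seed=9, scene_spec=self.SPEC)
        b = make_cohort("a9_mito", 2, 1, base_seed=9, scene_spec=self.SPEC)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        for (sa, _), (sb, _) in zip(a.scenes, b.scenes):
            np.testing.assert_array_equal(
                sa.channels["mCherry"], sb.channels["mCherry"]
            )

    def test_truth_group_means_near_preset(self):
        """Generator self-consistency: realized densities ~ preset truth."""
        bundle = make_cohort("chp_auto", 4, 3, base_seed=2,
                             scene_spec=self.SPEC)
        truth_d = [t.densities["red_only"] for _, t in bundle.scenes]
        frame = bundle.metadata.assign(d=truth_d)
        preset = preset_table()["chp_auto"]
        area = 128 * 128 * self.SPEC.pixel_size**2
        for grp, levels in preset.groups.items():
            vals = frame.loc[frame.group == grp, "d"]
            lam = levels.red_only_density * area
            se = np.sqrt(lam * len(vals)) / (len(vals) * area)
            subj_se = levels.red_only_density * 0.10 / 2
            tol = 3 * np.hypot(se, subj_se)
            assert abs(vals.mean() - levels.red_only_density) < tol

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="a9_mito"):
            make_cohort("nope", 2, 1, base_seed=0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_cohort("a9_mito", 1, 1, base_seed=0)
        with pytest.raises(ValueError):
            make_cohort("a9_mito", 2, 0, base_seed=0)


class TestFluxPlate:
    def test_bafa1_blocks_red_only(self):
        _, truth = render_flux_plate("DFP+BafA1", 2, seed=0)
        assert (truth["n_red_only"] == 0).all()
        assert truth["n_double_positive"].mean() > 0

    def test_dfp_exceeds_vehicle(self):
        _, tv = render_flux_plate("vehicle", 2, seed=0)
        _, td = render_flux_plate("DFP", 2, seed=0)
        assert td["n_red_only"].mean() > tv["n_red_only"].mean()

    def test_zero_fields_rejected(self):
        with pytest.raises(ValueError):
            render_flux_plate("vehicle", 0, seed=0)

    def test_unknown_condition(self):
        with pytest.raises(KeyError, match="vehicle"):
            render_flux_plate("nope", 1, seed=0)

    def test_condition_table_invariants(self):
        table = flux_condition_table()
        for name, cond in table.items():
            if "BafA1" in name:
                assert cond.red_only_mean == 0.0

    def test_cells_have_nuclei_and_channels(self):
        stacks, truth = render_flux_plate("vehicle", 1, seed=3)
        st = stacks[0]
        assert set(st.channels) == {"mCherry", "GFP", "nuclei"}
        assert (truth["field"] == 0).all()
        assert len(truth) == flux_condition_table()["vehicle"].cells_per_field
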