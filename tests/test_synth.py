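"""Tests of the synthetic scene generator and its ground-truth bookkeeping."""

import math

import numpy as np
import pytest
from scipy import ndimage

from corebreak import (CassetteLayout, GroundTruthDebris, GroundTruthRoot,
                       generate_calibration_dataset, generate_scene,
                       generate_template, random_scene)
from corebreak.synth import InvalidLayoutError, default_depth_profile


class TestLayout:
    def test_default_has_40_disjoint_wells_inside_frame(self):
        layout = CassetteLayout.default(0.35)
        assert layout.n_wells == 40
        layout.validate()  # raises on overlap / out of bounds
        c = layout.well_centres()
        assert c.shape == (40, 2)
        # raster order: y non-decreasing, x increasing within a row
        assert (np.diff(c[:5, 0]) > 0).all()
        assert (np.diff(c[::5, 1]) > 0).all()

    def test_overlapping_wells_rejected(self):
        with pytest.raises(InvalidLayoutError):
            CassetteLayout(well_radius_px=200.0, pitch_px=300.0)

    def test_well_outside_bounds_rejected(self):
        with pytest.raises(InvalidLayoutError):
            CassetteLayout(origin_px=(10.0, 352.0))


class TestTemplate:
    def test_exactly_40_bright_discs(self, layout, template):
        blue = template[..., 2].astype(float)
        lab, n = ndimage.label(blue > 128)
        assert n == 40

    def test_deterministic_for_same_seed(self, layout):
        a = generate_template(layout, seed=9, jitter_px=1.0, flare=0.02)
        b = generate_template(layout, seed=9, jitter_px=1.0, flare=0.02)
        assert np.array_equal(a, b)

    def test_disc_pixel_count_matches_area(self):
        # independent oracle: count bright pixels inside each disc's
        # bounding box and compare with pi r^2
        layout = CassetteLayout.default(0.35)
        r = layout.well_radius_px
        img = generate_template(layout, seed=0, noise_sd=0.0)
        blue = img[..., 2].astype(float)
        for cx, cy in layout.well_centres()[:8]:
            x0, x1 = int(cx - r - 2), int(cx + r + 3)
            y0, y1 = int(cy - r - 2), int(cy + r + 3)
            count = (blue[y0:y1, x0:x1] > 128).sum()
            assert count == pytest.approx(math.pi * r * r, rel=0.05)

    def test_jittered_centres_returned_in_raster_order(self, layout):
        img, centres = generate_template(layout, seed=3, jitter_px=2.0,
                                         return_centres=True)
        nominal = layout.well_centres()
        assert np.abs(centres - nominal).max() <= 2.0


class TestScene:
    def test_empty_noise_free_scene_is_flat_background(self):
        layout = CassetteLayout.default(0.25)
        scene = generate_scene(layout, [], [], noise_sd=0.0, seed=0,
                               texture_sd=0.0)
        blue = scene.image[..., 2]
        assert blue.max() == blue.min()

    def test_ground_truth_arc_length_is_polyline_length(self):
        root = GroundTruthRoot(polyline=np.array([[0., 0.], [30., 40.]]),
                               width_px=5)
        assert root.arc_length_px == pytest.approx(50.0)

    def test_explicit_root_recorded_with_well_and_length(self):
        layout = CassetteLayout.default(0.25)
        c = layout.well_centres()[6]  # well 7
        root = GroundTruthRoot(polyline=np.array([c - [50, 0], c + [50, 0]]),
                               width_px=5, well_index=7)
        scene = generate_scene(layout, [root], seed=0)
        assert len(scene.roots) == 1
        assert scene.roots[0].well_index == 7
        assert scene.roots[0].arc_length_px == pytest.approx(100.0)

    def test_three_roots_per_well_gives_120_ground_truth_roots(self):
        scene = random_scene(CassetteLayout.default(0.5), seed=0,
                             roots_per_well=(3, 3))
        assert len(scene.roots) == 120

    def test_identical_seed_reproduces_scene_byte_for_byte(self):
        layout = CassetteLayout.default(0.25)
        a = random_scene(layout, seed=11, roots_per_well=(1, 2), n_debris=1)
        b = random_scene(layout, seed=11, roots_per_well=(1, 2), n_debris=1)
        assert np.array_equal(a.image, b.image)
        assert len(a.roots) == len(b.roots)

    def test_stroke_pixels_lie_near_polyline(self):
        # every above-background pixel within width/2 + 1 of the polyline
        layout = CassetteLayout.default(0.25)
        c = layout.well_centres()[0]
        root = GroundTruthRoot(polyline=np.array([c - [40, 10], c + [40, 10]]),
                               width_px=6, peak_intensity=200)
        scene = generate_scene(layout, [root], seed=0, texture_sd=0.0)
        blue = scene.image[..., 2].astype(float)
        bg = np.median(blue)
        ys, xs = np.nonzero(blue > bg + 20)
        # distance from each stroke pixel to the segment's line
        p0, p1 = root.polyline
        d = np.abs((p1[0] - p0[0]) * (p0[1] - ys) - (p0[0] - xs) * (p1[1] - p0[1]))
        d /= np.hypot(*(p1 - p0))
        assert d.max() <= root.width_px / 2 + 1.0

    def test_dim_scene_mean_blue_below_threshold(self, params):
        layout = CassetteLayout.default(0.3)
        dim = random_scene(layout, seed=2, roots_per_well=(1, 1), dim=True)
        lit = random_scene(layout, seed=2, roots_per_well=(1, 1), dim=False)
        f = params.downsample_factor
        assert dim.image[..., 2].mean() < params.dim_mean_threshold
        assert lit.image[..., 2].mean() > params.dim_mean_threshold

    def test_out_of_frame_stroke_clipped_and_flagged(self):
        layout = CassetteLayout.default(0.25)
        root = GroundTruthRoot(polyline=np.array([[-40., 10.], [60., 10.]]),
                               width_px=5)
        scene = generate_scene(layout, [root], seed=0)
        assert scene.roots[0].clipped
        assert scene.roots[0].polyline[:, 0].min() >= 0

    def test_debris_thicker_than_roots(self):
        scene = random_scene(CassetteLayout.default(0.3), seed=4,
                             roots_per_well=(0, 1), n_debris=3)
        for d in scene.debris:
            assert d.min_width_px > 2 * 2 * 4  # 2 x ds factor x max root radius

    def test_scene_roundtrip_to_png_and_sidecar(self, tmp_path):
        scene = random_scene(CassetteLayout.default(0.25), seed=1,
                             roots_per_well=(1, 1))
        p = tmp_path / "scene.png"
        scene.save(p)
        from PIL import Image

        back = np.asarray(Image.open(p))
        assert np.array_equal(back, scene.image)
        assert (tmp_path / "scene.truth.json").exists()


class TestCalibrationDataset:
    def test_zero_density_zero_noise_gives_all_zero_counts(self):
        ds = generate_calibration_dataset(depth_profile=lambda z: 0.0 * np.asarray(z),
                                          gain=2.0, n_cores=3, seed=0,
                                          noise="none", core_sd=0.0)
        assert all(f.root_number == 0 for p in ds.profiles for f in p.faces)
        assert (ds.pairs["summed_count"] == 0).all()

    def test_noise_free_counts_are_rounded_gain_times_density(self):
        g = 2.0
        ds = generate_calibration_dataset(gain=g, n_cores=2, seed=0,
                                          noise="none", core_sd=0.0)
        prof = ds.profiles[0]
        for f in prof.faces:
            expected = round(g * default_depth_profile(f.depth_cm))
            assert f.root_number == expected

    def test_single_core_rejected(self):
        with pytest.raises(ValueError, match="n_cores"):
            generate_calibration_dataset(n_cores=1)

    def test_windows_pair_counts_with_10cm_increments(self):
        ds = generate_calibration_dataset(n_cores=2, seed=1)
        assert ((ds.pairs["bottom_cm"] - ds.pairs["top_cm"]) == 10).all()
        # windowed count equals the profile's sum over the three depths
        from corebreak.calibrate import window_counts

        prof = {p.core_id: p for p in ds.profiles}
        row = ds.pairs.iloc[7]
        assert row["summed_count"] == window_counts(
            prof[row["core_id"]], (row["top_cm"], row["bottom_cm"]))
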