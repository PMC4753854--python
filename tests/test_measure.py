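"""Tests of root filtering, per-well measurement and CSV output."""

import numpy as np
import pytest

from corebreak import CassetteLayout, GroundTruthRoot, generate_scene
from corebreak.associate import LabelledRoots, RootComponent, label_by_well
from corebreak.measure import (CassetteMeasurement, WellRow, areal_density,
                               component_length_px, filter_roots, length_mm,
                               measure_wells, read_csv, write_csv)
from corebreak.params import PipelineParams
from corebreak.pipeline import params_for_layout, process_frame
from corebreak.wells import WellCircle, WellMap, find_wells, rasterize_circles
from corebreak.synth import generate_template


def _wellmap_one(shape=(60, 60)):
    circles = [WellCircle(label=1, centre_px=(30.0, 30.0), radius_px=20.0)]
    return WellMap(circles=circles,
                   label_image=rasterize_circles(circles, shape),
                   source_shape=shape)


def _component(mask, well=1):
    rows, cols = np.nonzero(mask)
    return RootComponent(well=well, pixel_count=rows.size,
                         pixels=(rows, cols))


def _labelled(mask, well=1):
    lab = np.where(mask, well, 0).astype(np.int32)
    return LabelledRoots(label_image=lab, components=[_component(mask, well)])


def _rgb_for(mask, rgb):
    img = np.zeros(mask.shape + (3,), dtype=float)
    img[mask] = rgb
    return img


class TestComponentLength:
    def test_straight_chain_length(self):
        mask = np.zeros((10, 40), dtype=bool)
        mask[5, 2:32] = True
        L = component_length_px(np.nonzero(mask))
        assert L == pytest.approx(29.0, abs=0.5)

    def test_diagonal_chain_length(self):
        mask = np.eye(20, dtype=bool)
        L = component_length_px(np.nonzero(mask))
        assert L == pytest.approx(19 * np.sqrt(2), rel=0.05)

    def test_single_pixel_counts_as_one(self):
        assert component_length_px((np.array([3]), np.array([4]))) == 1.0


class TestFilterRoots:
    def _line_mask(self, n=30):
        mask = np.zeros((60, 60), dtype=bool)
        mask[30, 10:10 + n] = True
        return mask

    def test_red_object_excluded_by_hue(self):
        mask = self._line_mask()
        labelled = _labelled(mask)
        rgb = _rgb_for(mask, (220.0, 30.0, 30.0))   # red, hue ~ 0
        out = filter_roots(labelled, rgb, PipelineParams())
        assert out.components == []

    def test_blue_bright_long_root_retained(self):
        mask = self._line_mask()
        labelled = _labelled(mask)
        rgb = _rgb_for(mask, (30.0, 40.0, 220.0))   # blue
        out = filter_roots(labelled, rgb, PipelineParams())
        assert len(out.components) == 1

    def test_length_at_threshold_excluded_strict_inequality(self):
        params = PipelineParams(min_root_length_px=10.0)
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:16] = True                       # 11 px -> length 10 exactly
        labelled = _labelled(mask)
        rgb = _rgb_for(mask, (30.0, 40.0, 220.0))
        out = filter_roots(labelled, rgb, params)
        assert out.components == []

    def test_dark_object_excluded_by_lightness(self):
        mask = self._line_mask()
        labelled = _labelled(mask)
        rgb = _rgb_for(mask, (5.0, 8.0, 40.0))      # blue but dark
        out = filter_roots(labelled, rgb, PipelineParams())
        assert out.components == []


class TestMeasureWells:
    def test_crossing_roots_count_as_single_object(self):
        layout = CassetteLayout.default(0.35)
        params = params_for_layout(layout)
        template = generate_template(layout, seed=1)
        wm = find_wells(template, params)
        c = layout.well_centres()[8]                # well 9
        roots = [
            GroundTruthRoot(polyline=np.array([c - [60, 60], c + [60, 60]]),
                            width_px=6, well_index=9),
            GroundTruthRoot(polyline=np.array([c - [60, -60], c + [60, -60]]),
                            width_px=6, well_index=9),
        ]
        scene = generate_scene(layout, roots, seed=0)
        res = process_frame(scene.image, wm, params)
        assert res.measurement.root_number(9) == 1   # merged at the crossing
        assert res.measurement.total_roots() == 1

    def test_empty_well_reports_zero_zero(self):
        wm = _wellmap_one()
        empty = LabelledRoots(label_image=np.zeros((60, 60), dtype=np.int32),
                              components=[])
        m = measure_wells(empty, wm, dim=False)
        assert m.root_number(1) == 0 and m.root_length(1) == 0.0

    def test_known_root_length_within_ten_percent(self):
        layout = CassetteLayout.default(0.35)
        params = params_for_layout(layout)
        template = generate_template(layout, seed=1)
        wm = find_wells(template, params)
        c = layout.well_centres()[8]
        root = GroundTruthRoot(polyline=np.array([c - [80, 0], c + [80, 0]]),
                               width_px=6, well_index=9)
        scene = generate_scene(layout, [root], seed=0)
        res = process_frame(scene.image, wm, params)
        assert res.measurement.root_length(9) == pytest.approx(
            root.arc_length_px / 2, rel=0.10)


class TestConversions:
    def test_paper_resolution_identity(self):
        assert areal_density(13.0) == pytest.approx(169.0)

    def test_unit_resolution(self):
        assert areal_density(1.0) == 1.0

    def test_length_conversion_accounts_for_downsampling(self):
        params = PipelineParams(px_per_mm=13.0, downsample_factor=1)
        assert length_mm(130.0, params) == pytest.approx(10.0)
        params2 = PipelineParams(px_per_mm=13.0, downsample_factor=2)
        assert length_mm(65.0, params2) == pytest.approx(10.0)

    def test_non_positive_resolution_rejected(self):
        with pytest.raises(ValueError):
            areal_density(0.0)


class TestCsv:
    def _measurement(self, dim=0):
        rows = [WellRow(core=k, root_number=0, root_length=0.0)
                for k in range(1, 41)]
        rows[4] = WellRow(core=5, root_number=2, root_length=123.45)
        return CassetteMeasurement(dim=dim, rows=rows)

    def test_header_and_row_count(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(self._measurement(), p)
        lines = p.read_text().splitlines()
        assert lines[0] == "Dim,Core,RootNumber,RootLength"
        assert len(lines) == 41

    def test_roundtrip_identical(self, tmp_path):
        m = self._measurement()
        p = tmp_path / "m.csv"
        write_csv(m, p)
        back = read_csv(p)
        assert back.dim == 0
        assert back.root_number(5) == 2
        assert back.root_length(5) == 123.45
        assert back.root_number(40) == 0

    def test_dim_flag_written_to_every_row(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(self._measurement(dim=1), p)
        for line in p.read_text().splitlines()[1:]:
            assert line.startswith("1,")

    def test_zero_roots_nonzero_length_rejected(self):
        with pytest.raises(ValueError):
            CassetteMeasurement(dim=0, rows=[WellRow(core=1, root_number=0,
                                                     root_length=5.0)])
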