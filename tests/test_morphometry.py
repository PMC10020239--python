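"""Backbone tracing, contour length, FWHM width, Feret diameter, topology."""

import math

import numpy as np
import pytest

import toroquant as tq
from toroquant.config import ImagingConfig
from toroquant.morphometry import (
    TOPOLOGY_FIGURE_EIGHT,
    TOPOLOGY_OPEN,
    TOPOLOGY_TOROID,
    classify_topology,
    contour_length,
    extract_backbone,
    feret_diameter,
    width_fwhm,
)
from toroquant.segmentation import segment_cells, threshold_channel


def annulus_mask(size=64, r=10.0, half_width=3.0):
    y, x = np.mgrid[:size, :size]
    d = np.hypot(x - size / 2, y - size / 2)
    return np.abs(d - r) <= half_width


class TestExtractBackbone:
    def test_perfect_annulus_gives_single_closed_loop(self):
        bb = extract_backbone(annulus_mask(r=10.0))
        assert bb.cycle_count == 1
        assert bb.branch_nodes == 0
        assert bb.closed == [True]
        length_px = contour_length(bb, 1.0)
        assert length_px == pytest.approx(2 * math.pi * 10, rel=0.05)

    def test_straight_bar_is_open_without_branches(self):
        mask = np.zeros((32, 32), bool)
        mask[14:18, 4:28] = True
        bb = extract_backbone(mask)
        assert bb.cycle_count == 0
        assert bb.branch_nodes == 0
        assert classify_topology(bb) == TOPOLOGY_OPEN

    def test_figure_eight_mask_has_two_cycles_sharing_node(self, fig8_cell):
        stack, truth = fig8_cell
        cells = segment_cells(stack.plane("phase"))
        from toroquant.imaging_io import deconvolve_stack

        dec = deconvolve_stack(stack)
        cm = threshold_channel(dec.plane("dna"), cells, 1)
        bb = extract_backbone(cm, dec.plane("dna"))
        assert bb.cycle_count == 2
        assert classify_topology(bb) == TOPOLOGY_FIGURE_EIGHT

    def test_tiny_mask_warns_open(self):
        mask = np.zeros((16, 16), bool)
        mask[5, 5] = True
        bb = extract_backbone(mask)
        assert bb.warning
        assert contour_length(bb, 0.065) == 0.0

    def test_deterministic_path_start_and_orientation(self):
        mask = annulus_mask()
        p1 = extract_backbone(mask).primary_path()
        p2 = extract_backbone(mask).primary_path()
        np.testing.assert_array_equal(p1, p2)
        # starts at topmost-then-leftmost skeleton pixel
        assert tuple(p1[0]) == min(map(tuple, p1.astype(int).tolist()))


class TestBackboneExport:
    def test_polyline_json_round_trips(self, tmp_path):
        import json

        from toroquant.morphometry import backbone_to_json

        bb = extract_backbone(annulus_mask())
        text = backbone_to_json(bb, tmp_path / "bb.json")
        payload = json.loads((tmp_path / "bb.json").read_text())
        assert payload == json.loads(text)
        assert payload["cycle_count"] == 1
        assert payload["paths"][0]["closed"] is True
        assert len(payload["paths"][0]["pixels"]) == len(bb.primary_path())


class TestContourLength:
    def test_straight_path_arithmetic(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 3:13] = True  # 10 px straight line -> 9 steps
        bb = extract_backbone(mask)
        assert contour_length(bb, 0.065) == pytest.approx(9 * 0.065)

    def test_recovers_true_contour_on_synthetic_toroid(self, wt_cell):
        stack, truth = wt_cell
        df = tq.analyze_stack(stack)
        measured = df["contour_length_um"][0]
        assert measured == pytest.approx(truth.true_contour_length_um, rel=0.05)

    def test_rotation_changes_length_by_under_2pct(self):
        mask = annulus_mask(r=11.0)
        l0 = contour_length(extract_backbone(mask), 1.0)
        l90 = contour_length(extract_backbone(np.rot90(mask)), 1.0)
        assert abs(l90 - l0) / l0 < 0.02


class TestWidthFwhm:
    def _tube_image(self, sigma_px, size=64, r=18.0):
        y, x = np.mgrid[:size, :size]
        d = np.hypot(x - size / 2, y - size / 2) - r
        return np.exp(-0.5 * (d / sigma_px) ** 2) * 1000.0

    def test_gaussian_tube_fwhm_matches_closed_form(self):
        sigma_px = 0.187 / 0.065
        img = self._tube_image(sigma_px)
        mask = img > 0.4 * img.max()
        bb = extract_backbone(mask)
        fwhm, n_valid, _ = width_fwhm(bb, img, 0.065)
        assert n_valid >= 10
        assert fwhm == pytest.approx(2.3548 * 0.187, rel=0.05)
        assert fwhm == pytest.approx(0.44, abs=0.03)

    def test_scale_invariance(self):
        sigma_px = 2.5
        img = self._tube_image(sigma_px)
        mask = img > 0.4 * img.max()
        bb = extract_backbone(mask)
        f1, _, _ = width_fwhm(bb, img, 0.065)
        f2, _, _ = width_fwhm(bb, img * 2.0, 0.065)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_too_few_stations_flagged_nan(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 5:10] = True
        bb = extract_backbone(mask)
        fwhm, n_valid, _ = width_fwhm(bb, np.ones((20, 20)), 0.065)
        assert math.isnan(fwhm)

    def test_recovers_true_width_on_wildtype_fixture(self, wt_cell):
        stack, truth = wt_cell
        df = tq.analyze_stack(stack)
        assert df["width_fwhm_um"][0] == pytest.approx(truth.true_fwhm_um, rel=0.10)


class TestFeret:
    def test_single_pixel_zero(self):
        assert feret_diameter(np.array([[3, 3]]), 0.065) == 0.0

    def test_two_pixels_five_apart(self):
        assert feret_diameter(np.array([[0, 0], [0, 5]]), 0.065) == pytest.approx(0.325)

    def test_disk_diameter_within_one_pixel(self):
        y, x = np.mgrid[:40, :40]
        disk = np.hypot(x - 20, y - 20) <= 8.0
        coords = np.argwhere(disk)
        assert feret_diameter(coords, 1.0) == pytest.approx(16.0, abs=1.0)


class TestTopologyClassification:
    def test_toroid_fixture(self, wt_cell):
        stack, _ = wt_cell
        df = tq.analyze_stack(stack)
        assert df["topology"][0] == TOPOLOGY_TOROID

    def test_figure_eight_fixture(self, fig8_cell):
        stack, _ = fig8_cell
        df = tq.analyze_stack(stack)
        assert df["topology"][0] == TOPOLOGY_FIGURE_EIGHT

    def test_rotated_fixture_same_class_and_similar_measures(self, wt_cell):
        stack, _ = wt_cell
        rot = tq.MultiChannelStack(
            channels={k: np.rot90(v, axes=(1, 2)).copy() for k, v in stack.channels.items()},
            pixel_size_um=stack.pixel_size_um,
        )
        d0 = tq.analyze_stack(stack)
        d1 = tq.analyze_stack(rot)
        assert d1["topology"][0] == d0["topology"][0] == TOPOLOGY_TOROID
        assert d1["contour_length_um"][0] == pytest.approx(
            d0["contour_length_um"][0], rel=0.02
        )
        assert d1["width_fwhm_um"][0] == pytest.approx(
            d0["width_fwhm_um"][0], rel=0.02
        )
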