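"""Foci detection, colocalization, and compaction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import toroquant as tq
from toroquant.quantify import (
    Focus,
    FociSet,
    compaction_ratio,
    detect_foci,
    focus_overlaps_mask,
    intensity_overlap_fraction,
    qc_foci,
)
from toroquant.segmentation import segment_cells, threshold_channel


def spot_image(centers, sigma=2.3, size=64, amplitude=500.0):
    y, x = np.mgrid[:size, :size]
    img = np.zeros((size, size))
    for r, c in centers:
        img += amplitude * np.exp(-((y - r) ** 2 + (x - c) ** 2) / (2 * sigma**2))
    return img


class TestDetectFoci:
    def test_single_spot_center_within_half_pixel(self):
        img = spot_image([(30.3, 25.7)])
        cell = np.ones((64, 64), bool)
        fs = detect_foci(img, cell, "ori")
        assert fs.count == 1
        err = np.hypot(fs.foci[0].center[0] - 30.3, fs.foci[0].center[1] - 25.7)
        assert err <= 0.5

    def test_two_spots_ten_pixels_apart_found(self):
        img = spot_image([(20, 20), (20, 30)])
        fs = detect_foci(img, np.ones((64, 64), bool), "ori")
        assert fs.count == 2

    def test_two_spots_two_pixels_apart_merge(self):
        img = spot_image([(20, 20), (20, 22)])
        fs = detect_foci(img, np.ones((64, 64), bool), "ori")
        assert fs.count == 1

    def test_zero_foci_is_valid(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(10.0, (64, 64)).astype(float)
        fs = detect_foci(img, np.ones((64, 64), bool), "ter")
        assert fs.count == 0

    def test_separation_beyond_3_psf_sigma_counted_exactly(self):
        """Rendered ori pairs separated by >3 PSF sigma are never merged."""
        import math

        sep_angle = 2 * math.degrees(math.asin(3.6 / (0.716 / 0.065)))
        spec = tq.strain_spec(
            "wildtype", seed=9, ori_angles_deg=(90.0, 90.0 + sep_angle)
        )
        stack, truth = tq.render_cell(spec)
        cells = segment_cells(stack.plane("phase"))
        fs = detect_foci(stack.plane("ori"), cells.mask_of(1), "ori")
        assert fs.count == 2


class TestQcFoci:
    @pytest.mark.parametrize(
        "n_ori,n_ter,keep,flag",
        [
            (1, 2, False, "more_ter_than_ori"),
            (2, 1, True, ""),
            (0, 0, True, "anucleate"),
            (1, 1, True, ""),
        ],
    )
    def test_discard_rule(self, n_ori, n_ter, keep, flag):
        mk = lambda ch, n: FociSet(ch, [Focus((0.0, 0.0), 1.0) for _ in range(n)])
        got_keep, got_flag = qc_foci(mk("ori", n_ori), mk("ter", n_ter))
        assert got_keep is keep and got_flag == flag


class TestIntensityOverlap:
    def test_full_cover_is_100_percent(self):
        img = spot_image([(30, 30)])
        cell = np.ones((64, 64), bool)
        assert intensity_overlap_fraction(img, cell, cell) == pytest.approx(100.0)

    def test_disjoint_mask_is_0_percent(self):
        img = np.zeros((64, 64))
        img[10, 10] = 5.0
        mask = np.zeros((64, 64), bool)
        mask[40:50, 40:50] = True
        assert intensity_overlap_fraction(img, mask, np.ones((64, 64), bool)) == 0.0

    def test_zero_signal_is_undefined(self):
        out = intensity_overlap_fraction(
            np.zeros((8, 8)), np.ones((8, 8), bool), np.ones((8, 8), bool)
        )
        assert np.isnan(out)

    def test_growing_mask_never_decreases_percent(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32))
        cell = np.ones((32, 32), bool)
        vals = []
        for k in (4, 8, 16, 32):
            mask = np.zeros((32, 32), bool)
            mask[:k, :] = True
            vals.append(intensity_overlap_fraction(img, mask, cell))
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_fixture_fraction_recovered_within_2_points(self, wt_population):
        err = (
            wt_population["dna_in_mukb_percent"]
            - 100.0 * wt_population["true_dna_in_mukb_fraction"]
        )
        assert abs(err.mean()) <= 2.0


class TestFocusOverlapsMask:
    def _mask(self):
        m = np.zeros((64, 64), bool)
        m[20:30, 20:30] = True
        return m

    def test_focus_inside_mask(self):
        assert focus_overlaps_mask(Focus((25.0, 25.0), 1.0), self._mask())

    def test_focus_far_away(self):
        assert not focus_overlaps_mask(Focus((60.0, 60.0), 1.0), self._mask())

    def test_focus_tangent_to_edge_counts(self):
        # PSF FWHM 0.35 um / 0.065 um/px: footprint radius ~2.7 px
        assert focus_overlaps_mask(Focus((25.0, 32.0), 1.0), self._mask())


class TestCompactionRatio:
    def test_equal_density_gives_exactly_one(self):
        dna = np.full((32, 32), 7.0)
        dna_mask = np.zeros((32, 32), bool)
        dna_mask[8:24, 8:24] = True
        mukb_mask = np.zeros((32, 32), bool)
        mukb_mask[8:24, 8:16] = True
        res = compaction_ratio(dna, dna_mask, mukb_mask)
        assert res.ratio == 1.0

    def test_double_density_gives_exactly_two(self):
        dna = np.full((32, 32), 3.0)
        dna_mask = np.zeros((32, 32), bool)
        dna_mask[8:24, 8:24] = True
        mukb_mask = np.zeros((32, 32), bool)
        mukb_mask[8:24, 8:16] = True
        dna[mukb_mask] *= 2
        res = compaction_ratio(dna, dna_mask, mukb_mask)
        assert res.ratio == pytest.approx(2.0)

    def test_empty_partition_is_undefined(self):
        dna = np.ones((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        res = compaction_ratio(dna, mask, mask)  # outside partition empty
        assert res.undefined and np.isnan(res.ratio)

    @settings(max_examples=15, deadline=None)
    @given(gain=st.floats(0.1, 50.0))
    def test_invariant_to_positive_rescaling(self, gain):
        rng = np.random.default_rng(3)
        dna = rng.random((24, 24)) + 0.5
        dna_mask = np.zeros((24, 24), bool)
        dna_mask[4:20, 4:20] = True
        mukb_mask = np.zeros((24, 24), bool)
        mukb_mask[4:20, 4:10] = True
        r1 = compaction_ratio(dna, dna_mask, mukb_mask).ratio
        r2 = compaction_ratio(dna * gain, dna_mask, mukb_mask).ratio
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_wildtype_fixture_recovers_18(self, wt_population):
        assert wt_population["compaction_ratio"].mean() == pytest.approx(1.8, abs=0.15)

    def test_mukb_over_ter_keeps_compaction_and_ter_overlap(self):
        """Relocating the MukB arc over ter (the MatP-depleted phenotype)
        leaves the compaction readout intact: the metric does not depend on
        where along the chromosome the condensin domain sits. The fixture
        turns off the local DNA arm bias so the relocation effect is
        isolated from the known bias/threshold interaction."""
        ratios = {}
        for on_ter in (False, True):
            spec = tq.strain_spec(
                "wildtype", seed=6, mukb_on_ter=on_ter, dna_arm_bias=0.0
            )
            stack, truth = tq.render_cell(spec)
            df = tq.analyze_stack(stack)
            ratios[on_ter] = df["compaction_ratio"][0]
            if on_ter:
                assert bool(df["ter_overlaps_mukb"][0])
                assert not bool(df["ori_overlaps_mukb"][0])
        assert ratios[True] == pytest.approx(truth.compaction_factor, abs=0.15)
        assert ratios[True] == pytest.approx(ratios[False], abs=0.12)
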