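"""Segmentation: plane splitting, colour thresholding, regenerate tracing,
tip polygons and ray widths, each checked against per-pixel brute force
or generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import finquant as fq
from finquant.exceptions import (
    EmptyPolygonError,
    EmptyRegenerateError,
    InvalidAnnotationError,
    MissingRayError,
)
from finquant.records import AmputationPlane, RegionMask, ThresholdSpec
from finquant.segmentation import (
    apply_rgb_threshold,
    autotune_red_min,
    distal_tip_polygon,
    ray_widths_at_first_joint,
    segment_regenerate,
    shoelace_area,
    split_by_plane,
)

from conftest import random_plane


class TestSplitByPlane:
    def test_vertical_plane_on_line_pixels_are_distal(self):
        plane = AmputationPlane((0, 5), (9, 5), "right")
        distal, proximal = split_by_plane((10, 10), plane)
        assert distal.n_pixels == 50  # cols 5..9
        assert distal.mask[:, 5].all()

    def test_diagonal_plane_count_difference_is_online_count(self):
        n = 21
        plane = AmputationPlane((0, 0), (n - 1, n - 1), "right")
        distal, proximal = split_by_plane((n, n), plane)
        assert distal.n_pixels - proximal.n_pixels == n  # the diagonal

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        for _ in range(10):
            plane = random_plane(rng, (64, 64))
            distal, proximal = split_by_plane((64, 64), plane)
            assert not (distal.mask & proximal.mask).any()
            assert (distal.mask | proximal.mask).all()

    def test_matches_per_pixel_brute_force(self, rng):
        plane = random_plane(rng, (64, 64))
        distal, _ = split_by_plane((64, 64), plane)
        n = plane.distal_normal
        r0, c0 = plane.p_dorsal
        for r in range(64):
            for c in range(64):
                d = (r - r0) * n[0] + (c - c0) * n[1]
                assert distal.mask[r, c] == (d >= 0)

    def test_degenerate_plane_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            AmputationPlane((3, 3), (3, 3), "up")

    def test_parallel_distal_side_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            AmputationPlane((0, 0), (0, 9), "right")  # plane runs left-right


class TestColourThreshold:
    SPEC = ThresholdSpec(red_min=40)

    def test_all_black_image_gives_empty_mask(self):
        img = np.zeros((8, 8, 3), np.uint8)
        assert apply_rgb_threshold(img, self.SPEC).n_pixels == 0

    @pytest.mark.parametrize(
        "pixel,included",
        [((255, 0, 0), True), ((255, 40, 0), False), ((39, 0, 0), False),
         ((40, 30, 30), True), ((40, 31, 0), False), ((40, 0, 31), False)],
    )
    def test_band_membership_is_conjunctive(self, pixel, included):
        img = np.zeros((1, 1, 3), np.uint8)
        img[0, 0] = pixel
        assert (apply_rgb_threshold(img, self.SPEC).n_pixels == 1) == included

    def test_matches_brute_force_on_random_image(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        mask = apply_rgb_threshold(img, self.SPEC).mask
        for r in range(32):
            for c in range(32):
                p = img[r, c]
                expect = (40 <= p[0] <= 255) and p[1] <= 30 and p[2] <= 30
                assert mask[r, c] == expect

    @given(st.integers(20, 60), st.integers(0, 40))
    @settings(max_examples=25, deadline=None)
    def test_mask_is_antitone_in_red_min(self, red_min, bump):
        img = np.random.default_rng(7).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        lo = apply_rgb_threshold(img, ThresholdSpec(red_min=red_min))
        hi = apply_rgb_threshold(img, ThresholdSpec(red_min=min(255, red_min + bump)))
        assert not (hi.mask & ~lo.mask).any()

    def test_restriction_mask_is_respected(self, rng):
        img = np.full((8, 8, 3), (200, 0, 0), np.uint8)
        region = np.zeros((8, 8), bool)
        region[:4] = True
        m = apply_rgb_threshold(img, self.SPEC, restrict_to=RegionMask(region))
        assert m.n_pixels == 32 and m.mask[:4].all()


class TestAutotune:
    def test_bimodal_red_clamps_to_search_maximum(self):
        img = np.zeros((10, 10, 3), np.uint8)
        img[..., 0] = 10
        img[5:, :, 0] = 200  # Otsu midpoint ~105, beyond the 20-60 range
        distal = RegionMask(np.ones((10, 10), bool))
        tuned = autotune_red_min(img, distal)
        assert tuned.spec.red_min == 60
        assert not tuned.no_signal

    def test_no_signal_flagged_when_red_below_floor(self):
        img = np.full((10, 10, 3), 10, np.uint8)
        tuned = autotune_red_min(img, RegionMask(np.ones((10, 10), bool)))
        assert tuned.no_signal and tuned.spec.red_min == 60

    def test_tuned_mask_recovers_ground_truth(self, default_fin):
        record, truth = default_fin
        distal, _ = split_by_plane(record.fluorescence.shape[:2], record.plane)
        tuned = autotune_red_min(record.fluorescence, distal)
        got = apply_rgb_threshold(
            record.fluorescence, tuned.spec, restrict_to=distal
        ).mask
        want = truth.mineral_mask_distal
        jaccard = (got & want).sum() / (got | want).sum()
        assert jaccard >= 0.95


class TestSegmentRegenerate:
    def test_recovers_ground_truth_area(self, default_fin):
        record, truth = default_fin
        distal, _ = split_by_plane(record.brightfield.shape[:2], record.plane)
        regen = segment_regenerate(record.brightfield, distal)
        assert abs(regen.n_pixels - truth.regenerate_mask.sum()) <= (
            0.02 * truth.regenerate_mask.sum()
        )

    def test_blank_distal_half_is_an_error(self):
        img = np.full((20, 20, 3), 240, np.uint8)
        distal = RegionMask(np.ones((20, 20), bool))
        with pytest.raises(EmptyRegenerateError):
            segment_regenerate(img, distal)

    def test_manual_outline_takes_precedence(self):
        img = np.full((20, 20, 3), 240, np.uint8)
        distal = RegionMask(np.ones((20, 20), bool))
        outline = [(2, 2), (2, 10), (10, 10), (10, 2)]
        regen = segment_regenerate(img, distal, manual_outline=outline)
        from finquant.segmentation import rasterize_outline

        assert (regen.mask == rasterize_outline(outline, (20, 20)).mask).all()


def _mineral_on_plane(rays, shape=(80, 320), r0=60):
    """Rectangular rays rising from a horizontal plane at row r0.

    rays: list of (col_start, width, height)."""
    m = np.zeros(shape, bool)
    for c0, w, h in rays:
        m[r0 - h + 1: r0 + 1, c0: c0 + w] = True
    plane = AmputationPlane((r0, 0), (r0, shape[1] - 1), "up")
    return fq.MineralMask(m), plane


class TestDistalTipPolygon:
    def test_single_ray_gives_triangle_area(self):
        mineral, plane = _mineral_on_plane([(100, 10, 40)])
        poly = distal_tip_polygon(mineral, plane)
        assert len(poly) == 3
        # apex at the leftmost top pixel of the ray, height 39 px above plane
        assert shoelace_area(poly) == pytest.approx(319 * 39 / 2)

    def test_two_equal_rays_give_trapezoid_area(self):
        mineral, plane = _mineral_on_plane([(50, 10, 40), (250, 10, 40)])
        poly = distal_tip_polygon(mineral, plane)
        assert len(poly) == 4
        assert shoelace_area(poly) == pytest.approx(39 * (319 + 200) / 2)

    def test_shoelace_matches_rasterization_oracle(self, rng):
        from skimage.draw import polygon as draw_polygon

        heights = rng.integers(80, 150, 5)
        rays = [(40 + 55 * i, 12, int(h)) for i, h in enumerate(heights)]
        mineral, plane = _mineral_on_plane(rays, shape=(200, 320), r0=160)
        poly = distal_tip_polygon(mineral, plane)
        area = shoelace_area(poly)
        verts = np.asarray(poly, float)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(200, 320))
        assert area == pytest.approx(len(rr), rel=0.01)

    def test_empty_mineral_is_signalled(self):
        mineral, plane = _mineral_on_plane([])
        with pytest.raises(EmptyPolygonError):
            distal_tip_polygon(mineral, plane)

    def test_polygon_tips_cover_all_mineral_heights(self, default_fin):
        record, truth = default_fin
        poly = distal_tip_polygon(
            fq.MineralMask(truth.mineral_mask_distal), record.plane
        )
        tip_rows = {p[0] for p in poly[1:-1]}
        top_row = np.nonzero(truth.mineral_mask_distal.any(axis=1))[0].min()
        assert min(tip_rows) == top_row


class TestRayWidths:
    def _stump(self, width=12, joint_at=10, gap=3, shape=(120, 60)):
        """One ray below a horizontal plane with a joint `joint_at` px down."""
        m = np.zeros(shape, bool)
        r0 = 10
        c0 = 20
        for d in range(1, shape[0] - r0 - 1):
            cycle = (d - 1) % 40
            if joint_at <= cycle < joint_at + gap:
                continue
            m[r0 + d, c0: c0 + width] = True
        plane = AmputationPlane((r0, 0), (r0, shape[1] - 1), "up")
        return fq.MineralMask(m), plane

    def test_constant_width_ray_measured_exactly(self):
        mineral, plane = self._stump(width=12)
        assert ray_widths_at_first_joint(mineral, plane) == [12.0]

    def test_mask_without_gaps_raises(self):
        m = np.zeros((60, 30), bool)
        m[11:55, 10:20] = True
        plane = AmputationPlane((10, 0), (10, 29), "up")
        with pytest.raises(MissingRayError):
            ray_widths_at_first_joint(fq.MineralMask(m), plane)

    def test_manual_widths_take_precedence(self):
        mineral, plane = self._stump(width=12)
        assert ray_widths_at_first_joint(
            mineral, plane, manual_widths_px=[7.5, 8.5]
        ) == [7.5, 8.5]

    def test_generator_truth_recovered_within_one_pixel(self, default_fin):
        record, truth = default_fin
        _, proximal = split_by_plane(record.fluorescence.shape[:2], record.plane)
        tuned = autotune_red_min(
            record.fluorescence,
            RegionMask(np.ones(record.fluorescence.shape[:2], bool)),
        )
        mineral = apply_rgb_threshold(
            record.fluorescence, tuned.spec, restrict_to=proximal
        )
        widths = ray_widths_at_first_joint(mineral, record.plane)
        assert len(widths) == len(truth.ray_widths_first_joint_px)
        for got, want in zip(sorted(widths), sorted(truth.ray_widths_first_joint_px)):
            assert abs(got - want) <= 1.0
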