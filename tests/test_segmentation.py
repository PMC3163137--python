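"""Segmentation chain: color transform, wall/tissue/lumen detection, assembly."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import lymphquant as lq
from lymphquant.errors import (
    DegenerateHistogramError,
    EstimationError,
    RegistrationError,
)
from lymphquant.synthgen import GLASS_RGB, TISSUE_RGB, WALL_RGB

from conftest import small_config


def _image(pixels):
    return lq.SlideImage(np.asarray(pixels, dtype=np.uint8), 1.0)


def _flat(color, shape=(50, 50)):
    px = np.empty((*shape, 3), dtype=np.uint8)
    px[:] = color
    return px


class TestExcessRed:
    @pytest.mark.parametrize(
        "rgb, expected",
        [((255, 0, 0), 510), ((0, 255, 255), -510), ((7, 7, 7), 0),
         ((100, 50, 30), 120), ((0, 0, 0), 0)],
    )
    def test_formula(self, rgb, expected):
        image = _image(_flat(rgb, (2, 2)))
        assert (lq.excess_red(image) == expected).all()

    def test_signed_range_not_clamped(self):
        px = _flat((0, 255, 255), (4, 4))
        px[0, 0] = (255, 0, 0)
        er = lq.excess_red(_image(px))
        assert er.min() == -510 and er.max() == 510


class TestDetectWalls:
    def test_pure_red_disc_on_grey_is_recovered(self):
        px = _flat((128, 128, 128), (120, 120))
        rr, cc = np.ogrid[:120, :120]
        disc = (rr - 60) ** 2 + (cc - 60) ** 2 <= 30**2
        px[disc] = (255, 0, 0)
        mask, t = lq.detect_walls(_image(px))
        # exact up to a 1-px boundary ring
        boundary = ndimage.binary_dilation(disc) & ~ndimage.binary_erosion(disc)
        mismatch = mask.values ^ disc
        assert not (mismatch & ~boundary).any()

    def test_no_red_excess_is_degenerate(self):
        px = _flat((90, 90, 90))
        with pytest.raises(DegenerateHistogramError):
            lq.detect_walls(_image(px))

    def test_synthetic_rings_are_covered(self, small_slide):
        image, truth = small_slide
        wall_mask, t = lq.detect_walls(image)
        ps = image.pixel_size_um
        rr, cc = np.mgrid[: image.shape[0], : image.shape[1]]
        for v in truth.vessels.itertuples():
            d2 = (rr - v.row) ** 2 + (cc - v.col) ** 2
            annulus = (d2 <= (v.outer_radius_um / ps) ** 2) & (
                d2 > (v.lumen_radius_um / ps) ** 2
            )
            covered = (wall_mask.values & annulus).sum() / annulus.sum()
            assert covered >= 0.8, f"vessel {v.label}: wall coverage {covered:.2f}"

    def test_min_area_filter_is_monotone_in_vessel_count(self, small_slide):
        image, _ = small_slide
        counts = []
        for min_area in (0, 20, 200, 2000):
            cfg = lq.SegmentationConfig(min_wall_area_px=min_area)
            counts.append(lq.segment_slide(image, cfg).vessel_count)
        assert counts == sorted(counts, reverse=True)


class TestDetectTissue:
    def test_tissue_blob_recovered_at_decimated_scale(self):
        # vessel-free slide: lumens are glass-bright, so only a plain tissue
        # blob on glass has a fully tissue-colored ground truth
        image, truth = lq.generate_slide(small_config(n_vessels=0, seed=3))
        tissue, t = lq.detect_tissue(image)
        assert tissue.pixel_size_um == pytest.approx(8 * image.pixel_size_um)
        truth_dec = lq.decimate_binary(truth.tissue_mask, 8)
        overlap = (tissue.values & truth_dec.values).sum() / truth_dec.values.sum()
        assert overlap >= 0.95

    def test_all_glass_image_is_degenerate(self):
        px = _flat(GLASS_RGB, (64, 64))
        with pytest.raises(DegenerateHistogramError):
            lq.detect_tissue(_image(px))

    def test_full_resolution_area_consistent_with_decimated(self, small_slide):
        image, _ = small_slide
        t8, _ = lq.detect_tissue(image, factor=8)
        t1, _ = lq.detect_tissue(image, factor=1)
        assert t1.area_mm2() == pytest.approx(t8.area_mm2(), rel=0.1)

    def test_polarity_override_inverts_the_mask(self, small_slide):
        image, _ = small_slide
        dark, t = lq.detect_tissue(image)
        light, _ = lq.detect_tissue(
            image, config=lq.SegmentationConfig(tissue_polarity="light")
        )
        assert not (dark.values & light.values).any()


class TestDetectLumens:
    def _ring_image(self):
        """Ring wall with bright interior + a far bright hole in tissue."""
        px = _flat(TISSUE_RGB, (200, 200))
        px[:, :20] = GLASS_RGB  # background strip for mu_bg estimation
        rr, cc = np.ogrid[:200, :200]
        d2 = (rr - 100) ** 2 + (cc - 60) ** 2
        ring = (d2 <= 20**2) & (d2 > 14**2)
        interior = d2 <= 14**2
        hole = (rr - 100) ** 2 + (cc - 160) ** 2 <= 12**2
        px[interior] = (250, 250, 250)
        px[hole] = (250, 250, 250)
        px[ring] = WALL_RGB
        tissue = np.ones((200, 200), dtype=bool)
        tissue[:, :20] = False
        return _image(px), lq.BinaryMask(ring, 1.0, "wall"), \
            lq.BinaryMask(tissue, 1.0, "tissue"), interior, hole

    def test_interior_kept_far_hole_discarded(self):
        image, wall, tissue, interior, hole = self._ring_image()
        lumen, threshold = lq.detect_lumens(image, wall, tissue)
        assert (lumen.values & interior).sum() / interior.sum() > 0.9
        assert not (lumen.values & hole).any()

    def test_collapsed_vessel_yields_no_lumen_but_wall_still_counts(self):
        image, wall, tissue, interior, hole = self._ring_image()
        # overwrite the bright interior with tissue -> collapsed vessel
        image.pixels[interior] = TISSUE_RGB
        lumen, _ = lq.detect_lumens(image, wall, tissue)
        assert not (lumen.values & interior).any()
        labels, excluded = lq.assemble_vessels(wall, lumen)
        assert labels.max() == 1  # the wall alone still forms one vessel

    def test_every_kept_lumen_touches_a_wall(self):
        image, truth = lq.generate_slide(small_config(seed=2))
        wall, _ = lq.detect_walls(image)
        tissue, _ = lq.detect_tissue(image)
        lumen, _ = lq.detect_lumens(image, wall, tissue)
        labels, n = ndimage.label(lumen.values, structure=np.ones((3, 3)))
        wall_dilated = ndimage.binary_dilation(
            wall.values, structure=np.ones((3, 3))
        )
        touching = set(np.unique(labels[wall_dilated & (labels > 0)]))
        assert touching == set(range(1, n + 1))

    def test_tissue_covering_everything_prevents_background_estimate(self):
        image, wall, _, _, _ = self._ring_image()
        tissue = lq.BinaryMask(np.ones((200, 200), bool), 1.0, "tissue")
        with pytest.raises(EstimationError):
            lq.detect_lumens(image, wall, tissue)


class TestAssembleVessels:
    def test_bridged_rings_are_one_object(self):
        wall = np.zeros((40, 80), dtype=bool)
        rr, cc = np.ogrid[:40, :80]
        for cx in (20, 60):
            d2 = (rr - 20) ** 2 + (cc - cx) ** 2
            wall |= (d2 <= 15**2) & (d2 > 10**2)
        wall[20, 20:60] = True  # 1-px bridge
        labels, _ = lq.assemble_vessels(
            lq.BinaryMask(wall, 1.0), lq.BinaryMask(np.zeros_like(wall), 1.0)
        )
        assert labels.max() == 1

    def test_hole_filling_makes_solid_objects(self):
        wall = np.zeros((40, 40), dtype=bool)
        rr, cc = np.ogrid[:40, :40]
        d2 = (rr - 20) ** 2 + (cc - 20) ** 2
        wall |= (d2 <= 15**2) & (d2 > 10**2)
        labels, _ = lq.assemble_vessels(
            lq.BinaryMask(wall, 1.0), lq.BinaryMask(np.zeros_like(wall), 1.0)
        )
        assert labels[20, 20] == 1  # lumen pixels filled even with no lumen mask

    def test_exclusion_mask_drops_whole_objects(self):
        wall = np.zeros((30, 90), dtype=bool)
        wall[10:20, 10:20] = True
        wall[10:20, 40:50] = True
        wall[10:20, 70:80] = True
        exclusion = np.zeros_like(wall)
        exclusion[15, 45] = True  # touches only the middle object
        labels, excluded = lq.assemble_vessels(
            lq.BinaryMask(wall, 1.0),
            lq.BinaryMask(np.zeros_like(wall), 1.0),
            lq.BinaryMask(exclusion, 1.0, "exclusion"),
        )
        assert len(excluded) == 1
        remaining = set(np.unique(labels)) - {0}
        assert len(remaining) == 2 and excluded[0] not in remaining

    def test_no_exclusion_keeps_everything(self):
        wall = np.zeros((20, 20), dtype=bool)
        wall[5:10, 5:10] = True
        labels, excluded = lq.assemble_vessels(
            lq.BinaryMask(wall, 1.0), lq.BinaryMask(np.zeros_like(wall), 1.0)
        )
        assert excluded == [] and labels.max() == 1

    def test_shape_mismatch_is_a_registration_error(self):
        with pytest.raises(RegistrationError):
            lq.assemble_vessels(
                lq.BinaryMask(np.zeros((10, 10), bool), 1.0),
                lq.BinaryMask(np.zeros((12, 10), bool), 1.0),
            )


class TestEndToEnd:
    def test_segmentation_is_deterministic(self, small_slide):
        image, _ = small_slide
        a = lq.segment_slide(image)
        b = lq.segment_slide(image)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        np.testing.assert_array_equal(a.wall_mask.values, b.wall_mask.values)
        assert a.wall_threshold == b.wall_threshold
        assert a.tissue_threshold == b.tissue_threshold

    def test_confounders_are_excluded_by_mask(self):
        image, truth = lq.generate_slide(
            small_config(n_vessels=10, n_confounders=3, seed=11)
        )
        exclusion = lq.exclusion_from_confounders(truth)
        res = lq.segment_slide(image, exclusion_mask=exclusion)
        assert res.vessel_count == 10
        assert len(res.excluded_labels) == 3

    def test_result_masks_are_consistent(self, small_segmentation):
        res = small_segmentation
        assert not (res.lumen_mask.values & res.wall_mask.values).any()
        union = res.wall_mask.values | res.lumen_mask.values
        filled = ndimage.binary_fill_holes(union)
        assert (res.vessel_mask.values == filled).all()
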