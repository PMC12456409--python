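"""Segmentation, front-rear geometry, intensity ratios, profiles, foci."""

import numpy as np
import pytest

from dcmigration import polarity as pol
from dcmigration import synthetic as syn
from dcmigration.datatypes import CellImage
from dcmigration.errors import GeometryError, SegmentationError


@pytest.fixture
def clean_cell():
    """Noise-free rear-bright cell with the nucleus shifted toward the rear."""
    spec = syn.PolarizedCellSpec(rear_front_ratio=2.0, noise_sd=0.0,
                                 nucleus_offset=-5.0, seed=0)
    return syn.generate_polarized_cell_image(spec), spec


def _geometry(img):
    cell = pol.segment_cell(img, "signal")
    nuc = pol.segment_cell(img, "nucleus") & cell
    return pol.compute_geometry(cell, nuc, img.pixel_size)


class TestSegmentation:
    def test_noise_free_ellipse_recovered_within_boundary_band(self, clean_cell):
        img, _ = clean_cell
        mask = pol.segment_cell(img, "signal")
        truth = img.channel("mask_truth") > 0
        disagree = mask ^ truth
        from scipy import ndimage

        boundary_band = truth ^ ndimage.binary_erosion(truth, iterations=1)
        boundary_band |= ndimage.binary_dilation(truth, iterations=1) ^ truth
        assert not np.any(disagree & ~boundary_band)

    def test_all_background_is_error(self):
        img = CellImage({"signal": np.zeros((20, 20))}, pixel_size=0.2)
        with pytest.raises(SegmentationError):
            pol.segment_cell(img, "signal")

    def test_larger_of_two_objects_retained(self):
        arr = np.zeros((40, 40))
        arr[5:10, 5:10] = 100.0   # 25 px
        arr[20:32, 20:32] = 100.0  # 144 px
        img = CellImage({"signal": arr}, pixel_size=0.2)
        mask = pol.segment_cell(img, "signal")
        assert mask[25, 25] and not mask[7, 7]


class TestGeometry:
    def test_offset_nucleus_distances(self, clean_cell):
        img, spec = clean_cell
        geom = _geometry(img)
        gt = img.metadata["ground_truth"]
        assert geom.rear_distance == pytest.approx(gt["rear_distance_um"],
                                                   abs=img.pixel_size)
        assert geom.front_distance == pytest.approx(gt["front_distance_um"],
                                                    abs=img.pixel_size)
        assert geom.rear_distance <= geom.front_distance

    def test_centered_nucleus_is_tie_broken_and_flagged(self):
        spec = syn.PolarizedCellSpec(nucleus_offset=0.0, noise_sd=0.0, seed=0)
        img = syn.generate_polarized_cell_image(spec)
        geom = _geometry(img)
        assert geom.tie
        assert geom.rear_distance == pytest.approx(geom.front_distance, abs=0.3)

    def test_truth_offsets_recovered_over_seeds(self):
        """Nucleus-to-edge distances match generator truth within 1 px, 20 seeds."""
        for seed in range(20):
            spec = syn.PolarizedCellSpec(nucleus_offset=-5.0, noise_sd=5.0, seed=seed)
            img = syn.generate_polarized_cell_image(spec)
            geom = _geometry(img)
            gt = img.metadata["ground_truth"]
            assert geom.rear_distance == pytest.approx(gt["rear_distance_um"],
                                                       abs=2 * img.pixel_size)

    def test_nucleus_outside_cell_rejected(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        nuc = np.zeros_like(cell)
        nuc[0:3, 0:3] = True
        with pytest.raises(GeometryError):
            pol.compute_geometry(cell, nuc, 0.2)

    def test_rear_always_shorter_distance_across_offsets(self):
        for offset in (-8.0, -3.0, 3.0, 8.0):
            spec = syn.PolarizedCellSpec(nucleus_offset=offset, noise_sd=0.0, seed=1)
            img = syn.generate_polarized_cell_image(spec)
            geom = _geometry(img)
            assert geom.rear_distance <= geom.front_distance


class TestRearFrontRatio:
    def test_uniform_cell_ratio_one(self):
        spec = syn.PolarizedCellSpec(rear_front_ratio=1.0, noise_sd=0.0,
                                     nucleus_offset=-5.0, seed=0)
        img = syn.generate_polarized_cell_image(spec)
        geom = _geometry(img)
        assert pol.rear_front_ratio(img, geom) == pytest.approx(1.0, abs=1e-6)

    def test_recovery_with_noise_over_seeds(self):
        """R_true=2 with 5% noise recovered within 5% over 20 seeds."""
        ratios = []
        for seed in range(20):
            spec = syn.PolarizedCellSpec(rear_front_ratio=2.0, noise_sd=5.0, seed=seed)
            img = syn.generate_polarized_cell_image(spec)
            ratios.append(pol.rear_front_ratio(img, _geometry(img)))
        np.testing.assert_allclose(ratios, 2.0, rtol=0.05)

    def test_swapping_rear_front_labels_inverts_the_ratio(self, clean_cell):
        """Flipping the polarity axis (rear and front interchange) maps the
        measured ratio R to 1/R."""
        img, _ = clean_cell
        geom = _geometry(img)
        r = pol.rear_front_ratio(img, geom)
        flipped = pol.CellGeometry(
            cell_mask=geom.cell_mask,
            nucleus_mask=geom.nucleus_mask,
            pixel_size=geom.pixel_size,
            axis=-geom.axis,
            rear_point=geom.front_point,
            front_point=geom.rear_point,
            rear_distance=geom.front_distance,
            front_distance=geom.rear_distance,
            nucleus_centroid=geom.nucleus_centroid,
        )
        r_f = pol.rear_front_ratio(img, flipped)
        assert r * r_f == pytest.approx(1.0, abs=1e-2)

    def test_canvas_padding_does_not_change_ratio(self, clean_cell):
        img, _ = clean_cell
        r = pol.rear_front_ratio(img, _geometry(img))
        padded = CellImage(
            {k: np.pad(v, 30) for k, v in img.channels.items()}, img.pixel_size
        )
        r_p = pol.rear_front_ratio(padded, _geometry(padded))
        assert r_p == pytest.approx(r, abs=1e-9)


class TestLineProfile:
    def test_uniform_cell_flat_at_one(self):
        spec = syn.PolarizedCellSpec(rear_front_ratio=1.0, noise_sd=0.0,
                                     nucleus_offset=-5.0, seed=0)
        img = syn.generate_polarized_cell_image(spec)
        prof = pol.width_averaged_profile(img, _geometry(img), from_end="rear")
        np.testing.assert_allclose(prof.intensity, 1.0, atol=1e-6)

    def test_rear_bright_profile_steps_down_past_nucleus(self, clean_cell):
        img, spec = clean_cell
        geom = _geometry(img)
        prof = pol.width_averaged_profile(img, geom, from_end="rear")
        assert prof.intensity[0] == pytest.approx(1.0, abs=0.02)
        # the step sits at the nucleus centroid: rear extent = 25-5 = 20 µm
        rear_extent = spec.cell_axes[0] / 2 + spec.nucleus_offset
        before = prof.intensity[prof.offsets < rear_extent - 2.0]
        after = prof.intensity[prof.offsets > rear_extent + 2.0]
        assert before.mean() > 0.95
        assert after.mean() < 0.6

    def test_per_cell_max_is_one(self):
        for seed in range(5):
            spec = syn.PolarizedCellSpec(noise_sd=5.0, seed=seed)
            img = syn.generate_polarized_cell_image(spec)
            prof = pol.width_averaged_profile(img, _geometry(img), from_end="rear",
                                              length=50.0)
            assert np.nanmax(prof.intensity) == pytest.approx(1.0)

    def test_group_average_is_mean_of_normalized_profiles(self, clean_cell):
        img, _ = clean_cell
        geom = _geometry(img)
        p1 = pol.width_averaged_profile(img, geom, from_end="rear")
        p2 = pol.width_averaged_profile(img, geom, from_end="front")
        grp = pol.average_profiles([p1, p2])
        n = min(len(p1.intensity), len(p2.intensity))
        np.testing.assert_allclose(
            grp["mean"][:n], (p1.intensity[:n] + p2.intensity[:n]) / 2
        )


class TestFociCounting:
    def _disk_image(self, centers, radius=3, shape=(100, 100), px=1.0):
        arr = np.zeros(shape)
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        for r0, c0 in centers:
            arr[(rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2] = 100.0
        return CellImage({"foci": arr, "mask": np.ones(shape)}, pixel_size=px)

    def test_planted_disks_counted_exactly(self):
        centers = [(10, 10), (10, 40), (10, 70), (40, 10), (40, 40), (40, 70), (70, 10)]
        img = self._disk_image(centers)
        mask = np.zeros((100, 100), dtype=bool)
        mask[:80, :80] = True  # 6400 px = 6400 µm² at 1 µm/px
        res = pol.count_foci(img, mask, "foci", threshold=50.0)
        assert res["count"] == 7
        assert res["density_per_um2"] == pytest.approx(7 / 6400)

    def test_empty_channel_counts_zero(self):
        img = CellImage({"foci": np.zeros((50, 50))}, pixel_size=0.5)
        mask = np.ones((50, 50), dtype=bool)
        res = pol.count_foci(img, mask, "foci", threshold=10.0)
        assert res["count"] == 0.0

    def test_recovery_over_seeds_nonoverlapping(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            centers = [(15 + 20 * (i // 4), 15 + 20 * (i % 4)) for i in range(n)]
            img = self._disk_image(centers)
            mask = np.ones((100, 100), dtype=bool)
            res = pol.count_foci(img, mask, "foci", threshold=50.0)
            assert res["count"] == n


class TestRegionCounting:
    def test_objects_in_annulus(self):
        arr = np.zeros((120, 120))
        rows, cols = np.mgrid[0:120, 0:120]
        rr = np.hypot(rows - 60, cols - 60)
        centers = [(60 + int(45 * np.cos(a)), 60 + int(45 * np.sin(a)))
                   for a in np.linspace(0, 2 * np.pi, 12, endpoint=False)]
        for r0, c0 in centers:
            arr[(rows - r0) ** 2 + (cols - c0) ** 2 <= 4] = 50.0
        img = CellImage({"cells": arr}, pixel_size=1.0)
        annulus = (rr >= 35) & (rr <= 55)
        assert pol.count_objects_in_region(img, annulus, "cells", threshold=25.0) == 12

    def test_empty_region_counts_zero(self):
        img = CellImage({"cells": np.zeros((30, 30))}, pixel_size=1.0)
        region = np.ones((30, 30), dtype=bool)
        assert pol.count_objects_in_region(img, region, "cells", threshold=5.0) == 0

    def test_count_invariant_to_annulus_rotation(self):
        arr = np.zeros((121, 121))
        rows, cols = np.mgrid[0:121, 0:121]
        rng = np.random.default_rng(4)
        for _ in range(8):
            a = rng.uniform(0, 2 * np.pi)
            r0, c0 = 60 + int(44 * np.cos(a)), 60 + int(44 * np.sin(a))
            arr[(rows - r0) ** 2 + (cols - c0) ** 2 <= 4] = 80.0
        img = CellImage({"cells": arr}, pixel_size=1.0)
        rr = np.hypot(rows - 60, cols - 60)
        base = (rr >= 35) & (rr <= 55)
        rotated = np.rot90(base).copy()
        assert pol.count_objects_in_region(img, base, "cells", threshold=40.0) == \
            pol.count_objects_in_region(img, rotated, "cells", threshold=40.0)
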