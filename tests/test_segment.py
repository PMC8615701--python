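"""Segmentation: nuclei, rings, organoids, cell area, core/periphery."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from organotrace.segment import (
    LabelImage, assign_core_periphery, derive_cytoplasm_rings,
    estimate_background, segment_cell_area, segment_nuclei,
    segment_organoids,
)
from organotrace.simulate import (
    ImagingConfig, organoid_cell_layout, random_cell_layout,
    render_monolayer_frame, render_tubulin_frame,
)


def disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


class TestSegmentNuclei:
    def test_recovers_exact_count_noise_free(self, imaging_noise_free):
        cells = random_cell_layout(12, imaging_noise_free, seed=4)
        img, _ = render_monolayer_frame(cells, imaging_noise_free, 1)
        nuclei = segment_nuclei(img[0])
        assert nuclei.n_objects == 12
        # labels consecutive from 1
        assert sorted(np.unique(nuclei.labels)) == list(range(13))

    def test_background_only_image_gives_empty_mask(self, imaging_default):
        img, _ = render_monolayer_frame([], imaging_default, 1)
        nuclei = segment_nuclei(img[0])
        assert nuclei.n_objects == 0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((128, 128))
        img[disk_mask(img.shape, 50, 64, 14)] += 400.0
        img[disk_mask(img.shape, 76, 64, 14)] += 400.0
        img = ndi.gaussian_filter(img, 1.5) + 100.0
        nuclei = segment_nuclei(img)
        assert nuclei.n_objects == 2
        centroids = ndi.center_of_mass(np.ones_like(nuclei.labels),
                                       nuclei.labels, [1, 2])
        cols = sorted(c for _, c in centroids)
        assert cols[0] == pytest.approx(50, abs=3)
        assert cols[1] == pytest.approx(76, abs=3)

    def test_area_filter_drops_outliers(self):
        img = np.zeros((128, 128))
        img[disk_mask(img.shape, 30, 30, 14)] += 400.0  # area ~615 px
        img[disk_mask(img.shape, 90, 90, 4)] += 400.0   # area ~50 px
        img = ndi.gaussian_filter(img, 1.5) + 100.0
        nuclei = segment_nuclei(img, min_area_px=120, max_area_px=5000)
        assert nuclei.n_objects == 1

    def test_invalid_area_bounds_rejected(self):
        with pytest.raises(ValueError, match="min_area_px"):
            segment_nuclei(np.zeros((8, 8)), min_area_px=10, max_area_px=5)


class TestCytoplasmRings:
    def test_ring_area_matches_analytic_annulus(self):
        labels = disk_mask((64, 64), 32, 32, 10).astype(np.int32)
        rings = derive_cytoplasm_rings(LabelImage(labels, 1.0), 5)
        expected = math.pi * (15**2 - 10**2)
        assert (rings.labels == 1).sum() == pytest.approx(expected, rel=0.08)

    def test_rings_disjoint_and_touch_their_nucleus(self):
        labels = np.zeros((64, 96), np.int32)
        labels[disk_mask(labels.shape, 30, 32, 10)] = 1
        labels[disk_mask(labels.shape, 58, 32, 10)] = 2
        nuclei = LabelImage(labels, 1.0)
        rings = derive_cytoplasm_rings(nuclei, 8)
        assert not ((rings.labels > 0) & (labels > 0)).any()
        for k in (1, 2):
            ring = rings.labels == k
            grown = ndi.binary_dilation(labels == k)
            assert (ring & grown).any()  # ring touches its nucleus
        # nearest-nucleus partition: no ring pixel closer to the other nucleus
        d1 = ndi.distance_transform_edt(labels != 1)
        d2 = ndi.distance_transform_edt(labels != 2)
        assert np.all(d1[rings.labels == 1] <= d2[rings.labels == 1])
        assert np.all(d2[rings.labels == 2] <= d1[rings.labels == 2])

    def test_ring_clipped_at_image_border(self):
        labels = disk_mask((40, 40), 3, 20, 6).astype(np.int32)
        rings = derive_cytoplasm_rings(LabelImage(labels, 1.0), 5)
        assert rings.labels.shape == (40, 40)
        assert (rings.labels == 1).any()

    def test_ring_width_validated(self):
        with pytest.raises(ValueError):
            derive_cytoplasm_rings(LabelImage(np.zeros((8, 8), int), 1.0), 0)


class TestSegmentOrganoids:
    def _organoid_frame(self, cfg, centers_px, radius_px, seed=1):
        cells = []
        for i, c in enumerate(centers_px):
            cells += organoid_cell_layout(6, radius_px, c, seed + i,
                                          nucleus_radius_px=8.0,
                                          cyto_radius_px=8.0 * math.sqrt(2))
        return render_monolayer_frame(cells, cfg, seed)

    def test_counts_and_centroids_recovered(self):
        cfg = ImagingConfig(width_px=512, height_px=512, noise_sd=0.0)
        centers = [(120.0, 120.0), (380.0, 140.0), (250.0, 390.0)]
        img, _ = self._organoid_frame(cfg, centers, 60.0)
        mask, records = segment_organoids(img[0], img[1], cfg.pixel_size_um,
                                          closing_radius_px=25.0)
        assert len(records) == 3
        found = sorted((r.centroid_xy_um[0], r.centroid_xy_um[1])
                       for r in records)
        expected = sorted(((x + 0.5) * cfg.pixel_size_um,
                           (y + 0.5) * cfg.pixel_size_um)
                          for x, y in centers)
        cell_radius_um = 60.0 * cfg.pixel_size_um
        for (fx, fy), (ex, ey) in zip(found, expected):
            assert math.hypot(fx - ex, fy - ey) < cell_radius_um

    def test_size_class_threshold_membership(self):
        cfg = ImagingConfig(noise_sd=0.0)
        psz = cfg.pixel_size_um
        for area_um2, expected in ((10000.0, "large"), (5000.0, "small")):
            r_px = math.sqrt(area_um2 / math.pi) / psz
            img = np.where(disk_mask((512, 512), 256, 256, r_px), 800.0, 100.0)
            _, records = segment_organoids(img, img, psz,
                                           closing_radius_px=0.0)
            assert len(records) == 1
            assert records[0].size_class == expected
            # the low triangle threshold overshoots the blurred disk edge
            assert records[0].area_um2 == pytest.approx(area_um2, rel=0.15)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            segment_organoids(np.zeros((8, 8)), np.zeros((9, 8)), 1.0)

    def test_area_invariant_under_pixel_size(self):
        """Halving the pixel size quadruples pixel count but leaves the
        physical area unchanged within 2%."""
        areas = []
        for psz, r_px, sigma in ((0.65, 80.0, 3.0), (0.325, 160.0, 6.0)):
            img = np.where(disk_mask((512, 512), 256, 256, r_px), 800.0, 100.0)
            _, recs = segment_organoids(img, img, psz, closing_radius_px=0.0,
                                        smooth_sigma=sigma)
            areas.append(recs[0].area_um2)
        assert abs(areas[0] - areas[1]) / areas[1] < 0.02

    def test_count_recovery_over_random_layouts(self):
        """Organoid count matches ground truth in >=95% of random
        non-overlapping layouts (noise off)."""
        cfg = ImagingConfig(width_px=448, height_px=448, noise_sd=0.0)
        rng = np.random.default_rng(0)
        hits = 0
        n_layouts = 40
        for trial in range(n_layouts):
            centers = []
            while len(centers) < 2:
                c = rng.uniform(80, 368, size=2)
                if all(np.hypot(*(c - np.array(o))) > 140 for o in centers):
                    centers.append(tuple(c))
            img, _ = self._organoid_frame(cfg, centers, 55.0,
                                          seed=100 + 3 * trial)
            _, records = segment_organoids(img[0], img[1], cfg.pixel_size_um,
                                           closing_radius_px=25.0)
            hits += len(records) == 2
        assert hits >= 0.95 * n_layouts


class TestCorePeriphery:
    def test_matches_analytic_distance_rule(self):
        """In a circular organoid of radius 150 px, nuclei <= 100 px from
        the boundary are periphery, deeper ones core."""
        org = LabelImage(disk_mask((400, 400), 200, 200, 150).astype(np.int32),
                         1.0)
        nuc_labels = np.zeros((400, 400), np.int32)
        truths = {}
        label = 0
        for depth in list(range(5, 96, 10)) + list(range(105, 150, 10)):
            label += 1
            r = 150 - depth
            x = 200 + r * math.cos(0.7 * label)
            y = 200 + r * math.sin(0.7 * label)
            nuc_labels[disk_mask((400, 400), x, y, 3)] = label
            truths[label] = "periphery" if depth <= 100 else "core"
        out = assign_core_periphery(org, LabelImage(nuc_labels, 1.0), 100)
        assert len(out) == label
        for a in out:
            assert a.zone == truths[a.nucleus_id]

    def test_small_organoid_is_all_periphery(self):
        org = LabelImage(disk_mask((256, 256), 128, 128, 90).astype(np.int32),
                         1.0)
        nuc = np.zeros((256, 256), np.int32)
        nuc[disk_mask((256, 256), 128, 128, 4)] = 1     # dead center
        nuc[disk_mask((256, 256), 170, 128, 4)] = 2
        out = assign_core_periphery(org, LabelImage(nuc, 1.0), 100)
        assert {a.zone for a in out} == {"periphery"}

    def test_partitions_all_in_organoid_nuclei(self):
        org = LabelImage(disk_mask((300, 300), 150, 150, 140).astype(np.int32),
                         1.0)
        nuc = np.zeros((300, 300), np.int32)
        for k, (x, y) in enumerate([(150, 150), (150, 60), (240, 150),
                                    (60, 150), (150, 240)], start=1):
            nuc[disk_mask((300, 300), x, y, 4)] = k
        out = assign_core_periphery(org, LabelImage(nuc, 1.0), 100)
        assert len(out) == 5  # every nucleus got exactly one zone

    def test_nucleus_outside_organoid_skipped(self):
        org = LabelImage(disk_mask((128, 128), 40, 40, 20).astype(np.int32),
                         1.0)
        nuc = np.zeros((128, 128), np.int32)
        nuc[disk_mask((128, 128), 100, 100, 4)] = 1
        assert assign_core_periphery(org, LabelImage(nuc, 1.0), 10) == []

    def test_rim_width_validated(self):
        org = LabelImage(np.ones((8, 8), np.int32), 1.0)
        with pytest.raises(ValueError):
            assign_core_periphery(org, org, 0)


class TestCellArea:
    def test_tubulin_footprint_iou(self):
        cfg = ImagingConfig(width_px=256, height_px=256, noise_sd=0.0)
        img, truth_mask = render_tubulin_frame(0.3, cfg, 5)
        mask = segment_cell_area(img)
        found = mask.labels > 0
        iou = (found & truth_mask).sum() / (found | truth_mask).sum()
        assert iou > 0.9

    def test_background_only_frame_empty(self, imaging_default):
        img, _ = render_monolayer_frame([], imaging_default, 1)
        assert segment_cell_area(img[0]).n_objects == 0

    def test_uniform_positive_frame_fully_foreground(self):
        mask = segment_cell_area(np.full((32, 32), 500.0))
        assert (mask.labels == 1).all()

    def test_zero_frame_empty(self):
        assert segment_cell_area(np.zeros((32, 32))).n_objects == 0


class TestBackground:
    def test_recovers_generator_background_exactly(self, imaging_noise_free):
        cells = random_cell_layout(5, imaging_noise_free, seed=2)
        img, _ = render_monolayer_frame(cells, imaging_noise_free, 1)
        fg = img[1] > imaging_noise_free.background_level
        assert estimate_background(img[1], fg) == 100.0

    def test_all_foreground_uses_percentile_fallback(self):
        img = np.linspace(0, 100, 64 * 64).reshape(64, 64)
        value = estimate_background(img, np.ones((64, 64), bool))
        assert value == pytest.approx(np.percentile(img, 5))

    def test_zero_image(self):
        assert estimate_background(np.zeros((16, 16)),
                                   np.zeros((16, 16), bool)) == 0.0
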