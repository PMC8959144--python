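"""ROI extraction, background subtraction, detection and count tables."""

import numpy as np
import pandas as pd
import pytest

from ponsquant import counting
from ponsquant.counting import (
    UNASSIGNED,
    count_per_region,
    count_section,
    detect_objects,
    extract_rois,
    filter_by_circularity,
    normalize_counts,
    subtract_background,
)
from ponsquant.types import AtlasPlate, RegionMap, SectionImage


def disk_mask(r):
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= r**2


def brute_force_opening(img, radius):
    """Grayscale opening with a disk, by direct sliding-window min then max."""
    se = disk_mask(radius)
    offs = np.argwhere(se) - radius
    h, w = img.shape
    pad = radius
    big = np.pad(img.astype(float), pad, mode="reflect")
    eroded = np.full((h, w), np.inf)
    for dy, dx in offs:
        eroded = np.minimum(eroded, big[pad + dy : pad + dy + h, pad + dx : pad + dx + w])
    big_e = np.pad(eroded, pad, mode="reflect")
    opened = np.full((h, w), -np.inf)
    for dy, dx in offs:
        opened = np.maximum(opened, big_e[pad + dy : pad + dy + h, pad + dx : pad + dx + w])
    return opened


class TestExtractRois:
    def test_two_colour_partition(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:, :5] = (255, 0, 0)
        px[:, 5:] = (0, 255, 0)
        plate = AtlasPlate(px)
        rmap = RegionMap([(1, "a", (255, 0, 0)), (2, "b", (0, 255, 0))])
        masks, unassigned, n_un = extract_rois(plate, rmap)
        assert masks[1].sum() == masks[2].sum() == 50
        assert not (masks[1] & masks[2]).any()
        assert n_un == 0
        assert (masks[1] | masks[2]).all()

    def test_unmapped_colour_reported_not_fatal(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:, :5] = (255, 0, 0)
        px[0, 7] = (9, 9, 9)  # colour absent from the map
        plate = AtlasPlate(px)
        rmap = RegionMap([(1, "a", (255, 0, 0))])
        with pytest.warns(UserWarning, match="absent"):
            masks, unassigned, n_un = extract_rois(plate, rmap)
        assert n_un == 1
        assert unassigned[0, 7]

    def test_synthetic_plate_mask_areas_match_generator(self, small_section_set):
        spec, (sections, plates, rmap, truth) = small_section_set
        masks, _, n_un = extract_rois(plates[0], rmap)
        assert n_un == 0
        assert masks[1].sum() == masks[2].sum() == 200 * 100


class TestSubtractBackground:
    def test_flat_field_maps_to_zero(self):
        img = SectionImage(np.full((50, 50), 900, dtype=np.uint16))
        out = subtract_background(img, 10)
        assert (out.pixels == 0).all()

    def test_blob_peak_preserved_vs_opening_oracle(self):
        rng = np.random.default_rng(0)
        img = np.full((60, 60), 500.0)
        yy, xx = np.mgrid[:60, :60]
        blob = 8000.0 * np.exp(-((yy - 30.0) ** 2 + (xx - 30.0) ** 2) / (2 * 1.0**2))
        img += blob
        simg = SectionImage(img.astype(np.uint16))
        out = subtract_background(simg, 9)
        # tophat = img - opening; oracle computes the opening by brute force
        oracle = simg.pixels.astype(float) - brute_force_opening(simg.pixels, 9)
        assert np.abs(out.pixels.astype(float) - oracle).max() <= 1
        peak = out.pixels.max()
        assert abs(float(peak) - 8000.0) / 8000.0 < 0.05

    def test_ramp_background_suppressed(self):
        yy, xx = np.mgrid[:80, :80]
        img = 2.0 * xx + 3000.0 * np.exp(-((yy - 40.0) ** 2 + (xx - 40.0) ** 2) / (2 * 1.0**2))
        out = subtract_background(SectionImage(img.astype(np.uint16)), 9)
        blob_zone = (np.hypot(yy - 40, xx - 40) < 5)
        residual = out.pixels.astype(float)[~blob_zone].max()
        assert residual < 0.10 * 3000.0

    def test_radius_validation(self):
        img = SectionImage(np.zeros((20, 20), dtype=np.uint16))
        with pytest.raises(ValueError):
            subtract_background(img, 0)
        with pytest.raises(ValueError):
            subtract_background(img, 25)


class TestDetectObjects:
    def test_empty_image_gives_empty_list(self):
        img = SectionImage(np.zeros((30, 30), dtype=np.uint16))
        assert detect_objects(img, threshold=10) == []

    def test_two_disks_two_objects(self):
        px = np.zeros((60, 60), dtype=np.uint16)
        px[10:21, 10:21][disk_mask(5)] = 1000
        px[35:46, 35:46][disk_mask(5)] = 1000
        objs = detect_objects(SectionImage(px), threshold=500)
        assert len(objs) == 2

    def test_disk_area_and_circularity_match_rasterization(self):
        r = 6
        px = np.zeros((30, 30), dtype=np.uint16)
        px[8 : 8 + 2 * r + 1, 8 : 8 + 2 * r + 1][disk_mask(r)] = 1000
        (obj,) = detect_objects(SectionImage(px), threshold=500)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        expected_area = int(np.sum(yy**2 + xx**2 <= r**2))
        assert obj.area == expected_area == 113
        assert obj.circularity == pytest.approx(0.952, abs=0.1)

    def test_threshold_monotonicity(self, small_section_set):
        """Raising the threshold never increases the count of planted somata.

        Holds because planted blobs have disjoint supports: components can
        only shrink and vanish as the threshold rises, never split.
        """
        spec, (sections, plates, rmap, truth) = small_section_set
        img = sections[0]
        counts = [
            len(detect_objects(img, threshold=t, min_area=1))
            for t in range(2100, 20000, 1200)
        ]
        assert counts[0] == truth["raw_count"].sum()
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCircularityFilter:
    def test_empty_passthrough(self):
        assert filter_by_circularity([]) == []

    @pytest.mark.parametrize("r", [4, 6, 9])
    def test_disks_pass_gate(self, r):
        px = np.zeros((40, 40), dtype=np.uint16)
        px[5 : 5 + 2 * r + 1, 5 : 5 + 2 * r + 1][disk_mask(r)] = 1000
        objs = detect_objects(SectionImage(px), threshold=500)
        assert len(filter_by_circularity(objs)) == 1

    def test_thin_line_removed(self):
        px = np.zeros((10, 40), dtype=np.uint16)
        px[5, 5:25] = 1000
        objs = detect_objects(SectionImage(px), threshold=500)
        assert len(objs) == 1
        assert objs[0].circularity < 0.5
        assert filter_by_circularity(objs) == []

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            filter_by_circularity([], lo=0.8, hi=0.2)


class TestCountPerRegion:
    def _rois(self):
        left = np.zeros((20, 20), dtype=bool)
        left[:, :10] = True
        return {1: left, 2: ~left}

    def _obj(self, r, c):
        from ponsquant.types import DetectedObject

        return DetectedObject(centroid=(r, c), area=5, perimeter=8.0,
                              circularity=0.9, mean_intensity=100.0)

    def test_centroid_membership(self):
        tab = count_per_region([self._obj(5, 3), self._obj(5, 15)], self._rois())
        got = dict(zip(tab.region_id, tab.raw_count))
        assert got == {UNASSIGNED: 0, 1: 1, 2: 1}

    def test_background_goes_to_unassigned(self):
        rois = {1: np.zeros((20, 20), dtype=bool)}
        tab = count_per_region([self._obj(5, 5)], rois)
        got = dict(zip(tab.region_id, tab.raw_count))
        assert got[UNASSIGNED] == 1

    def test_count_conservation(self):
        objs = [self._obj(5, c) for c in range(2, 18, 3)]
        tab = count_per_region(objs, self._rois())
        assert tab["raw_count"].sum() == len(objs)

    def test_full_pipeline_recovers_planted_counts(self, small_section_set):
        spec, (sections, plates, rmap, truth) = small_section_set
        tab = count_section(sections[0], plates[0], rmap)
        got = dict(zip(tab.region_id, tab.raw_count))
        assert got[1] == 50 and got[2] == 20 and got[UNASSIGNED] == 0

    def test_shape_mismatch_errors(self):
        rois = {1: np.zeros((20, 20), dtype=bool), 2: np.zeros((10, 10), dtype=bool)}
        with pytest.raises(ValueError, match="shape"):
            count_per_region([], rois)


class TestNormalizeCounts:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_ms_percentage(self):
        t = self._table(
            [
                {"animal_id": "a1", "genotype": "c", "section_index": 0, "region_id": 2, "raw_count": 30},
                {"animal_id": "a1", "genotype": "c", "section_index": 0, "region_id": 3, "raw_count": 70},
            ]
        )
        out = normalize_counts(t, "MS_percentage")
        assert out.iloc[0]["pct_M"] == 30.0
        assert out.iloc[0]["pct_S"] == 70.0
        assert out.iloc[0]["pct_M"] + out.iloc[0]["pct_S"] == 100.0

    def test_ms_symmetry(self):
        t = self._table(
            [
                {"animal_id": "a1", "genotype": "c", "section_index": 0, "region_id": 2, "raw_count": 42},
                {"animal_id": "a1", "genotype": "c", "section_index": 0, "region_id": 3, "raw_count": 42},
            ]
        )
        out = normalize_counts(t, "MS_percentage")
        assert out.iloc[0]["pct_M"] == out.iloc[0]["pct_S"] == 50.0

    def test_per_section(self):
        rows = [
            {"animal_id": "a1", "genotype": "c", "section_index": s, "region_id": 1, "raw_count": 5}
            for s in range(8)
        ]
        out = normalize_counts(self._table(rows), "per_section")
        assert out.iloc[0]["total_count"] == 40
        assert out.iloc[0]["per_section"] == 5.0

    def test_zero_denominator_names_animal(self):
        t = self._table(
            [
                {"animal_id": "bad", "genotype": "c", "section_index": 0, "region_id": 2, "raw_count": 0},
                {"animal_id": "bad", "genotype": "c", "section_index": 0, "region_id": 3, "raw_count": 0},
            ]
        )
        with pytest.raises(ValueError, match="bad"):
            normalize_counts(t, "MS_percentage")

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            normalize_counts(self._table([{"animal_id": "a", "genotype": "c",
                                           "section_index": 0, "region_id": 1,
                                           "raw_count": 1}]), "nope")
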