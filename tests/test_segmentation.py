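"""Thresholding, connected components, hole filling, edge exclusion and
the area-restriction sweep."""

import numpy as np
import pytest

from conftest import brute_force_components
from nanopsd.imaging import Micrograph
from nanopsd.segmentation import (
    SegmentationConfig,
    extract_particles,
    region_from_mask,
    restriction_sweep,
    segment,
    threshold,
    th_percent_for_gray,
)


def micrograph(px, nm_per_px=1.0):
    return Micrograph(np.asarray(px, dtype=np.uint8), nm_per_px)


def loose_cfg(**kw):
    base = dict(
        th_percent=50.0,
        include_holes=False,
        exclude_edges=False,
        min_area_px=0,
    )
    base.update(kw)
    return SegmentationConfig(**base)


class TestThreshold:
    def test_full_histogram_percentile_selects_everything(self, rng):
        m = micrograph(rng.integers(0, 256, (16, 16)))
        assert threshold(m, 100.0).all()

    def test_constant_image_all_foreground_at_any_th(self):
        m = micrograph(np.full((8, 8), 90))
        for th in (1.0, 37.5, 100.0):
            assert threshold(m, th).all()

    def test_two_level_image_half_threshold_selects_dark_half(self, rng):
        # hand-enumerated two-level histogram: 50 % gray 0, 50 % gray 255;
        # the 50th percentile lies between the levels, so dark polarity
        # selects exactly the gray-0 pixels
        px = np.zeros((10, 10), dtype=np.uint8)
        dark = rng.random((10, 10)) < 0.5
        while dark.mean() != 0.5:
            dark = rng.random((10, 10)) < 0.5
        px[~dark] = 255
        mask = threshold(micrograph(px), 50.0)
        assert np.array_equal(mask, dark)

    def test_light_polarity_mirrors_dark(self):
        px = np.zeros((4, 4), dtype=np.uint8)
        px[:2] = 200
        assert np.array_equal(threshold(micrograph(px), 50.0, "light"), px == 200)

    def test_foreground_monotone_in_th(self, rng):
        m = micrograph(rng.integers(0, 256, (32, 32)))
        counts = [threshold(m, th).sum() for th in (5, 20, 50, 80, 100)]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("th", [0.0, -3.0, 100.5])
    def test_invalid_th_rejected(self, th):
        with pytest.raises(ValueError):
            threshold(micrograph(np.zeros((4, 4))), th)

    def test_th_percent_for_gray_inverts_percentile(self, rng):
        m = micrograph(rng.integers(0, 256, (64, 64)))
        th = th_percent_for_gray(m, 120)
        mask = threshold(m, th) if th > 0 else np.zeros_like(m.pixels, bool)
        assert np.array_equal(mask, m.pixels <= 120)


class TestExtractParticles:
    def test_single_interior_square(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        m = micrograph(np.where(mask, 0, 255))
        regions = extract_particles(mask, m, SegmentationConfig(min_area_px=50))
        assert len(regions) == 1
        assert regions[0].pixel_count == 100
        assert regions[0].id == 1

    def test_include_holes_absorbs_interior_hole(self):
        # 9x9 ring with a 3x3 hole: filled pixel count is the full square, 81
        mask = np.zeros((15, 15), dtype=bool)
        mask[3:12, 3:12] = True
        mask[6:9, 6:9] = False
        m = micrograph(np.where(mask, 0, 255))
        (reg,) = extract_particles(mask, m, loose_cfg(include_holes=True))
        assert reg.pixel_count == 81
        assert reg.holes_filled_px == 9
        without = extract_particles(mask, m, loose_cfg(include_holes=False))
        assert without[0].pixel_count == 72

    def test_hole_fill_does_not_absorb_nested_component(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[3:12, 3:12] = True
        mask[6:9, 6:9] = False
        mask[7, 7] = True  # separate particle inside the hole
        m = micrograph(np.where(mask, 0, 255))
        regions = extract_particles(mask, m, loose_cfg(include_holes=True))
        counts = sorted(r.pixel_count for r in regions)
        assert counts == [1, 80]  # ring fills 8 background px, keeps the inner particle

    def test_exclude_edges_removes_border_touching_component(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:4, 3:6] = True  # overlaps row 0
        mask[6:9, 6:9] = True
        m = micrograph(np.where(mask, 0, 255))
        regions = extract_particles(mask, m, loose_cfg(exclude_edges=True))
        assert len(regions) == 1
        assert not regions[0].touches_edge

    def test_min_area_px_filters_small_components(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px
        mask[8:16, 8:16] = True  # 64 px
        m = micrograph(np.where(mask, 0, 255))
        regions = extract_particles(mask, m, loose_cfg(min_area_px=50))
        assert [r.pixel_count for r in regions] == [64]

    def test_nm2_bounds_inclusive(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[2:7, 2:7] = True  # 25 px -> 6.25 nm2 at 0.5 nm/px
        mask[10:14, 10:14] = True  # 16 px -> 4.0 nm2
        m = micrograph(np.where(mask, 0, 255), nm_per_px=0.5)
        regions = extract_particles(
            mask, m, loose_cfg(min_area_nm2=4.0, max_area_nm2=6.25)
        )
        assert sorted(r.pixel_count for r in regions) == [16, 25]

    def test_connectivity_4_splits_diagonal_pair(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = mask[3, 3] = True
        m = micrograph(np.where(mask, 0, 255))
        assert len(extract_particles(mask, m, loose_cfg(connectivity=8))) == 1
        assert len(extract_particles(mask, m, loose_cfg(connectivity=4))) == 2

    def test_ids_row_major_and_consecutive(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[12:14, 2:4] = True  # lower-left
        mask[2:4, 15:17] = True  # upper-right
        mask[2:4, 2:4] = True  # upper-left
        m = micrograph(np.where(mask, 0, 255))
        regions = extract_particles(mask, m, loose_cfg())
        assert [r.id for r in regions] == [1, 2, 3]
        cents = [r.centroid_px for r in regions]
        assert cents[0][1] == cents[1][1] < cents[2][1]  # rows ordered
        assert cents[0][0] < cents[1][0]  # same row: left first

    def test_mask_shape_mismatch_rejected(self):
        m = micrograph(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="dimensions"):
            extract_particles(np.zeros((4, 4), dtype=bool), m, loose_cfg())

    def test_empty_result_is_valid(self):
        m = micrograph(np.full((8, 8), 200))
        assert extract_particles(np.zeros((8, 8), dtype=bool), m, loose_cfg()) == []


class TestLabelingOracle:
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_components_agree_with_flood_fill(self, connectivity, rng):
        for _ in range(12):
            mask = rng.random((32, 32)) < 0.35
            m = micrograph(np.where(mask, 0, 255))
            regions = extract_particles(
                mask, m, loose_cfg(connectivity=connectivity)
            )
            got = {
                frozenset(zip(r.rows.tolist(), r.cols.tolist())) for r in regions
            }
            expected = set(brute_force_components(mask, connectivity))
            assert got == expected

    def test_label_conservation_with_holes_and_edges(self, rng):
        for _ in range(8):
            mask = rng.random((40, 40)) < 0.4
            m = micrograph(np.where(mask, 0, 255))
            cfg = loose_cfg(include_holes=True, exclude_edges=True)
            regions = extract_particles(mask, m, cfg)
            # no surviving region touches the border
            for r in regions:
                assert r.rows.min() > 0 and r.cols.min() > 0
                assert r.rows.max() < 39 and r.cols.max() < 39
            # pixel sets are pairwise disjoint
            all_px = [set(zip(r.rows.tolist(), r.cols.tolist())) for r in regions]
            total = sum(len(s) for s in all_px)
            assert len(set().union(*all_px)) == total if all_px else True
            # every surviving pixel is foreground or a filled hole
            filled = sum(r.holes_filled_px for r in regions)
            fg = sum(mask[r.rows, r.cols].sum() for r in regions)
            assert total == fg + filled


class TestRestrictionSweep:
    def areas_to_regions(self, areas_nm2, nm_per_px=1.0):
        regions = []
        for i, a in enumerate(areas_nm2, start=1):
            n_px = int(round(a / nm_per_px**2))
            mask = np.zeros((1, n_px), dtype=bool)
            mask[0, :] = True
            regions.append(region_from_mask(mask, nm_per_px, region_id=i))
        return regions

    def test_hand_filtered_interval(self):
        regions = self.areas_to_regions([10, 30, 50, 200])
        out = restriction_sweep(regions, 1.0, [(26, 160)])
        assert out.hit_count.iloc[0] == 2
        assert out.surviving_ids.iloc[0] == [2, 3]

    def test_unbounded_interval_hits_all(self):
        regions = self.areas_to_regions([10, 30, 50, 200])
        out = restriction_sweep(regions, 1.0, [(0, np.inf)])
        assert out.hit_count.iloc[0] == 4

    def test_nested_intervals_monotone(self, rng):
        areas = rng.uniform(5, 250, size=40)
        regions = self.areas_to_regions(areas)
        intervals = [(26, 160), (30, 160), (40, 160), (40, 100)]
        out = restriction_sweep(regions, 1.0, intervals)
        hits = out.hit_count.tolist()
        assert hits == sorted(hits, reverse=True)

    def test_agrees_with_brute_force_filter(self, rng):
        areas = rng.uniform(1, 300, size=60)
        regions = self.areas_to_regions(areas)
        real = np.array([r.pixel_count for r in regions], dtype=float)
        for lo, hi in [(26, 160), (10, 50), (100, 299)]:
            out = restriction_sweep(regions, 1.0, [(lo, hi)])
            assert out.hit_count.iloc[0] == int(((real >= lo) & (real <= hi)).sum())

    def test_inclusive_bounds(self):
        regions = self.areas_to_regions([26, 160])
        out = restriction_sweep(regions, 1.0, [(26, 160)])
        assert out.hit_count.iloc[0] == 2

    def test_invalid_interval_named_in_error(self):
        regions = self.areas_to_regions([10])
        with pytest.raises(ValueError, match=r"\(50, 20\)"):
            restriction_sweep(regions, 1.0, [(50, 20)])


class TestSegmentEndToEnd:
    def test_blank_image_yields_no_particles_with_edge_exclusion(self):
        # constant image: everything is foreground, one border-touching
        # component, removed by edge exclusion
        m = micrograph(np.full((32, 32), 128))
        assert segment(m, SegmentationConfig(th_percent=50.0)) == []
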