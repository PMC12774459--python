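"""B-scan → en face projection: normalization, bands, merging."""

import numpy as np
import pytest
from conftest import random_small_geometry
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import epi_bruteforce

from ermquant import (
    BScanDetection,
    Orientation,
    ScanGeometry,
    build_epi,
    normalize_coordinate,
    project_detection,
    scan_band,
)


class TestNormalizeCoordinate:
    @pytest.mark.parametrize(
        "x_bscan, expected",
        [(768, 496.0), (0, 0.0), (384, 248.0), (96, 62.0)],
    )
    def test_linear_rescaling(self, x_bscan, expected, geometry):
        assert normalize_coordinate(x_bscan, geometry) == pytest.approx(expected)

    @pytest.mark.parametrize("x_bscan", [-1, 768.5, 1e9])
    def test_out_of_range_rejected(self, x_bscan, geometry):
        with pytest.raises(ValueError, match="x_bscan"):
            normalize_coordinate(x_bscan, geometry)


class TestScanBand:
    @pytest.mark.parametrize(
        "scan_index, expected",
        [(0, (0, 19)), (12, (238, 257)), (24, (476, 496))],
    )
    def test_default_bands(self, scan_index, expected, geometry):
        assert scan_band(scan_index, Orientation.HORIZONTAL, geometry) == expected

    @pytest.mark.parametrize("n_scans", [1, 5, 25])
    @pytest.mark.parametrize("orientation", ["horizontal", "vertical"])
    def test_bands_tile_the_frame(self, n_scans, orientation, geometry):
        geom = ScanGeometry(n_scans_per_orientation=n_scans)
        covered = np.zeros(496, dtype=int)
        for k in range(n_scans):
            start, stop = scan_band(k, orientation, geom)
            assert start < stop
            covered[start:stop] += 1
        assert (covered == 1).all(), "bands must partition the frame exactly"

    @given(n_scans=st.integers(1, 40), extent=st.integers(1, 600))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tiling_for_arbitrary_scan_counts(self, n_scans, extent):
        geom = ScanGeometry(
            enface_width=extent, enface_height=extent, n_scans_per_orientation=n_scans
        )
        covered = np.zeros(extent, dtype=int)
        for k in range(n_scans):
            start, stop = scan_band(k, "vertical", geom)
            covered[start:stop] += 1
        assert (covered == 1).all()

    def test_invalid_inputs(self, geometry):
        with pytest.raises(ValueError):
            scan_band(25, "horizontal", geometry)
        with pytest.raises(ValueError):
            scan_band(0, "diagonal", geometry)


class TestProjectDetection:
    def test_full_width_horizontal_scan(self, geometry):
        det = BScanDetection(12, "horizontal", 0, 768)
        region = project_detection(det, geometry)
        assert (region.row_start, region.row_stop) == (238, 257)
        assert (region.col_start, region.col_stop) == (0, 496)

    def test_full_width_vertical_scan_swaps_axes(self, geometry):
        det = BScanDetection(0, "vertical", 0, 768)
        region = project_detection(det, geometry)
        assert (region.row_start, region.row_stop) == (0, 496)
        assert (region.col_start, region.col_stop) == (0, 19)

    def test_half_width_detection(self, geometry):
        det = BScanDetection(0, "horizontal", 384, 768)
        region = project_detection(det, geometry)
        assert (region.col_start, region.col_stop) == (248, 496)
        assert (region.row_start, region.row_stop) == (0, 19)

    def test_subpixel_extent_never_lost(self, geometry):
        # 1-pixel B-scan box maps to < 1 en face pixel but must still paint one
        det = BScanDetection(3, "horizontal", 100, 101)
        region = project_detection(det, geometry)
        assert region.col_stop - region.col_start >= 1

    def test_degenerate_detection_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BScanDetection(0, "horizontal", 100, 100)

    def test_axis_symmetry_on_square_geometry(self, geometry, rng):
        for _ in range(20):
            k = int(rng.integers(0, 25))
            x0, x1 = sorted(rng.integers(0, 769, size=2).tolist())
            if x0 == x1:
                continue
            h = project_detection(BScanDetection(k, "horizontal", x0, x1), geometry)
            v = project_detection(BScanDetection(k, "vertical", x0, x1), geometry)
            assert (h.row_start, h.row_stop) == (v.col_start, v.col_stop)
            assert (h.col_start, h.col_stop) == (v.row_start, v.row_stop)


class TestBuildEpi:
    def test_empty_input_gives_empty_mask(self, geometry):
        epi = build_epi([], geometry)
        assert epi.n_true == 0
        assert not epi.grid.any()

    def test_full_frame_coverage(self, geometry):
        dets = [BScanDetection(k, "horizontal", 0, 768) for k in range(25)]
        epi = build_epi(dets, geometry)
        assert epi.n_true == 496 * 496 == 246016
        assert epi.grid.all()

    def test_duplicate_detection_is_idempotent_in_grid(self, geometry):
        det = BScanDetection(5, "horizontal", 100, 300)
        one = build_epi([det], geometry)
        two = build_epi([det, det], geometry)
        assert np.array_equal(one.grid, two.grid)
        assert two.coverage.max() == 2
        assert one.coverage.max() == 1

    def test_low_confidence_detections_dropped(self, geometry):
        det = BScanDetection(5, "horizontal", 100, 300, confidence=0.1)
        epi = build_epi([det], geometry, min_confidence=0.25)
        assert epi.n_true == 0
        epi = build_epi([det], geometry, min_confidence=0.05)
        assert epi.n_true > 0

    def test_union_monotone_in_detections(self, geometry, rng):
        dets = []
        prev = 0
        for _ in range(15):
            x0, x1 = sorted(rng.integers(0, 769, size=2).tolist())
            if x0 == x1:
                continue
            dets.append(
                BScanDetection(
                    int(rng.integers(0, 25)),
                    rng.choice(["horizontal", "vertical"]),
                    x0,
                    x1,
                )
            )
            count = build_epi(dets, geometry).n_true
            assert count >= prev
            prev = count

    def test_geometry_mismatch_rejected(self, small_geometry):
        det = BScanDetection(2, "horizontal", 0, 700)  # beyond 48-px B-scan
        with pytest.raises(ValueError):
            build_epi([det], small_geometry)

    def test_matches_bruteforce_on_random_small_geometries(self, rng):
        for _ in range(40):
            geom = random_small_geometry(rng)
            dets = []
            for _ in range(int(rng.integers(0, 5))):
                x0, x1 = sorted(
                    rng.integers(0, geom.bscan_width + 1, size=2).tolist()
                )
                if x0 == x1:
                    continue
                dets.append(
                    BScanDetection(
                        int(rng.integers(0, geom.n_scans_per_orientation)),
                        rng.choice(["horizontal", "vertical"]),
                        x0,
                        x1,
                    )
                )
            epi = build_epi(dets, geom, min_confidence=0.0)
            assert np.array_equal(epi.grid, epi_bruteforce(dets, geom))
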