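"""Gap-grid analysis: subdivision, cover fractions, LAI suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyaroma.gap import (
    AnalysisSettings,
    BinaryCanopyMask,
    GapGrid,
    analyze_mask,
    compute_cover_fractions,
    compute_lai_suite,
    subdivide_and_classify,
)
from canopyaroma.synthetic import CanopySpec, gen_canopy_mask

from conftest import make_mask_with_cell_gap_fractions


class TestSubdivision:
    def test_full_sky_cell_counts_all_gaps_as_large(self):
        pixels = np.ones((100, 100), dtype=bool)
        pixels[0:20, 0:20] = False  # one 20x20 cell fully sky
        grid = subdivide_and_classify(BinaryCanopyMask(pixels))
        assert grid.t_p[0, 0] == 400
        assert grid.t_g[0, 0] == 400
        assert grid.l_g[0, 0] == 400

    def test_scattered_gaps_below_threshold_are_small(self):
        pixels = np.ones((100, 100), dtype=bool)
        pixels[::10, ::10] = False  # 1% scattered gaps everywhere
        grid = subdivide_and_classify(BinaryCanopyMask(pixels))
        assert grid.total_gap == 100
        assert grid.total_large_gap == 0

    def test_all_foliage_mask_has_no_gaps(self):
        grid = subdivide_and_classify(BinaryCanopyMask(np.ones((50, 50), dtype=bool)))
        assert grid.total_gap == 0 and grid.total_large_gap == 0

    def test_cell_level_rule_straddles_threshold(self):
        # cells with gap fractions 0.9, 0.5, 0.74, 0.76 at threshold 0.75:
        # large gaps appear exactly in cells 1 (0.9) and 4 (0.76)
        mask = make_mask_with_cell_gap_fractions([0.9, 0.5, 0.74, 0.76])
        grid = subdivide_and_classify(mask, AnalysisSettings(grid_rows=2, grid_cols=2))
        large = grid.l_g > 0
        assert large.tolist() == [[True, False], [False, True]]
        assert grid.l_g[0, 0] == 90 and grid.l_g[1, 1] == 76

    def test_remainder_pixels_attach_to_last_cells(self):
        mask = BinaryCanopyMask(np.ones((101, 103), dtype=bool))
        grid = subdivide_and_classify(mask)
        assert grid.total_pixels == 101 * 103
        assert grid.t_p[-1, -1] == 21 * 23

    def test_empty_and_oversized_grid_raise(self):
        with pytest.raises(ValueError, match="empty raster"):
            BinaryCanopyMask(np.ones((0, 5), dtype=bool))
        with pytest.raises(ValueError, match="larger than mask"):
            subdivide_and_classify(
                BinaryCanopyMask(np.ones((3, 3), dtype=bool)),
                AnalysisSettings(grid_rows=5, grid_cols=5),
            )

    def test_component_mode_ignores_fragmented_gaps(self):
        # one 9x9 sky block (81% of a 10x10 cell) vs same area scattered
        solid = np.ones((20, 20), dtype=bool)
        solid[0:9, 0:9] = False
        settings = AnalysisSettings(grid_rows=2, grid_cols=2, large_gap_mode="component")
        grid = subdivide_and_classify(BinaryCanopyMask(solid), settings)
        assert grid.l_g[0, 0] == 81
        scattered = np.ones((20, 20), dtype=bool)
        scattered.ravel()[0:162:2] = False  # 81 isolated gap pixels
        grid2 = subdivide_and_classify(BinaryCanopyMask(scattered), settings)
        assert grid2.total_large_gap == 0


class TestCoverFractions:
    def test_hand_arithmetic_example(self):
        grid = GapGrid(
            t_p=np.array([[10000]]), t_g=np.array([[2200]]), l_g=np.array([[1600]])
        )
        ff, fc, phi = compute_cover_fractions(grid)
        assert ff == pytest.approx(0.78)
        assert fc == pytest.approx(0.84)
        assert phi == pytest.approx(1 - 0.78 / 0.84)

    def test_no_gaps_gives_full_cover_zero_porosity(self):
        grid = GapGrid(t_p=np.array([[100]]), t_g=np.array([[0]]), l_g=np.array([[0]]))
        assert compute_cover_fractions(grid) == (1.0, 1.0, 0.0)

    def test_all_sky_convention(self):
        grid = GapGrid(
            t_p=np.array([[100]]), t_g=np.array([[100]]), l_g=np.array([[100]])
        )
        assert compute_cover_fractions(grid) == (0.0, 0.0, 1.0)

    def test_invalid_tallies_rejected(self):
        with pytest.raises(ValueError):
            GapGrid(t_p=np.array([[10]]), t_g=np.array([[5]]), l_g=np.array([[7]]))


class TestLaiSuite:
    def test_hand_arithmetic_example(self):
        arch = compute_lai_suite(0.78, 0.84, 1 - 0.78 / 0.84, AnalysisSettings(k=0.7))
        assert arch.lai == pytest.approx(3.167, abs=2e-3)
        assert arch.omega0 == pytest.approx(0.683, abs=2e-3)
        assert arch.lai_e == pytest.approx(2.163, abs=2e-3)

    @pytest.mark.parametrize("ff", [0.3, 0.5, 0.78, 0.912, 0.99])
    def test_random_dispersion_limit_is_exactly_one(self, ff):
        # fc = 1 (no large gaps) implies phi = 1 - ff and omega0 = 1 exactly
        arch = compute_lai_suite(ff, 1.0, 1.0 - ff)
        assert arch.omega0 == 1.0
        assert arch.lai_e == arch.lai

    def test_all_sky_returns_empty_record(self):
        arch = compute_lai_suite(0.0, 0.0, 1.0)
        assert arch.empty_flag
        assert (arch.lai, arch.lai_e, arch.omega0) == (0.0, 0.0, 1.0)

    def test_solid_canopy_hits_porosity_floor_cap(self):
        settings = AnalysisSettings(k=0.7, porosity_floor=1e-6)
        arch = compute_lai_suite(1.0, 1.0, 0.0, settings)
        assert arch.lai == pytest.approx(-math.log(1e-6) / 0.7)
        assert np.isfinite(arch.omega0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="k must be > 0"):
            AnalysisSettings(k=-1.0)
        with pytest.raises(ValueError, match="exceed crown cover"):
            compute_lai_suite(0.9, 0.5, 0.1)


class TestAnalyzeMask:
    def test_fully_sky_mask_yields_empty_architecture(self):
        arch = analyze_mask(BinaryCanopyMask(np.zeros((50, 50), dtype=bool)))
        assert arch.empty_flag and arch.lai == 0.0

    def test_constructed_mask_matches_hand_computed_record(self):
        # 5x5 grid of 100x100 cells; cell (0,0) fully sky, every other cell
        # exactly 500 scattered gap pixels -> t_g=22000, l_g=10000 and the
        # frozen record below (independent hand-arithmetic oracle)
        pixels = np.ones((500, 500), dtype=bool)
        pixels[0:100, 0:100] = False
        for ci in range(5):
            for cj in range(5):
                if ci == cj == 0:
                    continue
                cell = np.ones(10000, dtype=bool)
                cell[::20] = False  # 500 scattered gap pixels
                pixels[
                    ci * 100 : (ci + 1) * 100, cj * 100 : (cj + 1) * 100
                ] = cell.reshape(100, 100)
        arch = analyze_mask(BinaryCanopyMask(pixels))
        assert arch.ff == pytest.approx(0.912)
        assert arch.fc == pytest.approx(0.96)
        assert arch.phi == pytest.approx(0.05)
        assert arch.lai == pytest.approx(4.108433, abs=1e-5)
        assert arch.omega0 == pytest.approx(0.845098, abs=1e-5)
        assert arch.lai_e == pytest.approx(3.472026, abs=1e-5)

    def test_beer_law_inversion_recovers_lai(self):
        recovered = []
        for seed in range(10):
            mask, _ = gen_canopy_mask(
                CanopySpec(true_lai=3.0, k=0.7, size=(400, 400), seed=seed)
            )
            recovered.append(analyze_mask(mask).lai)
        assert abs(np.mean(recovered) - 3.0) < 0.15

    def test_determinism_bit_for_bit(self):
        mask, _ = gen_canopy_mask(CanopySpec(true_lai=2.5, size=(200, 200), seed=3))
        assert analyze_mask(mask) == analyze_mask(mask)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), gap_p=st.floats(0.05, 0.95))
def test_cover_fraction_invariants_on_random_masks(seed, gap_p):
    """0 <= ff <= fc <= 1 and cell tallies are consistent for any mask."""
    rng = np.random.default_rng(seed)
    mask = BinaryCanopyMask(rng.random((60, 60)) >= gap_p)
    grid = subdivide_and_classify(mask)
    assert np.all(grid.l_g <= grid.t_g) and np.all(grid.t_g <= grid.t_p)
    ff, fc, phi = compute_cover_fractions(grid)
    assert 0.0 <= ff <= fc <= 1.0
    assert 0.0 <= phi <= 1.0


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_adding_foliage_never_decreases_cover(seed):
    rng = np.random.default_rng(seed)
    pixels = rng.random((50, 50)) >= 0.5
    mask = BinaryCanopyMask(pixels)
    gaps = np.flatnonzero(~pixels.ravel())
    if gaps.size == 0:
        return
    flipped = pixels.copy()
    flipped.ravel()[rng.choice(gaps, size=min(20, gaps.size), replace=False)] = True
    ff_before, _, _ = compute_cover_fractions(subdivide_and_classify(mask))
    ff_after, _, _ = compute_cover_fractions(
        subdivide_and_classify(BinaryCanopyMask(flipped))
    )
    assert ff_after >= ff_before
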