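"""Geometry layer: distance-based morphology, shells, mirroring, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perishell.grid import VolumeGrid
from perishell.maskops import (block_mean, dilate, erode, make_shells, mirror,
                               resample_mask)

from _oracles import dilate_oracle, erode_oracle, footprint_fraction_oracle, shell_oracle
from conftest import make_grid


def random_mask(rng, shape=(16, 16, 16), p=0.25):
    return rng.random(shape) < p


# ----------------------------------------------------------------------
# erode / dilate
# ----------------------------------------------------------------------

class TestErodeDilate:
    def test_cube_erosion_keeps_center(self):
        """A 3^3 solid cube at 2.5 mm spacing eroded by 2.5 mm keeps only
        the centre voxel (its distance to background is 5 mm)."""
        m = np.zeros((9, 9, 9), bool)
        m[3:6, 3:6, 3:6] = True
        out = erode(make_grid(m, spacing=(2.5, 2.5, 2.5)), 2.5)
        assert out.count() == 1
        assert out.values[4, 4, 4]

    def test_zero_margin_is_identity(self):
        rng = np.random.default_rng(0)
        m = random_mask(rng)
        g = make_grid(m)
        assert (erode(g, 0.0).values == m).all()
        assert (dilate(g, 0.0).values == m).all()

    def test_margin_beyond_radius_annihilates(self):
        m = np.zeros((9, 9, 9), bool)
        m[3:6, 3:6, 3:6] = True
        assert erode(make_grid(m), 10.0).count() == 0

    def test_unit_dilation_gives_six_neighbour_cross(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        out = dilate(make_grid(m), 1.0)
        assert out.count() == 7
        assert out.values[3, 3, 3] and out.values[2, 3, 3] and out.values[3, 4, 3]
        assert not out.values[2, 2, 3]  # diagonal is at sqrt(2) > 1

    def test_erode_dilate_duality_on_random_mask(self):
        rng = np.random.default_rng(7)
        m = random_mask(rng)
        r = 1.8
        left = dilate(make_grid(m), r).values
        right = ~erode(make_grid(~m), r).values
        assert (left == right).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nearest_neighbour_oracle(self, seed):
        """Spacing-aware erosion/dilation agree with exhaustive
        nearest-neighbour distances on random masks (larger sweep in the
        acceptance suite)."""
        rng = np.random.default_rng(seed)
        m = random_mask(rng, p=rng.uniform(0.1, 0.6))
        spacing = tuple(rng.uniform(0.8, 2.6, size=3))
        margin = rng.uniform(0.5, 4.0)
        g = VolumeGrid(m, spacing)
        assert (erode(g, margin).values == erode_oracle(m, spacing, margin)).all()
        assert (dilate(g, margin).values == dilate_oracle(m, spacing, margin)).all()

    def test_rejects_nonbinary_input(self):
        g = make_grid(np.full((4, 4, 4), 0.5))
        with pytest.raises(ValueError, match="binary"):
            erode(g, 1.0)
        with pytest.raises(ValueError, match="binary"):
            dilate(g, 1.0)

    def test_rejects_negative_margin(self):
        g = make_grid(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError):
            erode(g, -1.0)


# ----------------------------------------------------------------------
# shells
# ----------------------------------------------------------------------

class TestShells:
    def test_single_voxel_shell_counts(self):
        """Around a single voxel, shell 1 at thickness 2 holds the 32
        lattice points with 0 < x^2+y^2+z^2 <= 4."""
        c = np.zeros((15, 15, 15), bool)
        c[7, 7, 7] = True
        wm = np.ones_like(c)
        ss = make_shells(make_grid(c), make_grid(wm), thickness=2.0, do_mirror=False)
        assert ss.shells[0].count() == 32
        oracle = shell_oracle(c, wm, 2, 2.0)
        assert (ss.shells[1].values == oracle).all()

    def test_wm_equal_to_cluster_empties_shells(self):
        c = np.zeros((9, 9, 9), bool)
        c[4, 4, 4] = True
        ss = make_shells(make_grid(c), make_grid(c.copy()), do_mirror=False)
        assert all(s.count() == 0 for s in ss.shells)
        assert ss.expansions[-1].count() == 1

    def test_thickness_bands_nest(self):
        """Union of thickness-1 shells 1..2 equals shell 1 at thickness 2."""
        rng = np.random.default_rng(3)
        c = np.zeros((20, 20, 20), bool)
        c[9:11, 9:12, 8:11] = True
        wm = rng.random(c.shape) < 0.9
        wm |= c
        thin = make_shells(make_grid(c), make_grid(wm), thickness=1.0, do_mirror=False)
        thick = make_shells(make_grid(c), make_grid(wm), thickness=2.0, do_mirror=False)
        union = thin.shells[0].values | thin.shells[1].values
        assert (union == thick.shells[0].values).all()

    def test_structural_invariants_validate(self, default_case):
        """Disjointness, the expansion identity and WM containment hold on
        every phantom cluster."""
        wm = default_case.wm_mask
        for cm in default_case.cluster_masks:
            ss = make_shells(cm, wm)
            ss.validate(wm)

    def test_empty_cluster_rejected(self):
        z = np.zeros((8, 8, 8), bool)
        with pytest.raises(ValueError, match="empty"):
            make_shells(make_grid(z), make_grid(np.ones_like(z)))

    def test_cluster_outside_wm_rejected_with_count(self):
        c = np.zeros((8, 8, 8), bool)
        c[2:5, 2:5, 2:5] = True
        wm = np.zeros_like(c)
        wm[2:5, 2:5, 2:4] = True  # 9 cluster voxels stick out
        with pytest.raises(ValueError, match="9 voxel"):
            make_shells(make_grid(c), make_grid(wm))


# ----------------------------------------------------------------------
# mirroring
# ----------------------------------------------------------------------

class TestMirror:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 30))
    def test_involution_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = random_mask(rng, shape=(12, 10, 8), p=0.3)
        g = make_grid(m)  # midline (12-1)/2: all reflections stay in-grid
        assert (mirror(mirror(g)).values == m).all()
        assert mirror(g).count() == g.count()

    def test_symmetric_mask_is_fixed_point(self):
        m = np.zeros((11, 7, 7), bool)
        m[3, 2, 2] = m[7, 2, 2] = True  # symmetric about i = 5
        g = make_grid(m, midline=5.0)
        assert (mirror(g).values == m).all()

    def test_reflection_arithmetic(self):
        m = np.zeros((21, 5, 5), bool)
        m[15, 2, 2] = True  # midline 10, offset +5
        out = mirror(make_grid(m, midline=10.0))
        assert out.count() == 1 and out.values[5, 2, 2]

    def test_half_integer_midline_even_grid(self):
        m = np.zeros((8, 5, 5), bool)
        m[0, 1, 1] = True
        out = mirror(make_grid(m))  # midline 3.5 -> i' = 7 - i
        assert out.values[7, 1, 1] and out.count() == 1

    def test_out_of_grid_reflections_warn_and_drop(self):
        m = np.zeros((9, 5, 5), bool)
        m[8, 2, 2] = True
        g = make_grid(m, midline=2.0)  # reflection lands at -4
        with pytest.warns(UserWarning, match="1 voxel"):
            out = mirror(g)
        assert out.count() == 0

    def test_undefined_midline_rejected(self):
        g = VolumeGrid(np.zeros((4, 4, 4), bool), (1, 1, 1), midline_index=None)
        with pytest.raises(ValueError, match="midline"):
            mirror(g)


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

class TestResample:
    def test_full_block_maps_to_single_voxel(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:4, 2:4, 2:4] = True
        for mf in (0.1, 0.5, 1.0):
            out = resample_mask(make_grid(m), factor=2, min_fraction=mf)
            assert out.count() == 1 and out.values[1, 1, 1]

    def test_partial_coverage_below_threshold_unset(self):
        m = np.zeros((2, 2, 2), bool)
        m.flat[:3] = True  # 3/8 of the single footprint
        out = resample_mask(make_grid(m), factor=2, min_fraction=0.5)
        assert out.count() == 0

    def test_min_fraction_one_is_logical_and(self):
        rng = np.random.default_rng(11)
        m = rng.random((8, 8, 8)) < 0.7
        out = resample_mask(make_grid(m), factor=2, min_fraction=1.0)
        frac = footprint_fraction_oracle(m, 2)
        assert (out.values == (frac >= 1.0)).all()

    def test_fraction_thresholds_match_counting_oracle(self):
        rng = np.random.default_rng(12)
        m = rng.random((8, 8, 8)) < 0.5
        frac = footprint_fraction_oracle(m, 2)
        for mf in (0.25, 0.5, 0.75):
            out = resample_mask(make_grid(m), factor=2, min_fraction=mf)
            assert (out.values == (frac >= mf - 1e-12)).all()

    def test_non_integer_ratio_rejected(self):
        g = VolumeGrid(np.zeros((6, 6, 6), bool), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="non-integer"):
            resample_mask(g, target_spacing=(1.5, 1.5, 1.5))

    def test_midline_and_spacing_transform(self):
        g = VolumeGrid(np.zeros((8, 8, 8), bool), (1.25, 1.25, 1.25), midline_index=3.5)
        out = resample_mask(g, factor=2)
        assert out.spacing == (2.5, 2.5, 2.5)
        assert out.midline_index == pytest.approx(1.5)

    def test_block_mean_of_constant_is_constant(self):
        g = VolumeGrid(np.full((8, 8, 8), 3.25), (1, 1, 1))
        out = block_mean(g, 2)
        assert np.allclose(out.values, 3.25)
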