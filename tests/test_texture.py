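"""Texture features: discretization, GLCM/GLSZM, KU/LE/LZE."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petgrow import ScalarVolume
from petgrow.texture import (CooccurrenceMatrix, RegionSample, SizeZoneMatrix,
                             UNIQUE_3D_DIRECTIONS, compute_glcm, compute_glszm,
                             discretize, kurtosis, local_entropy,
                             long_zone_emphasis, region_features)


def _volume(values_3d):
    return ScalarVolume(np.asarray(values_3d, dtype=float), spacing=(1, 1, 1))


def _line_volume(values):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return _volume(arr)


class TestDiscretize:
    def test_midpoint_falls_in_upper_bin(self):
        vol = _line_volume([0.0, 0.5, 1.0])
        region = np.ones(vol.shape, bool)
        gray = discretize(vol, region, G=2)
        assert gray.levels.ravel().tolist() == [1, 2, 2]

    def test_constant_region_maps_to_level_one(self):
        vol = _line_volume([3.7] * 5)
        gray = discretize(vol, np.ones(vol.shape, bool), G=64)
        assert set(gray.levels.ravel()) == {1}

    def test_matches_elementwise_binning_formula(self, rng):
        vals = rng.uniform(0, 10, size=1000)
        vol = _line_volume(vals)
        region = np.ones(vol.shape, bool)
        G = 16
        gray = discretize(vol, region, G=G)
        lo, hi = vals.min(), vals.max()
        expected = [
            min(G, 1 + math.floor(G * (x - lo) / (hi - lo))) for x in vals
        ]
        assert gray.levels.ravel().tolist() == expected

    def test_explicit_bounds_clip_into_range(self):
        vol = _line_volume([-5.0, 0.5, 99.0])
        gray = discretize(vol, np.ones(vol.shape, bool), G=4, bounds=(0.0, 1.0))
        assert gray.levels.ravel().tolist() == [1, 3, 4]

    def test_errors(self):
        vol = _line_volume([1.0, 2.0])
        with pytest.raises(ValueError, match="empty region"):
            discretize(vol, np.zeros(vol.shape, bool), G=4)
        with pytest.raises(ValueError, match="G"):
            discretize(vol, np.ones(vol.shape, bool), G=1)


def glcm_brute_force(levels, offsets, G):
    """O(voxels x offsets) pair count, symmetrized and normalized."""
    counts = np.zeros((G, G))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0:
                    continue
                for dx, dy, dz in offsets:
                    q = (x + dx, y + dy, z + dz)
                    if all(0 <= q[a] < shape[a] for a in range(3)) \
                            and levels[q] > 0:
                        counts[levels[x, y, z] - 1, levels[q] - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum()


class TestGLCM:
    def test_alternating_line_single_offset(self):
        vol = _line_volume([1.0, 2.0, 1.0, 2.0])
        gray = discretize(vol, np.ones(vol.shape, bool), G=2)
        m = compute_glcm(gray, offsets=[(1, 0, 0)])
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(m.entries, expected)

    def test_constant_region_is_point_mass(self):
        vol = _volume(np.full((3, 3, 3), 2.0))
        gray = discretize(vol, np.ones(vol.shape, bool), G=8)
        m = compute_glcm(gray)
        assert m.entries[0, 0] == 1.0
        assert m.entries.sum() == 1.0

    def test_matches_brute_force_on_random_region(self, rng):
        vol = _volume(rng.uniform(0, 5, size=(8, 8, 8)))
        region = rng.random((8, 8, 8)) < 0.6
        region[4, 4, 4] = True
        gray = discretize(vol, region, G=6)
        m = compute_glcm(gray)
        sym_offsets = list(UNIQUE_3D_DIRECTIONS)
        expected = glcm_brute_force(gray.levels, sym_offsets, G=6)
        np.testing.assert_allclose(m.entries, expected, atol=1e-14)
        assert abs(m.entries.sum() - 1.0) < 1e-12

    def test_isolated_voxel_has_no_pairs(self):
        vol = _volume(np.zeros((5, 5, 5)) + 1.0)
        vol.voxels[2, 2, 2] = 9.0
        region = np.zeros((5, 5, 5), bool)
        region[2, 2, 2] = True
        region[0, 0, 0] = True  # second isolated voxel, not adjacent
        gray = discretize(vol, region, G=2)
        with pytest.raises(ValueError, match="no co-occurring pairs"):
            compute_glcm(gray, offsets=[(1, 0, 0)])


def glszm_brute_force(levels, G):
    """Zone enumeration by BFS flood fill, 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, bool)
    zones = []
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for start in np.argwhere(levels > 0):
        start = tuple(start)
        if seen[start]:
            continue
        lev = levels[start]
        stack, members = [start], 0
        seen[start] = True
        while stack:
            p = stack.pop()
            members += 1
            for off in offs:
                q = tuple(p[a] + off[a] for a in range(3))
                if all(0 <= q[a] < shape[a] for a in range(3)) \
                        and not seen[q] and levels[q] == lev:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(lev), members))
    s_max = max(s for _, s in zones)
    entries = np.zeros((G, s_max), dtype=int)
    for lev, s in zones:
        entries[lev - 1, s - 1] += 1
    return entries


class TestGLSZM:
    def test_constant_region_single_zone(self):
        vol = _volume(np.full((3, 2, 1), 1.5))
        gray = discretize(vol, np.ones(vol.shape, bool), G=4)
        m = compute_glszm(gray)
        assert m.entries[0, 5] == 1
        assert m.entries.sum() == 1

    def test_checkerboard_diagonals_connect(self):
        vol = _volume(np.array([[[1.0], [2.0]], [[2.0], [1.0]]]))
        gray = discretize(vol, np.ones(vol.shape, bool), G=2)
        m = compute_glszm(gray, connectivity=26)
        # two zones (levels 1 and 2), each of size 2 via the diagonal
        assert m.total_zones == 2
        assert m.entries[0, 1] == 1 and m.entries[1, 1] == 1

    def test_matches_brute_force(self, rng):
        vol = _volume(rng.uniform(0, 3, size=(7, 7, 7)))
        region = rng.random((7, 7, 7)) < 0.7
        region[3, 3, 3] = True
        gray = discretize(vol, region, G=5)
        m = compute_glszm(gray)
        expected = glszm_brute_force(gray.levels, G=5)
        np.testing.assert_array_equal(m.entries, expected)

    def test_voxel_conservation(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(2, 7, size=3))
            region = rng.random(shape) < rng.uniform(0.2, 0.9)
            if not region.any():
                continue
            vol = _volume(rng.uniform(0, 1, size=shape))
            gray = discretize(vol, region, G=4)
            m = compute_glszm(gray)
            assert m.total_voxels == int(region.sum())


class TestKurtosis:
    def test_two_point_symmetric_sample(self):
        assert kurtosis([-1.0, 1.0, -1.0, 1.0]) == pytest.approx(1.0)

    def test_degenerate_and_short_samples_raise(self):
        with pytest.raises(ValueError, match="constant uptake"):
            kurtosis([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="too few"):
            kurtosis([1.0, 2.0, 3.0])

    def test_region_sample_fields_consistent(self):
        s = RegionSample.from_values([1.0, 2.0, 3.0, 6.0])
        assert s.count == 4
        assert s.mean == pytest.approx(3.0)
        assert s.stdv == pytest.approx(np.std([1, 2, 3, 6]))

    @given(
        a=st.floats(min_value=0.1, max_value=50,
                    allow_nan=False).filter(lambda v: abs(v) > 1e-6),
        b=st.floats(min_value=-100, max_value=100, allow_nan=False),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, a, b, flip):
        x = np.array([0.3, 1.7, -2.2, 4.1, 0.0, 5.5, -1.1, 2.9])
        scale = -a if flip else a
        assert kurtosis(scale * x + b) == pytest.approx(kurtosis(x), rel=1e-9)


class TestLocalEntropy:
    def _matrix(self, entries):
        e = np.asarray(entries, float)
        return CooccurrenceMatrix(entries=e, G=e.shape[0],
                                  offsets=((1, 0, 0),))

    def test_point_mass_is_zero(self):
        m = self._matrix([[1.0, 0.0], [0.0, 0.0]])
        assert local_entropy(m) == 0.0

    def test_uniform_four_cells_is_two_bits(self):
        m = self._matrix(np.full((2, 2), 0.25))
        assert local_entropy(m) == pytest.approx(2.0)

    def test_two_equal_cells_is_one_bit(self):
        m = self._matrix([[0.5, 0.5], [0.0, 0.0]])
        assert local_entropy(m) == pytest.approx(1.0)

    def test_base_is_configurable(self):
        m = self._matrix(np.full((2, 2), 0.25))
        assert local_entropy(m, base=math.e) == pytest.approx(math.log(4.0))

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            local_entropy(self._matrix([[0.5, 0.2], [0.0, 0.0]]))

    def test_bounded_by_two_log2_G(self, rng):
        for _ in range(20):
            G = int(rng.integers(2, 9))
            p = rng.random((G, G))
            p = (p + p.T) / (2 * p.sum())
            le = local_entropy(CooccurrenceMatrix(p, G, ((1, 0, 0),)))
            assert 0.0 <= le <= 2.0 * math.log2(G) + 1e-12


class TestLongZoneEmphasis:
    def _matrix(self, entries):
        e = np.asarray(entries)
        return SizeZoneMatrix(entries=e, G=e.shape[0])

    def test_all_singleton_zones(self):
        assert long_zone_emphasis(self._matrix([[3], [2]])) == 1.0

    def test_single_zone_of_size_n(self):
        e = np.zeros((2, 7), dtype=int)
        e[1, 6] = 1
        assert long_zone_emphasis(self._matrix(e)) == 49.0

    def test_mixed_zone_sizes(self):
        e = np.zeros((1, 3), dtype=int)
        e[0, 0] = 1
        e[0, 2] = 1
        assert long_zone_emphasis(self._matrix(e)) == pytest.approx(5.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            long_zone_emphasis(self._matrix(np.zeros((2, 2), dtype=int)))

    def test_at_least_one(self, rng):
        for _ in range(20):
            e = rng.integers(0, 4, size=(3, 5))
            if e.sum() == 0:
                e[0, 0] = 1
            assert long_zone_emphasis(self._matrix(e)) >= 1.0


class TestRegionFeatures:
    def test_constant_region_reports_failed_feature(self):
        vol = _volume(np.full((4, 4, 4), 2.0))
        with pytest.raises(ValueError, match="KU failed"):
            region_features(vol, np.ones(vol.shape, bool))

    def test_composes_individual_operations(self, rng):
        vol = _volume(rng.uniform(1, 4, size=(5, 5, 5)))
        region = np.ones(vol.shape, bool)
        feats = region_features(vol, region, G=8)
        gray = discretize(vol, region, G=8)
        assert feats.ku == kurtosis(vol.voxels[region])
        assert feats.le == local_entropy(compute_glcm(gray))
        assert feats.lze == long_zone_emphasis(compute_glszm(gray))

    def test_deterministic(self, rng):
        vol = _volume(rng.uniform(1, 4, size=(5, 5, 5)))
        region = np.ones(vol.shape, bool)
        f1 = region_features(vol, region, G=16)
        f2 = region_features(vol, region, G=16)
        assert (f1.ku, f1.le, f1.lze) == (f2.ku, f2.le, f2.lze)
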