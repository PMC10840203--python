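"""Geometry metrics against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest

import cardiomotion as cm

from conftest import random_mask


def brute_centroid(mask):
    pts = []
    for idx in zip(*np.nonzero(mask.voxels)):
        pt = np.empty(3)
        for d, direction in enumerate(("LR", "AP", "CC")):
            g, sign = mask.grid_axis_of(direction)
            pt[d] = sign * mask.spacing_mm[g] * idx[g]
        pts.append(pt)
    return np.mean(pts, axis=0)


class TestVolumeCentroid:
    def test_volume_examples(self):
        vox = np.zeros((4, 4, 4), bool)
        vox[:2, :2, :2] = True
        assert cm.volume_ml(cm.MaskVolume(vox, (1, 1, 1))) == pytest.approx(0.008)
        one = np.zeros((2, 2, 2), bool)
        one[0, 0, 0] = True
        assert cm.volume_ml(cm.MaskVolume(one, (1, 1, 5))) == pytest.approx(0.005)
        assert cm.volume_ml(cm.MaskVolume(np.zeros((2, 2, 2), bool), (1, 1, 1))) == 0.0

    def test_volume_matches_brute_force_count(self, rng):
        for _ in range(20):
            m = random_mask(rng, spacing=(0.7, 2.0, 5.0))
            expected = sum(1 for _ in zip(*np.nonzero(m.voxels))) * 7.0 / 1000
            assert cm.volume_ml(m) == pytest.approx(expected)

    def test_volume_strictly_increases_when_voxel_added(self, rng):
        m = random_mask(rng, p=0.3)
        bg = np.argwhere(~m.voxels)
        i, j, k = bg[rng.integers(len(bg))]
        v0 = cm.volume_ml(m)
        m.voxels[i, j, k] = True
        assert cm.volume_ml(m) > v0

    def test_centroid_examples(self):
        one = np.zeros((5, 5, 5), bool)
        one[0, 0, 0] = True
        np.testing.assert_allclose(
            cm.centroid_mm(cm.MaskVolume(one, (1, 1, 1))), [0, 0, 0]
        )
        two = np.zeros((5, 5, 5), bool)
        two[0, 0, 0] = two[0, 0, 4] = True  # axis 2 is LR under the default map
        c = cm.centroid_mm(cm.MaskVolume(two, (1, 1, 1)))
        assert c[0] == pytest.approx(2.0)

    def test_centroid_matches_brute_force(self, rng):
        for axis_map in [("+CC", "+AP", "+LR"), ("-AP", "+CC", "-LR")]:
            m = random_mask(rng, spacing=(1.5, 2.0, 5.0), axis_map=axis_map)
            np.testing.assert_allclose(cm.centroid_mm(m), brute_centroid(m))

    def test_centroid_empty_mask_errors(self):
        with pytest.raises(cm.EmptyMaskError):
            cm.centroid_mm(cm.MaskVolume(np.zeros((2, 2, 2), bool), (1, 1, 1)))


class TestDice:
    def test_identity_disjoint_and_half(self, rng):
        a = random_mask(rng)
        assert cm.dice(a, a) == 1.0
        va = np.zeros((4, 4, 4), bool)
        vb = np.zeros((4, 4, 4), bool)
        va[0], vb[2] = True, True
        assert cm.dice(cm.MaskVolume(va, (1, 1, 1)), cm.MaskVolume(vb, (1, 1, 1))) == 0.0
        # |A| = |B| = 8, |A∩B| = 4 -> 2*4/16 = 0.5
        va = np.zeros((4, 4, 4), bool)
        vb = np.zeros((4, 4, 4), bool)
        va[0, 0:2, :] = True          # rows 0 and 1
        vb[0, 1:3, :] = True          # rows 1 and 2
        A, B = cm.MaskVolume(va, (1, 1, 1)), cm.MaskVolume(vb, (1, 1, 1))
        assert (A.n_foreground, B.n_foreground) == (8, 8)
        assert cm.dice(A, B) == pytest.approx(0.5)

    def test_matches_direct_set_counting(self, rng):
        for _ in range(30):
            a, b = random_mask(rng), random_mask(rng)
            sa = set(map(tuple, np.argwhere(a.voxels)))
            sb = set(map(tuple, np.argwhere(b.voxels)))
            expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert cm.dice(a, b) == pytest.approx(expected)
            assert cm.dice(b, a) == cm.dice(a, b)

    def test_errors(self):
        a = cm.MaskVolume(np.ones((2, 2, 2), bool), (1, 1, 1))
        b = cm.MaskVolume(np.ones((2, 2, 3), bool), (1, 1, 1))
        with pytest.raises(cm.GeometryError):
            cm.dice(a, b)
        e = cm.MaskVolume(np.zeros((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(cm.EmptyMaskError):
            cm.dice(e, e)


class TestSurface:
    def test_counts(self):
        one = np.zeros((3, 3, 3), bool)
        one[1, 1, 1] = True
        assert len(cm.surface_points(cm.MaskVolume(one, (1, 1, 1)))) == 1
        cube = np.zeros((5, 5, 5), bool)
        cube[1:4, 1:4, 1:4] = True
        assert len(cm.surface_points(cm.MaskVolume(cube, (1, 1, 1)))) == 26
        slab = np.zeros((1, 4, 4), bool)
        slab[0] = True  # one-voxel-thick: every voxel borders the grid edge
        assert len(cm.surface_points(cm.MaskVolume(slab, (1, 1, 1)))) == 16

    def test_grid_border_counts_as_background(self):
        full = cm.MaskVolume(np.ones((3, 3, 3), bool), (1, 1, 1))
        assert len(cm.surface_points(full)) == 26


class TestHausdorff:
    def test_closed_forms(self):
        assert cm.hausdorff_bruteforce(np.array([[0., 0, 0]]), np.array([[3., 4, 0]])) == 5.0
        a = np.array([[0.0, 0, 0], [1, 0, 0]])
        b = np.array([[0.0, 0, 0], [0, 2, 0]])
        assert cm.hausdorff_bruteforce(a, b) == pytest.approx(2.0)
        assert cm.hausdorff_bruteforce(a, a) == 0.0

    def test_fast_equals_bruteforce_on_random_pairs(self, rng):
        """Oracle equivalence on 200 random mask pairs up to 16^3."""
        for trial in range(200):
            shape = tuple(rng.integers(3, 17, size=3))
            spacing = tuple(rng.choice([0.5, 1.0, 2.0, 5.0], size=3))
            a = random_mask(rng, shape=shape, spacing=spacing, p=0.2)
            b = random_mask(rng, shape=shape, spacing=spacing, p=0.2)
            ref = cm.hausdorff_bruteforce(cm.surface_points(a), cm.surface_points(b))
            fast = cm.hausdorff_fast(a, b)
            assert fast == pytest.approx(ref, abs=1e-9), f"trial {trial}"

    def test_identity_and_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert cm.hausdorff_fast(a, a) == 0.0
        assert cm.hausdorff_fast(a, b) == pytest.approx(cm.hausdorff_fast(b, a), abs=1e-12)

    def test_triangle_inequality_spot_checks(self, rng):
        for _ in range(20):
            a, b, c = (random_mask(rng, p=0.25) for _ in range(3))
            hab = cm.hausdorff_fast(a, b)
            hbc = cm.hausdorff_fast(b, c)
            hac = cm.hausdorff_fast(a, c)
            assert hac <= hab + hbc + 1e-9

    def test_empty_errors(self):
        e = cm.MaskVolume(np.zeros((2, 2, 2), bool), (1, 1, 1))
        f = cm.MaskVolume(np.ones((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(cm.EmptyMaskError):
            cm.hausdorff_fast(e, f)


class TestInvariances:
    def test_translation_invariance(self, rng):
        a = random_mask(rng, shape=(8, 8, 8), p=0.3)
        b = random_mask(rng, shape=(8, 8, 8), p=0.3)
        pad = 3
        big = lambda v, off: np.pad(v, [(off[i] + 1, pad - off[i] + 1) for i in range(3)])
        off = (2, 1, 3)
        a1 = cm.MaskVolume(big(a.voxels, (0, 0, 0)), (1, 2, 5))
        b1 = cm.MaskVolume(big(b.voxels, (0, 0, 0)), (1, 2, 5))
        a2 = cm.MaskVolume(big(a.voxels, off), (1, 2, 5))
        b2 = cm.MaskVolume(big(b.voxels, off), (1, 2, 5))
        assert cm.dice(a1, b1) == cm.dice(a2, b2)
        assert cm.hausdorff_fast(a1, b1) == pytest.approx(cm.hausdorff_fast(a2, b2), abs=1e-9)

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(3))))
    def test_axis_permutation_invariance(self, rng, perm):
        """Jointly permuting grid axes, spacing, and axis_map leaves
        volume, centroid, dice, and Hausdorff unchanged."""
        base_map = ("+CC", "+AP", "+LR")
        spacing = (5.0, 2.0, 1.0)
        a = random_mask(rng, spacing=spacing, p=0.3)
        b = random_mask(rng, spacing=spacing, p=0.3)
        pa = cm.MaskVolume(np.transpose(a.voxels, perm),
                           tuple(spacing[i] for i in perm),
                           tuple(base_map[i] for i in perm))
        pb = cm.MaskVolume(np.transpose(b.voxels, perm),
                           tuple(spacing[i] for i in perm),
                           tuple(base_map[i] for i in perm))
        assert cm.volume_ml(pa) == pytest.approx(cm.volume_ml(a))
        np.testing.assert_allclose(cm.centroid_mm(pa), cm.centroid_mm(a))
        assert cm.dice(pa, pb) == pytest.approx(cm.dice(a, b))
        assert cm.hausdorff_fast(pa, pb) == pytest.approx(cm.hausdorff_fast(a, b), abs=1e-9)
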