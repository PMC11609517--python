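"""Cube reassembly: voting oracle, tie rule, permutation invariance, b-scans."""

import numpy as np
import pytest

from octaplex.enface import EnFaceImage
from octaplex.inference import (OUTSIDE_ROI, PredictionCube, assemble_cube,
                                slice_bscan)
from octaplex.model import upsample_nearest
from octaplex.phantoms import BoundarySurfaces, OctaVolume
from octaplex.slabs import ThinSlabStack


def _stack(depth_maps, half_width, shape):
    slabs = [EnFaceImage(np.zeros(shape), "unlabeled", "c")
             for _ in range(len(depth_maps))]
    return ThinSlabStack(slabs=slabs, depth_maps=np.asarray(depth_maps),
                         half_width=half_width, cube_id="c")


def _flat_boundaries(shape, ilm, sd, da, rpe):
    full = np.full(shape, 1.0)
    return BoundarySurfaces(ilm=ilm * full, sd_junction=sd * full,
                            da_junction=da * full, rpe=rpe * full)


def _brute_force_assemble(depth_maps, preds, half_width, depth, ilm, rpe):
    n, h, w, k = preds.shape
    labels = np.full((h, w, depth), OUTSIDE_ROI, dtype=int)
    for y in range(h):
        for x in range(w):
            for z in range(depth):
                score = np.zeros(k)
                hit = False
                for i in range(n):
                    c = depth_maps[i, y, x]
                    if c - half_width <= z <= c + half_width:
                        score += preds[i, y, x]
                        hit = True
                if hit:
                    labels[y, x, z] = int(score.argmax())
                if not (np.floor(ilm[y, x]) <= z <= np.floor(rpe[y, x])):
                    labels[y, x, z] = OUTSIDE_ROI
    return labels


class TestAssembleCube:
    def test_single_slab_voxel_gets_argmax(self):
        dm = np.full((1, 4, 4), 5)
        preds = np.zeros((1, 4, 4, 3))
        preds[0, :, :] = [0.2, 0.7, 0.1]
        stack = _stack(dm, 1, (4, 4))
        b = _flat_boundaries((4, 4), 0, 3, 6, 10)
        cube = assemble_cube(stack, preds, b, depth=12)
        assert (cube.labels[:, :, 4:7] == 1).all()

    def test_two_slab_tie_resolves_to_shallower_class(self):
        # summed scores (0.8, 0.8, 0.4): classes 0 and 1 tie -> class 0
        dm = np.stack([np.full((2, 2), 4), np.full((2, 2), 5)])
        preds = np.zeros((2, 2, 2, 3))
        preds[0, :, :] = [0.6, 0.3, 0.1]
        preds[1, :, :] = [0.2, 0.5, 0.3]
        stack = _stack(dm, 1, (2, 2))
        b = _flat_boundaries((2, 2), 0, 3, 6, 10)
        cube = assemble_cube(stack, preds, b, depth=12)
        assert (cube.labels[:, :, 4] == 0).all()  # covered by both slabs

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, trial):
        g = np.random.default_rng(trial)
        h = w = 4
        depth = 8
        n_slabs = 3
        dm = g.integers(1, depth - 1, (n_slabs, h, w))
        dm.sort(axis=0)
        preds = g.random((n_slabs, h, w, 3))
        preds /= preds.sum(axis=-1, keepdims=True)
        ilm = g.uniform(0, 2, (h, w))
        rpe = g.uniform(depth - 3, depth - 1, (h, w))
        b = BoundarySurfaces(ilm=ilm, sd_junction=ilm + 1, da_junction=ilm + 2,
                             rpe=rpe)
        stack = _stack(dm, 1, (h, w))
        cube = assemble_cube(stack, preds, b, depth=depth)
        expect = _brute_force_assemble(dm, preds, 1, depth, ilm, rpe)
        np.testing.assert_array_equal(cube.labels.astype(int), expect)

    def test_voting_permutation_invariant(self):
        g = np.random.default_rng(9)
        dm = g.integers(2, 8, (4, 3, 3))
        preds = g.random((4, 3, 3, 3))
        b = _flat_boundaries((3, 3), 0, 3, 6, 9)
        a = assemble_cube(_stack(dm, 1, (3, 3)), preds, b, depth=11)
        order = [2, 0, 3, 1]
        c = assemble_cube(_stack(dm[order], 1, (3, 3)), preds[order], b,
                          depth=11)
        np.testing.assert_array_equal(a.labels, c.labels)

    def test_vitreous_cropped(self):
        dm = np.full((1, 4, 4), 2)
        preds = np.ones((1, 4, 4, 3)) / 3
        b = _flat_boundaries((4, 4), 4, 6, 8, 10)  # ilm at 4
        cube = assemble_cube(_stack(dm, 1, (4, 4)), preds, b, depth=12)
        assert (cube.labels[:, :, :4] == OUTSIDE_ROI).all()


class TestUpsampleNearest:
    def test_2x2_blocks(self):
        arr = np.arange(4.0).reshape(2, 2)
        out = upsample_nearest(arr, 4)
        expect = arr.repeat(2, axis=0).repeat(2, axis=1)
        np.testing.assert_array_equal(out, expect)

    def test_distribution_stack_upsample(self):
        g = np.random.default_rng(0)
        p = g.random((2, 2, 3))
        out = upsample_nearest(p, 4)
        assert out.shape == (4, 4, 3)
        np.testing.assert_array_equal(out[:2, :2], np.broadcast_to(p[0, 0], (2, 2, 3)))


class TestSliceBscan:
    def _volume(self):
        g = np.random.default_rng(0)
        return OctaVolume(voxels=g.integers(0, 256, (8, 10, 12)).astype(np.uint8),
                          patient_id="p", eye="OD", cube_id="c")

    def test_all_outside_roi_equals_plain_bscan(self):
        vol = self._volume()
        cube = PredictionCube(labels=np.full(vol.shape, OUTSIDE_ROI, np.uint8),
                              cube_id="c")
        out = slice_bscan(cube, vol, 3)
        expect = np.repeat(vol.voxels[3].astype(float)[:, :, None], 3, axis=2)
        np.testing.assert_array_equal(out, np.rint(expect).astype(np.uint8))

    def test_output_dims(self):
        vol = self._volume()
        cube = PredictionCube(labels=np.zeros(vol.shape, np.uint8), cube_id="c")
        assert slice_bscan(cube, vol, 0).shape == (10, 12, 3)

    def test_row_out_of_range(self):
        vol = self._volume()
        cube = PredictionCube(labels=np.zeros(vol.shape, np.uint8), cube_id="c")
        with pytest.raises(IndexError):
            slice_bscan(cube, vol, 8)

    def test_perfect_labels_render_ordered_bands(self):
        """With ground-truth labels, colored bands follow the anatomical
        order superficial above deep above avascular in every column."""
        h, w, depth = 8, 8, 20
        b = _flat_boundaries((h, w), 2, 7, 12, 17)
        labels = np.full((h, w, depth), OUTSIDE_ROI, np.uint8)
        z = np.arange(depth)
        for y in range(h):
            for x in range(w):
                labels[y, x, (z >= 2) & (z < 7)] = 0
                labels[y, x, (z >= 7) & (z < 12)] = 1
                labels[y, x, (z >= 12) & (z <= 17)] = 2
        g = np.random.default_rng(1)
        vol = OctaVolume(voxels=g.integers(0, 256, (h, w, depth)).astype(np.uint8),
                         patient_id="p", eye="OD", cube_id="c")
        cube = PredictionCube(labels=labels, cube_id="c")
        out = slice_bscan(cube, vol, 2)
        lab_row = labels[2]
        for x in range(w):
            zs = {c: np.where(lab_row[x] == c)[0] for c in (0, 1, 2)}
            assert zs[0].max() < zs[1].min() < zs[2].min()
            # colored voxels differ from the grayscale underneath
            colored = lab_row[x] != OUTSIDE_ROI
            gray = vol.voxels[2, x].astype(float)
            assert not np.array_equal(out[x, colored],
                                      np.repeat(gray[colored, None], 3, 1))
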