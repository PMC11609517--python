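"""Whole-cube inference: slab prediction, volumetric reassembly, b-scans.

A trained model runs over every thin slab of a stack; each slab's
per-pixel class distribution is deposited back onto the voxels of the
slab's averaging window, the per-voxel scores are summed over all
depositing slabs, and the most likely class wins (probability-mass voting;
ties resolve to the anatomically shallower class).  Voxels outside the
ILM-RPE region of interest are cropped to an ``outside_roi`` code, and the
labeled cube can be sliced in the b-scan direction with a class-colored
overlay for qualitative review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import SegmentationResults, upsample_nearest
from .phantoms import BoundarySurfaces, OctaVolume
from .slabs import ThinSlabStack

logger = logging.getLogger(__name__)

OUTSIDE_ROI = 255

#: RGB overlay colors per class (superficial, deep, avascular)
CLASS_COLORS = np.array([[220, 60, 50], [70, 190, 90], [70, 110, 230]],
                        dtype=np.float64)


@dataclass
class PredictionCube:
    """Per-voxel plexus assignment reassembled from slab predictions."""

    labels: np.ndarray          # (H, W, D) uint8, {0, 1, 2, OUTSIDE_ROI}
    cube_id: str
    scores: np.ndarray | None = None  # (H, W, D, 3) accumulated mass

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be (H, W, D)")


def predict_slabs(results: SegmentationResults,
                  stack: ThinSlabStack) -> np.ndarray:
    """Per-slab, per-pixel 3-class distributions, (n_slabs, H, W, 3).

    Slabs are resized to the model input, predicted, and the distribution
    maps upsampled back to the slab resolution by nearest neighbor.
    """
    probs = results.predict_proba([s.pixels for s in stack.slabs])
    h, w = stack.slabs[0].shape
    if probs.shape[1:3] != (h, w):
        probs = np.stack([upsample_nearest(p, h) for p in probs])
    return probs


def assemble_cube(stack: ThinSlabStack, slab_predictions: np.ndarray,
                  boundaries: BoundarySurfaces, *, depth: int | None = None,
                  keep_scores: bool = False) -> PredictionCube:
    """Accumulate slab class distributions into a labeled voxel cube.

    Slab ``i`` deposits its distribution onto every voxel of its averaging
    window ``[c_i - half_width, c_i + half_width]``; per voxel the class
    scores sum over depositing slabs and the argmax is assigned (ties to
    the lower, anatomically shallower, class index — np.argmax's first-hit
    rule).  Voxels outside [ilm, rpe] are set to ``OUTSIDE_ROI``.
    """
    n_slabs, h, w, k = slab_predictions.shape
    if n_slabs != len(stack):
        raise ValueError("predictions do not align with the slab stack")
    if depth is None:
        depth = int(stack.depth_maps.max()) + stack.half_width + 1
    scores = np.zeros((h, w, depth, k), dtype=np.float64)
    ii, jj = np.mgrid[0:h, 0:w]
    for i in range(n_slabs):
        c = stack.depth_maps[i]
        for off in range(-stack.half_width, stack.half_width + 1):
            z = c + off
            valid = (z >= 0) & (z < depth)
            np.add.at(scores, (ii[valid], jj[valid], z[valid]),
                      slab_predictions[i][valid])
    covered = scores.sum(axis=-1) > 0
    labels = np.where(covered, scores.argmax(axis=-1), OUTSIDE_ROI)
    z = np.arange(depth)[None, None, :]
    roi = (z >= np.floor(boundaries.ilm)[:, :, None]) & \
          (z <= np.floor(boundaries.rpe)[:, :, None])
    labels = np.where(roi, labels, OUTSIDE_ROI).astype(np.uint8)
    logger.info("assembled cube %s: %d/%d retinal voxels labeled",
                stack.cube_id, int((labels != OUTSIDE_ROI).sum()), labels.size)
    return PredictionCube(labels=labels, cube_id=stack.cube_id,
                          scores=scores if keep_scores else None)


def slice_bscan(cube: PredictionCube, volume: OctaVolume, row_index: int,
                *, overlay_alpha: float = 0.45) -> np.ndarray:
    """Class-colored overlay of one b-scan row, (W_enface, D_depth, 3) uint8.

    The flow b-scan renders in grayscale; voxels with a plexus label blend
    toward their class color, ``outside_roi`` voxels stay uncolored.
    """
    h, w, depth = volume.shape
    if not 0 <= row_index < h:
        raise IndexError(f"row_index {row_index} outside [0, {h})")
    flow = volume.voxels[row_index].astype(np.float64)          # (W, D)
    labels = cube.labels[row_index]                              # (W, D)
    rgb = np.repeat(flow[:, :, None], 3, axis=2)
    inside = labels != OUTSIDE_ROI
    colors = CLASS_COLORS[np.clip(labels, 0, 2)]
    rgb[inside] = ((1 - overlay_alpha) * rgb[inside]
                   + overlay_alpha * colors[inside])
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
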