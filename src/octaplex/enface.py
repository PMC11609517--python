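"""Weakly labeled single-class en face images from OCTA volumes.

A slab projection takes the maximum voxel value through depth between two
boundary surfaces; each projection inherits a whole-image ("weak") class
label from the layer segmentation that bounded it.  Deeper slabs are cleaned
of the superficial projection artifact by scaled subtraction, and a
percentile normalization (bottom 2% of pixels to 0, top 1% to 255, linear
rescale between) produces a second set of images whose intensity histograms
no longer give the class away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .phantoms import PLEXUS_CLASSES, PhantomCohort

logger = logging.getLogger(__name__)

EN_FACE_LABELS = PLEXUS_CLASSES + ("mixed", "unlabeled")

#: Default scale of the superficial subtraction used to suppress tails.
DEFAULT_REMOVAL_ALPHA = 0.4


@dataclass
class EnFaceImage:
    """A 2-D grayscale en face image with its weak class label."""

    pixels: np.ndarray
    class_label: str
    cube_id: str
    normalized: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if float(p.min()) < 0 or float(p.max()) > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.class_label not in EN_FACE_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.rint rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def project_enface(volume, upper: np.ndarray, lower: np.ndarray,
                   *, class_label: str = "unlabeled") -> EnFaceImage:
    """Maximum-intensity projection through the closed depth interval
    [upper(x,y), lower(x,y)] at each en face pixel."""
    upper = np.asarray(upper, dtype=np.float64)
    lower = np.asarray(lower, dtype=np.float64)
    h, w, depth = volume.shape
    if upper.shape != (h, w) or lower.shape != (h, w):
        raise ValueError("boundary maps must match volume en face dims")
    if (upper > lower).any():
        raise ValueError("upper boundary exceeds lower boundary somewhere")
    if (upper < 0).any() or (lower >= depth).any():
        raise ValueError("boundaries exceed volume depth range")

    # integer depths z with upper <= z <= lower (closed interval); where no
    # integer falls inside a sub-voxel interval, the nearest voxel is used
    lo = np.ceil(upper).astype(np.intp)
    hi = np.floor(lower).astype(np.intp)
    empty = lo > hi
    if empty.any():
        mid = np.clip(np.rint((upper + lower) / 2.0), 0, depth - 1).astype(np.intp)
        lo = np.where(empty, mid, lo)
        hi = np.where(empty, mid, hi)
    z = np.arange(depth)[None, None, :]
    mask = (z >= lo[:, :, None]) & (z <= hi[:, :, None])
    vox = volume.voxels.astype(np.float32)
    out = np.where(mask, vox, -1.0).max(axis=2)
    return EnFaceImage(pixels=out.astype(np.float64), class_label=class_label,
                       cube_id=volume.cube_id)


def remove_projection_artifact(deeper: EnFaceImage, superficial: EnFaceImage,
                               alpha: float = DEFAULT_REMOVAL_ALPHA) -> EnFaceImage:
    """Suppress superficial-vessel tails in a deeper slab.

    Implemented as a per-pixel scaled subtraction of the superficial
    projection, clamped at zero: ``clamp(deeper - alpha * superficial, 0, 255)``.
    A declared stand-in for the instrument's (unpublished) slab-based
    projection-removal algorithm.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if deeper.shape != superficial.shape:
        raise ValueError("image shapes differ")
    out = np.clip(deeper.pixels - alpha * superficial.pixels, 0.0, 255.0)
    return replace(deeper, pixels=out)


def normalize_image(image: EnFaceImage) -> EnFaceImage:
    """Percentile contrast normalization.

    The bottom 2% of pixel values map to 0, the top 1% to 255, and the
    central band rescales linearly to span [0, 255].  A constant image is
    returned unchanged (flag set) with a warning.
    """
    pix = image.pixels.astype(np.float64)
    lo = float(np.percentile(pix, 2.0))
    hi = float(np.percentile(pix, 99.0))
    if hi <= lo:
        warnings.warn(f"normalize_image: degenerate intensity range on "
                      f"{image.cube_id} ({image.class_label}); returned unchanged")
        return replace(image, normalized=True)
    out = _round_half_away(255.0 * (pix - lo) / (hi - lo))
    out = np.clip(out, 0.0, 255.0)
    out[pix <= lo] = 0.0
    out[pix >= hi] = 255.0
    return replace(image, pixels=out, normalized=True)


def project_class_slabs(volume, boundaries) -> dict[str, EnFaceImage]:
    """The three weakly labeled slab projections of one cube.

    Zone voxel sets are disjoint: a voxel at integer depth z is superficial
    when ilm <= z < sd_junction, deep when sd_junction <= z < da_junction,
    avascular when da_junction <= z <= rpe.
    """
    ilm, sd, da, rpe = boundaries.ordered()
    intervals = {
        "superficial": (ilm, np.maximum(np.ceil(sd) - 1.0, ilm)),
        "deep": (sd, np.maximum(np.ceil(da) - 1.0, sd)),
        "avascular": (da, rpe),
    }
    return {label: project_enface(volume, up, lo, class_label=label)
            for label, (up, lo) in intervals.items()}


def build_single_class_dataset(
    cohort: PhantomCohort,
    include_normalized: bool = False,
    *,
    removal_alpha: float = DEFAULT_REMOVAL_ALPHA,
) -> list[EnFaceImage]:
    """Single-class images for every cube of a cohort.

    Exactly 3 images per cube (superficial, deep, avascular) — tail
    artifacts removed from the deep and avascular slabs — plus, with
    ``include_normalized``, the percentile-normalized copy of each, for 6
    per cube.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    out: list[EnFaceImage] = []
    for volume, boundaries in cohort.volumes:
        slabs = project_class_slabs(volume, boundaries)
        sup = slabs["superficial"]
        cleaned = [
            sup,
            remove_projection_artifact(slabs["deep"], sup, removal_alpha),
            remove_projection_artifact(slabs["avascular"], sup, removal_alpha),
        ]
        out.extend(cleaned)
        if include_normalized:
            out.extend(normalize_image(img) for img in cleaned)
    logger.info("single-class dataset: %d cubes -> %d images",
                len(cohort), len(out))
    return out
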