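"""Synthetic two-class training images.

A randomly placed, sized and rotated ovoid of one plexus class is blended
into a single-class image of an adjacent class through a blurred-edge
weight mask, giving a realistic soft transition; thresholding the mask at
50% yields the binary segmentation target.  Only the four adjacent
pairings along the anatomical order superficial-deep-avascular are formed:
superficial inset into deep, deep into superficial, deep into avascular,
and avascular into deep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .enface import EnFaceImage
from .phantoms import PLEXUS_CLASSES

logger = logging.getLogger(__name__)

#: (majority, minority) pairs in the order they are generated per cube.
ADJACENT_PAIRS = (
    ("deep", "superficial"),
    ("superficial", "deep"),
    ("avascular", "deep"),
    ("deep", "avascular"),
)

DEFAULT_AREA_FRACTION_RANGE = (0.05, 0.25)
#: Edge blur width range in pixels at a 256-px image scale; scaled by
#: image size when datasets are built.
DEFAULT_BLUR_RANGE = (2.0, 6.0)

_CLAMP_HI = 0.995
_CLAMP_LO = 0.005


@dataclass
class BlendMask:
    """Soft ovoid weight mask: 1 = pure minority, 0 = pure majority."""

    weights: np.ndarray
    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float
    blur_width: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("weights must be 2-D")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w


@dataclass
class TwoClassSample:
    """A blended mixed-class image with its binary minority-region target."""

    image: EnFaceImage
    target: np.ndarray
    majority_class: str
    minority_class: str
    normalized: bool
    cube_id: str
    mask: BlendMask | None = None

    def __post_init__(self) -> None:
        if (self.majority_class, self.minority_class) not in ADJACENT_PAIRS:
            raise ValueError(
                f"({self.majority_class}, {self.minority_class}) is not an "
                f"adjacent plexus pairing")
        t = np.asarray(self.target)
        if t.shape != self.image.shape:
            raise ValueError("target shape differs from image shape")
        if not t.any() or t.all():
            raise ValueError("target must contain both classes")
        self.target = t.astype(bool)


def _ellipse_weights(shape, center, axes, rotation_deg, blur):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    theta = np.deg2rad(rotation_deg)
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    a, b = axes
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    weights = ndimage.gaussian_filter(inside.astype(np.float64), blur)
    weights[weights >= _CLAMP_HI] = 1.0
    weights[weights <= _CLAMP_LO] = 0.0
    return np.clip(weights, 0.0, 1.0), inside


def make_blend_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    area_fraction_range: tuple[float, float] = DEFAULT_AREA_FRACTION_RANGE,
    blur_width_range: tuple[float, float] = DEFAULT_BLUR_RANGE,
    *,
    max_retries: int = 50,
) -> BlendMask:
    """Random soft ovoid mask with an exact-1 core and exact-0 exterior.

    The ellipse area fraction is drawn from ``area_fraction_range`` (must
    sit inside (0, 0.5): the minority region stays much smaller than the
    majority), its edge smoothed over a width drawn from
    ``blur_width_range``.  Masks that lose their saturated core or touch
    the border are resampled up to ``max_retries`` times.
    """
    h, w = (int(s) for s in shape)
    if h < 16 or w < 16:
        raise ValueError("mask shape must be at least 16x16")
    f_lo, f_hi = area_fraction_range
    if not (0.0 < f_lo <= f_hi < 0.5):
        raise ValueError("area_fraction_range must lie inside (0, 0.5)")

    for _ in range(max_retries):
        frac = rng.uniform(f_lo, f_hi)
        aspect = rng.uniform(1.0, 2.5)
        area = frac * h * w
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        blur = rng.uniform(*blur_width_range)
        rot = rng.uniform(0.0, 180.0)
        margin = max(a, b) + 3.0 * blur + 1.0
        if 2 * margin >= min(h, w):
            continue  # ellipse cannot fit strictly inside with its blur band
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        weights, _ = _ellipse_weights((h, w), (cy, cx), (a, b), rot, blur)
        core = weights >= 0.999
        border = np.zeros((h, w), dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if not core.any() or weights.max() < 1.0 or weights.min() > 0.0:
            continue
        if (weights[border] > 0).any():
            continue
        if ndimage.label(core)[1] != 1:
            continue
        return BlendMask(weights=weights, center=(cy, cx), axes=(a, b),
                         rotation_deg=rot, blur_width=blur)
    raise RuntimeError("could not sample a valid blend mask for this shape "
                       "and parameter range")


def blend_pair(majority: EnFaceImage, minority: EnFaceImage,
               mask: BlendMask) -> TwoClassSample:
    """Blend a minority-class ovoid into a majority-class image.

    Pixel value is the convex combination ``(1-w)*majority + w*minority``
    rounded to 8 bits; the binary target is ``w >= 0.5``.
    """
    if (majority.class_label, minority.class_label) not in ADJACENT_PAIRS:
        raise ValueError(
            f"({majority.class_label}, {minority.class_label}) is not an "
            f"adjacent plexus pairing")
    if majority.shape != minority.shape:
        raise ValueError("image shapes differ")
    if majority.normalized != minority.normalized:
        raise ValueError("cannot blend a normalized with a raw image")
    if mask.weights.shape != majority.shape:
        raise ValueError("mask shape differs from image shape")
    w = mask.weights
    blended = (1.0 - w) * majority.pixels + w * minority.pixels
    blended = np.clip(np.floor(blended + 0.5), 0.0, 255.0)
    image = EnFaceImage(pixels=blended, class_label="mixed",
                        cube_id=majority.cube_id,
                        normalized=majority.normalized)
    return TwoClassSample(image=image, target=w >= 0.5,
                          majority_class=majority.class_label,
                          minority_class=minority.class_label,
                          normalized=majority.normalized,
                          cube_id=majority.cube_id, mask=mask)


def build_twoclass_dataset(
    single_class: list[EnFaceImage],
    rng: np.random.Generator,
    include_normalized: bool = False,
    *,
    area_fraction_range: tuple[float, float] = DEFAULT_AREA_FRACTION_RANGE,
    blur_width_range: tuple[float, float] = DEFAULT_BLUR_RANGE,
) -> list[TwoClassSample]:
    """Four blended samples per cube from raw sources (one per adjacent
    pairing), eight with ``include_normalized``.

    Each pairing draws an independent mask.  A cube missing one of its
    class images contributes only the pairings that remain feasible, with
    a logged warning.  Blur widths are specified at 256-px scale and scaled
    to the actual image size.
    """
    by_cube: dict[tuple[str, bool], dict[str, EnFaceImage]] = {}
    for img in single_class:
        if img.class_label in PLEXUS_CLASSES:
            by_cube.setdefault((img.cube_id, img.normalized), {})[
                img.class_label] = img

    samples: list[TwoClassSample] = []
    cube_ids = sorted({cid for cid, _ in by_cube})
    variants = [False, True] if include_normalized else [False]
    for cube_id in cube_ids:
        for normalized in variants:
            images = by_cube.get((cube_id, normalized), {})
            missing = [c for c in PLEXUS_CLASSES if c not in images]
            if missing:
                logger.warning(
                    "cube %s (normalized=%s): missing %s image(s); "
                    "building feasible pairings only",
                    cube_id, normalized, "/".join(missing))
            for maj, mino in ADJACENT_PAIRS:
                if maj not in images or mino not in images:
                    continue
                shape = images[maj].shape
                scale = min(shape) / 256.0
                blur = (max(0.5, blur_width_range[0] * scale),
                        max(0.75, blur_width_range[1] * scale))
                mask = make_blend_mask(shape, rng, area_fraction_range, blur)
                samples.append(blend_pair(images[maj], images[mino], mask))
    logger.info("two-class dataset: %d cubes -> %d samples",
                len(cube_ids), len(samples))
    return samples
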