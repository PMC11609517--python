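"""Synthetic OCTA phantom volumes with known plexus zones and boundary surfaces.

Real OCT-angiography cubes image three depth-ordered vascular zones: a
superficial plexus of bright large vessels, a deep plexus of fine capillary
mesh, and an avascular outer retina carrying only low-amplitude speckle.
The phantoms emulate exactly those texture statistics — plus the smooth
retinal boundary surfaces (ILM, superficial/deep junction, deep/avascular
junction, RPE) and, optionally, the "tail" projection artifact where
superficial large vessels echo at deeper depths — so that every downstream
stage (slab projection, blending, training, volumetric reassembly) can be
exercised and scored against a known ground truth.

Axial index convention: depth index 0 is innermost (vitreous side) and
increases toward the RPE.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Plexus classes in anatomical depth order (inner to outer).
PLEXUS_CLASSES = ("superficial", "deep", "avascular")

#: Fraction of healthy patients in the emulated clinic population (14 of 33).
HEALTHY_FRACTION = 14 / 33

# Texture recipe defaults.  The values are chosen so that the three classes
# are separable by patch statistics (see TextureParams docstring) while
# keeping the mean-intensity ordering superficial > deep > avascular.
_SUP_BACKGROUND = 100.0
_SUP_VESSEL = 245.0
_DEEP_MEAN = 85.0
_DEEP_AMPLITUDE = 45.0
_AVASC_MEAN = 14.0
_AVASC_MAX = 100.0
_VOXEL_NOISE_SD = 5.0
_FLOOR_LEVEL = 3.0


class ClassDomainError(ValueError):
    """Raised for a plexus class label outside {superficial, deep, avascular}."""


@dataclass
class OctaVolume:
    """A 3-D OCTA intensity cube with acquisition metadata.

    ``voxels`` is indexed ``(row, col, depth)`` — en face H x W x D — with
    intensities in [0, 255] stored as uint8.
    """

    voxels: np.ndarray
    patient_id: str
    eye: str
    cube_id: str
    pixel_size_um: tuple[float, float, float] = (12.0, 12.0, 2.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("voxels must be a 3-D array (H, W, D)")
        if any(s < 8 for s in v.shape):
            raise ValueError(f"all volume dims must be >= 8, got {v.shape}")
        if not np.isfinite(np.asarray(v, dtype=np.float64)).all():
            raise ValueError("voxel intensities must be finite")
        if float(v.min()) < 0 or float(v.max()) > 255:
            raise ValueError("voxel intensities must lie in [0, 255]")
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def depth(self) -> int:
        return self.voxels.shape[2]


@dataclass
class BoundarySurfaces:
    """Per-pixel depths (axial voxel units) of the four retinal surfaces.

    At every en face pixel: 0 <= ilm <= sd_junction <= da_junction <= rpe.
    The superficial zone is [ilm, sd_junction), the deep zone
    [sd_junction, da_junction) and the avascular zone [da_junction, rpe].
    """

    ilm: np.ndarray
    sd_junction: np.ndarray
    da_junction: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        maps = [np.asarray(m, dtype=np.float64) for m in
                (self.ilm, self.sd_junction, self.da_junction, self.rpe)]
        shape = maps[0].shape
        if any(m.shape != shape for m in maps):
            raise ValueError("all boundary maps must share one shape")
        if any(not np.isfinite(m).all() for m in maps):
            raise ValueError("boundary surfaces must be finite everywhere")
        if (maps[0] < 0).any():
            raise ValueError("ilm must be >= 0 everywhere")
        for upper, lower, name in zip(maps[:-1], maps[1:],
                                      ("ilm<=sd", "sd<=da", "da<=rpe")):
            if (upper > lower).any():
                raise ValueError(f"boundary ordering violated: {name}")
        self.ilm, self.sd_junction, self.da_junction, self.rpe = maps

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm.shape

    def ordered(self) -> tuple[np.ndarray, ...]:
        return self.ilm, self.sd_junction, self.da_junction, self.rpe

    def validate_against(self, volume: OctaVolume) -> None:
        if self.shape != volume.shape[:2]:
            raise ValueError("boundary maps do not match volume en face dims")
        if float(self.rpe.max()) >= volume.depth:
            raise ValueError("rpe reaches or exceeds volume depth")


@dataclass
class PatientRecord:
    patient_id: str
    disease_flag: bool
    cube_counts: dict[str, int] = field(default_factory=dict)  # eye -> count


@dataclass
class PhantomCohort:
    """A seeded, regenerable collection of phantom volumes grouped by patient."""

    patients: list[PatientRecord]
    volumes: list[tuple[OctaVolume, BoundarySurfaces]]
    rng_seed: int

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        for vol, _ in self.volumes:
            if vol.patient_id not in ids:
                raise ValueError(f"volume {vol.cube_id} has unknown patient "
                                 f"{vol.patient_id}")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def patient_of_cube(self) -> dict[str, str]:
        return {vol.cube_id: vol.patient_id for vol, _ in self.volumes}

    def disease_of_patient(self) -> dict[str, bool]:
        return {p.patient_id: p.disease_flag for p in self.patients}


# ---------------------------------------------------------------------------
# Texture synthesis


def _smooth_field(shape, rng, sigma, amplitude):
    """Low-frequency random surface: smoothed white noise, unit-sd rescaled."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return amplitude * f


def _superficial_vessels(shape, rng) -> np.ndarray:
    """Bright, branching, curvilinear large-vessel map (0 where no vessel).

    Persistent random walks, dilated to 3-px calibre and lightly blurred —
    a caricature of the arcade vessels a superficial slab projection shows.
    """
    h, w = shape
    canvas = np.zeros((h, w), dtype=np.float64)
    n_walks = max(3, (h * w) // 700)
    length = 2 * max(h, w)
    for _ in range(n_walks):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(length):
            canvas[int(y) % h, int(x) % w] = 1.0
            theta += rng.normal(0.0, 0.25)
            y += np.sin(theta)
            x += np.cos(theta)
            if rng.random() < 0.01:  # occasional branch kink
                theta = rng.uniform(0, 2 * np.pi)
    canvas = ndimage.binary_dilation(canvas > 0, structure=np.ones((2, 2)))
    vessels = ndimage.gaussian_filter(canvas.astype(np.float64), 0.5)
    vessels = np.clip(vessels * 1.4, 0.0, 1.0)
    return vessels * (_SUP_VESSEL - _SUP_BACKGROUND)


def generate_texture(class_label: str, shape: tuple[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """En face texture for one plexus class, float array in [0, 255].

    superficial — sparse bright curvilinear vessels on a smooth mid-grey
    background; deep — dense fine-scale capillary mesh (band-pass noise);
    avascular — low-amplitude speckle (max < 128 by construction).
    Mean intensity ordering superficial > deep > avascular holds in
    expectation.
    """
    if class_label not in PLEXUS_CLASSES:
        raise ClassDomainError(f"unknown plexus class {class_label!r}")
    h, w = int(shape[0]), int(shape[1])
    if h < 8 or w < 8:
        raise ValueError(f"texture shape must be >= 8x8, got {shape}")

    if class_label == "superficial":
        background = _SUP_BACKGROUND + _smooth_field((h, w), rng, 4.0, 8.0)
        tex = background + _superficial_vessels((h, w), rng)
    elif class_label == "deep":
        noise = rng.standard_normal((h, w))
        band = (ndimage.gaussian_filter(noise, 0.8, mode="reflect")
                - ndimage.gaussian_filter(noise, 2.5, mode="reflect"))
        sd = band.std()
        if sd > 0:
            band = band / sd
        tex = _DEEP_MEAN + _DEEP_AMPLITUDE * band
        tex = np.clip(tex, 20.0, 160.0)
    else:  # avascular
        speckle = np.abs(ndimage.gaussian_filter(
            rng.standard_normal((h, w)), 0.6, mode="reflect"))
        mean = speckle.mean()
        if mean > 0:
            speckle = speckle / mean
        tex = np.clip(_AVASC_MEAN * speckle, 0.0, _AVASC_MAX)
    return np.clip(tex, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Volume synthesis


def _boundary_surfaces(shape, depth, rng, disease=False) -> BoundarySurfaces:
    """Smooth monotone boundary stack at canonical fractional depths."""
    base = {"ilm": 0.14, "sd": 0.36, "da": 0.58, "rpe": 0.82}
    wobble = 0.035 * depth
    fields = {k: f * depth + _smooth_field(shape, rng, max(shape) / 6, wobble)
              for k, f in base.items()}
    if disease:
        # one localized dome pushing all surfaces outward, a generic
        # boundary distortion standing in for pathology
        h, w = shape
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        yy, xx = np.mgrid[0:h, 0:w]
        bump = np.exp(-(((yy - cy) / (0.18 * h)) ** 2
                        + ((xx - cx) / (0.18 * w)) ** 2))
        amp = 0.08 * depth
        for k in fields:
            fields[k] = fields[k] + amp * bump
    # enforce ordering with minimum zone thickness of 3 axial voxels
    ilm = np.clip(fields["ilm"], 1.0, 0.30 * depth)
    sd = np.maximum(fields["sd"], ilm + 3.0)
    da = np.maximum(fields["da"], sd + 3.0)
    rpe = np.maximum(fields["rpe"], da + 3.0)
    rpe = np.minimum(rpe, depth - 6.0)
    da = np.minimum(da, rpe - 3.0)
    sd = np.minimum(sd, da - 3.0)
    ilm = np.minimum(ilm, sd - 3.0)
    ilm = np.maximum(ilm, 0.0)
    return BoundarySurfaces(ilm=ilm, sd_junction=sd, da_junction=da, rpe=rpe)


def generate_phantom_volume(
    patient_id: str,
    eye: str,
    dims: tuple[int, int, int],
    rng: np.random.Generator,
    *,
    cube_id: str | None = None,
    projection_tails: bool = True,
    tail_attenuation: float = 0.4,
    disease: bool = False,
) -> tuple[OctaVolume, BoundarySurfaces]:
    """One phantom cube plus its ground-truth boundary surfaces.

    Depth interval [ilm, sd_junction) carries superficial texture,
    [sd_junction, da_junction) deep texture, and [da_junction, rpe] avascular
    texture; outside the retina only a low noise floor remains.  With
    ``projection_tails`` the superficial large-vessel map is added into the
    deep zone attenuated by ``tail_attenuation``, mimicking the projection
    artifact of OCTA ("tails" of large vessels at deeper depths).
    """
    h, w, depth = (int(d) for d in dims)
    if h < 8 or w < 8 or depth < 16:
        raise ValueError(f"volume dims too small: {dims}")
    surfaces = _boundary_surfaces((h, w), depth, rng, disease=disease)

    sup_bg = _SUP_BACKGROUND + _smooth_field((h, w), rng, 4.0, 8.0)
    vessels = _superficial_vessels((h, w), rng)
    sup_tex = np.clip(sup_bg + vessels, 0.0, 255.0)
    deep_tex = generate_texture("deep", (h, w), rng)
    avas_tex = generate_texture("avascular", (h, w), rng)
    if projection_tails:
        deep_tex = np.clip(deep_tex + tail_attenuation * vessels, 0.0, 255.0)

    z = np.arange(depth)[None, None, :]
    ilm = surfaces.ilm[:, :, None]
    sd = surfaces.sd_junction[:, :, None]
    da = surfaces.da_junction[:, :, None]
    rpe = surfaces.rpe[:, :, None]

    vol = np.full((h, w, depth), _FLOOR_LEVEL, dtype=np.float32)
    in_sup = (z >= ilm) & (z < sd)
    in_deep = (z >= sd) & (z < da)
    in_avas = (z >= da) & (z <= rpe)
    vol = np.where(in_sup, sup_tex[:, :, None], vol)
    vol = np.where(in_deep, deep_tex[:, :, None], vol)
    vol = np.where(in_avas, avas_tex[:, :, None], vol)
    vol += rng.normal(0.0, _VOXEL_NOISE_SD, size=vol.shape).astype(np.float32)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    volume = OctaVolume(
        voxels=vol,
        patient_id=patient_id,
        eye=eye,
        cube_id=cube_id or f"{patient_id}_{eye}_c0",
    )
    surfaces.validate_against(volume)
    return volume, surfaces


def generate_cohort(
    n_patients: int,
    cubes_per_patient_range: tuple[int, int],
    dims: tuple[int, int, int],
    seed: int,
    *,
    total_cubes: int | None = None,
    healthy_fraction: float = HEALTHY_FRACTION,
    projection_tails: bool = True,
) -> PhantomCohort:
    """A reproducible multi-patient cohort of phantom cubes.

    Per-patient cube counts are drawn uniformly from
    ``cubes_per_patient_range`` (inclusive); if ``total_cubes`` is given the
    counts are then adjusted within the range to hit that exact total.
    Patients with two or more cubes image both eyes.  Regenerating with the
    same seed reproduces identical voxel data.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients")
    lo, hi = (int(c) for c in cubes_per_patient_range)
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid cubes_per_patient_range {cubes_per_patient_range}")
    if total_cubes is not None and not (n_patients * lo <= total_cubes <= n_patients * hi):
        raise ValueError("total_cubes unreachable within the per-patient range")

    root = np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))

    counts = rng.integers(lo, hi + 1, size=n_patients)
    if total_cubes is not None:
        # nudge counts within [lo, hi] until the total matches
        diff = total_cubes - int(counts.sum())
        order = rng.permutation(n_patients)
        i = 0
        while diff != 0:
            j = order[i % n_patients]
            if diff > 0 and counts[j] < hi:
                counts[j] += 1
                diff -= 1
            elif diff < 0 and counts[j] > lo:
                counts[j] -= 1
                diff += 1
            i += 1

    n_healthy = max(1, int(round(healthy_fraction * n_patients)))
    disease_flags = np.array([False] * n_healthy
                             + [True] * (n_patients - n_healthy))
    rng.shuffle(disease_flags)

    patients: list[PatientRecord] = []
    volumes: list[tuple[OctaVolume, BoundarySurfaces]] = []
    for i in range(n_patients):
        pid = f"p{i + 1:03d}"
        n_cubes = int(counts[i])
        eyes = ["OD" if rng.random() < 0.5 else "OS"] if n_cubes == 1 else (
            ["OD", "OS"] + ["OD" if rng.random() < 0.5 else "OS"
                            for _ in range(n_cubes - 2)])
        rng.shuffle(eyes)
        rec = PatientRecord(patient_id=pid, disease_flag=bool(disease_flags[i]))
        for k, eye in enumerate(eyes):
            rec.cube_counts[eye] = rec.cube_counts.get(eye, 0) + 1
            cube_rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=seed, spawn_key=(1, i, k))))
            vol, bnd = generate_phantom_volume(
                pid, eye, dims, cube_rng,
                cube_id=f"{pid}_{eye}_c{k}",
                projection_tails=projection_tails,
                disease=rec.disease_flag,
            )
            volumes.append((vol, bnd))
        patients.append(rec)
    logger.info("generated cohort: %d patients, %d cubes", n_patients, len(volumes))
    return PhantomCohort(patients=patients, volumes=volumes, rng_seed=seed)
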