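"""File formats: TIFF volumes, PNG images and masks, CSV/JSON manifests.

Volumes are stored as multi-page 8-bit TIFF stacks, one en face page per
depth index.  Boundary surfaces travel in a JSON sidecar (lists of rows
per surface).  En face images and binary targets are 8-bit grayscale PNG;
thin-slab center-depth maps are 16-bit PNG.  Dataset manifests are CSV,
cohort and split manifests JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .blending import TwoClassSample
from .enface import EnFaceImage
from .phantoms import (BoundarySurfaces, OctaVolume, PatientRecord,
                       PhantomCohort)
from .slabs import ThinSlabStack

logger = logging.getLogger(__name__)


# -- volumes ----------------------------------------------------------------


def save_volume(volume: OctaVolume, boundaries: BoundarySurfaces | None,
                path) -> None:
    """Multi-page TIFF (pages = depth indices) + JSON boundary sidecar."""
    path = Path(path)
    pages = np.moveaxis(volume.voxels.astype(np.uint8), 2, 0)  # (D, H, W)
    tifffile.imwrite(path, pages, metadata={
        "patient_id": volume.patient_id, "eye": volume.eye,
        "cube_id": volume.cube_id,
        "pixel_size_um": list(volume.pixel_size_um)})
    if boundaries is not None:
        sidecar = {name: getattr(boundaries, name).tolist()
                   for name in ("ilm", "sd_junction", "da_junction", "rpe")}
        path.with_suffix(".boundaries.json").write_text(json.dumps(sidecar))


def load_volume(path) -> tuple[OctaVolume, BoundarySurfaces | None]:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    volume = OctaVolume(voxels=np.moveaxis(pages, 0, 2),
                        patient_id=meta.get("patient_id", "unknown"),
                        eye=meta.get("eye", "OD"),
                        cube_id=meta.get("cube_id", path.stem),
                        pixel_size_um=tuple(meta.get("pixel_size_um",
                                                     (12.0, 12.0, 2.0))))
    bpath = path.with_suffix(".boundaries.json")
    boundaries = None
    if bpath.exists():
        d = json.loads(bpath.read_text())
        boundaries = BoundarySurfaces(**{k: np.asarray(v) for k, v in d.items()})
    return volume, boundaries


def save_cohort(cohort: PhantomCohort, out_dir) -> Path:
    """Write every cube and a JSON cohort manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    disease = cohort.disease_of_patient()
    entries = []
    for volume, boundaries in cohort.volumes:
        rel = f"{volume.cube_id}.tif"
        save_volume(volume, boundaries, out_dir / rel)
        entries.append({"patient_id": volume.patient_id, "eye": volume.eye,
                        "cube_id": volume.cube_id, "path": rel,
                        "disease_flag": disease[volume.patient_id]})
    manifest = {
        "rng_seed": cohort.rng_seed,
        "patients": [{"patient_id": p.patient_id,
                      "disease_flag": p.disease_flag,
                      "cube_counts": p.cube_counts} for p in cohort.patients],
        "cubes": entries,
    }
    mpath = out_dir / "cohort.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    logger.info("cohort written to %s (%d cubes)", out_dir, len(entries))
    return mpath


def load_cohort(manifest_path) -> PhantomCohort:
    manifest_path = Path(manifest_path)
    d = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    patients = [PatientRecord(patient_id=p["patient_id"],
                              disease_flag=p["disease_flag"],
                              cube_counts={k: int(v) for k, v in
                                           p["cube_counts"].items()})
                for p in d["patients"]]
    volumes = []
    for e in d["cubes"]:
        vol, bnd = load_volume(base / e["path"])
        volumes.append((vol, bnd))
    return PhantomCohort(patients=patients, volumes=volumes,
                         rng_seed=int(d["rng_seed"]))


# -- en face images ---------------------------------------------------------


def _png_name(img: EnFaceImage) -> str:
    tag = "norm" if img.normalized else "raw"
    return f"{img.cube_id}_{img.class_label}_{tag}.png"


def save_single_class_dataset(images: list[EnFaceImage], out_dir) -> Path:
    """8-bit grayscale PNGs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        name = _png_name(img)
        iio.imwrite(out_dir / name,
                    np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8))
        rows.append({"cube_id": img.cube_id, "class_label": img.class_label,
                     "normalized": img.normalized, "path": name})
    mpath = out_dir / "single_class_manifest.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


def load_single_class_dataset(manifest_path) -> list[EnFaceImage]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    return [EnFaceImage(pixels=iio.imread(base / r.path).astype(np.float64),
                        class_label=r.class_label, cube_id=r.cube_id,
                        normalized=bool(r.normalized))
            for r in df.itertuples()]


def save_twoclass_dataset(samples: list[TwoClassSample], out_dir) -> Path:
    """PNG pairs (image, binary target) plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        tag = "norm" if s.normalized else "raw"
        stem = f"{s.cube_id}_{s.majority_class}-{s.minority_class}_{tag}"
        iio.imwrite(out_dir / f"{stem}.png",
                    np.clip(np.rint(s.image.pixels), 0, 255).astype(np.uint8))
        iio.imwrite(out_dir / f"{stem}_target.png",
                    (s.target.astype(np.uint8) * 255))
        row = {"cube_id": s.cube_id, "majority": s.majority_class,
               "minority": s.minority_class, "normalized": s.normalized,
               "image": f"{stem}.png", "target": f"{stem}_target.png"}
        if s.mask is not None:
            row.update(center_y=s.mask.center[0], center_x=s.mask.center[1],
                       semi_major=s.mask.axes[0], semi_minor=s.mask.axes[1],
                       rotation_deg=s.mask.rotation_deg,
                       blur_width=s.mask.blur_width)
        rows.append(row)
    mpath = out_dir / "twoclass_manifest.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


def load_twoclass_dataset(manifest_path) -> list[TwoClassSample]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    out = []
    for r in df.itertuples():
        image = EnFaceImage(
            pixels=iio.imread(base / r.image).astype(np.float64),
            class_label="mixed", cube_id=r.cube_id,
            normalized=bool(r.normalized))
        target = iio.imread(base / r.target) > 127
        out.append(TwoClassSample(image=image, target=target,
                                  majority_class=r.majority,
                                  minority_class=r.minority,
                                  normalized=bool(r.normalized),
                                  cube_id=r.cube_id))
    return out


# -- thin slabs -------------------------------------------------------------


def save_thin_slabs(stack: ThinSlabStack, out_dir) -> Path:
    """Slab PNGs, 16-bit depth-map PNGs, and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, slab in enumerate(stack.slabs):
        sname = f"{stack.cube_id}_slab{i:03d}.png"
        dname = f"{stack.cube_id}_slab{i:03d}_depth.png"
        iio.imwrite(out_dir / sname,
                    np.clip(np.rint(slab.pixels), 0, 255).astype(np.uint8))
        iio.imwrite(out_dir / dname,
                    stack.depth_maps[i].astype(np.uint16))
        entries.append({"slab": sname, "depth_map": dname})
    sidecar = {"cube_id": stack.cube_id, "half_width": stack.half_width,
               "slabs": entries}
    spath = out_dir / f"{stack.cube_id}_slabs.json"
    spath.write_text(json.dumps(sidecar, indent=2))
    return spath


def load_thin_slabs(sidecar_path) -> ThinSlabStack:
    sidecar_path = Path(sidecar_path)
    d = json.loads(sidecar_path.read_text())
    base = sidecar_path.parent
    slabs, depths = [], []
    for e in d["slabs"]:
        slabs.append(EnFaceImage(
            pixels=iio.imread(base / e["slab"]).astype(np.float64),
            class_label="unlabeled", cube_id=d["cube_id"]))
        depths.append(iio.imread(base / e["depth_map"]).astype(np.intp))
    return ThinSlabStack(slabs=slabs, depth_maps=np.stack(depths),
                         half_width=int(d["half_width"]),
                         cube_id=d["cube_id"])


# -- prediction cubes -------------------------------------------------------


def save_prediction_cube(cube, path) -> None:
    """Label codes {0,1,2,255} as a multi-page 8-bit TIFF."""
    pages = np.moveaxis(cube.labels, 2, 0)
    tifffile.imwrite(Path(path), pages, metadata={"cube_id": cube.cube_id})


def load_prediction_cube(path):
    from .inference import PredictionCube
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return PredictionCube(labels=np.moveaxis(pages, 0, 2),
                          cube_id=meta.get("cube_id", path.stem))
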