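"""The plexus segmentation model: configuration, augmentation, training.

The estimator follows the fit/results idiom: :class:`SegmentationModel`
holds the training and validation data plus a :class:`TrainConfig`;
``fit()`` runs seeded mini-batch Adam on per-pixel categorical
cross-entropy and returns a :class:`SegmentationResults` carrying the
learned weights, the loss history, diagnostics, prediction methods and a
``summary()`` table.

Training images are single-class slab projections (whole-image weak
labels), synthetic two-class blends (binary targets), or both
(``dataset_mix``).  Augmentation applies horizontal/vertical flips and a
rotation of up to 45 degrees followed by cropping to the largest inscribed
axis-aligned square (removing blank corners, which zooms slightly) with the
identical geometric transform on the label map.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import nn
from .blending import TwoClassSample
from .enface import EnFaceImage
from .phantoms import PLEXUS_CLASSES

logger = logging.getLogger(__name__)

DATASET_MIXES = ("single", "twoclass", "combined")

#: class name -> label index, anatomical order
CLASS_INDEX = {c: i for i, c in enumerate(PLEXUS_CLASSES)}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the reference training regime (256-px inputs, 3
    classes, Adam at a maximum learning rate of 1e-4, batch 32); the
    ``tiny`` backbone scale and a smaller epoch budget are the desk-scale
    defaults, while ``backbone_scale='paper'`` constructs the full-depth
    network.
    """

    input_size: int = 256
    n_classes: int = 3
    max_learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 300
    architecture: str = "unet_like"
    backbone_scale: str = "tiny"
    dataset_mix: str = "combined"
    seed: int = 0
    augment: bool = True
    lr_schedule: str = "constant"  # or "one_cycle"
    val_interval: int = 10
    base_channels: int | None = None  # override the scale preset

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("the plexus task is fixed at 3 classes")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.architecture not in nn.ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.backbone_scale not in nn.SCALE_PRESETS:
            raise ValueError(f"unknown backbone_scale {self.backbone_scale!r}")
        if self.dataset_mix not in DATASET_MIXES:
            raise ValueError(f"unknown dataset_mix {self.dataset_mix!r}")
        if self.lr_schedule not in ("constant", "one_cycle"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


# ---------------------------------------------------------------------------
# Geometry: resizing and augmentation


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix averaging input cells into output cells by
    exact interval overlap (area averaging in 1-D)."""
    edges = np.linspace(0.0, n_in, n_out + 1)
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        a, b = edges[i], edges[i + 1]
        for j in range(int(np.floor(a)), min(int(np.ceil(b)), n_in)):
            w[i, j] = min(b, j + 1) - max(a, j)
    return w / (n_in / n_out)


def resize_for_model(image: np.ndarray, target: int) -> np.ndarray:
    """Downsample a grayscale image to ``target`` x ``target`` by exact
    area averaging; a no-op when the size already matches."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if (h, w) == (target, target):
        return img.copy()
    return _area_weights(h, target) @ img @ _area_weights(w, target).T


def resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbor resample of a label/binary mask (stays categorical)."""
    m = np.asarray(mask)
    h, w = m.shape
    if (h, w) == (target, target):
        return m.copy()
    ri = np.minimum((np.arange(target) + 0.5) * h / target, h - 1).astype(np.intp)
    ci = np.minimum((np.arange(target) + 0.5) * w / target, w - 1).astype(np.intp)
    return m[np.ix_(ri, ci)]


def upsample_nearest(arr: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbor upsample of a 2-D map (or H x W x C stack)."""
    h, w = arr.shape[:2]
    ri = np.minimum((np.arange(target) + 0.5) * h / target, h - 1).astype(np.intp)
    ci = np.minimum((np.arange(target) + 0.5) * w / target, w - 1).astype(np.intp)
    return arr[np.ix_(ri, ci)]


def largest_inscribed_square_side(n: int, angle_deg: float) -> int:
    """Side of the largest axis-aligned square free of rotation padding
    when an n x n image rotates by ``angle_deg`` (|angle| <= 45)."""
    a = np.deg2rad(abs(angle_deg))
    return int(np.floor(n / (np.cos(a) + np.sin(a))))


#: safety margin (px) trimmed off the inscribed square so order-1
#: interpolation near the valid-region border cannot leak fill values
_CROP_MARGIN = 2


def augment(image: np.ndarray, target: np.ndarray, rng: np.random.Generator,
            *, max_rotation_deg: float = 45.0) -> tuple[np.ndarray, np.ndarray]:
    """Random flip / flip / rotate-and-crop augmentation of a square image
    and its label map, with the identical geometric transform on both.

    Rotation is followed by a center crop to the largest inscribed
    axis-aligned square (no padded corners survive) and a resize back to
    the input size, which zooms in slightly.  The label map uses
    nearest-neighbor interpolation throughout and stays categorical.
    """
    img = np.asarray(image, dtype=np.float64)
    tgt = np.asarray(target)
    if img.shape != tgt.shape:
        raise ValueError("image and target shapes differ")
    if img.shape[0] != img.shape[1]:
        raise ValueError("augmentation expects square images")
    n = img.shape[0]
    if rng.random() < 0.5:
        img, tgt = img[:, ::-1], tgt[:, ::-1]
    if rng.random() < 0.5:
        img, tgt = img[::-1, :], tgt[::-1, :]
    angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    if abs(angle) > 1e-3:
        img = sktransform.rotate(img, angle, resize=False, order=1,
                                 mode="constant", cval=0.0, preserve_range=True)
        tgt = sktransform.rotate(tgt.astype(np.float64), angle, resize=False,
                                 order=0, mode="constant", cval=0.0,
                                 preserve_range=True).astype(target.dtype)
        side = max(8, largest_inscribed_square_side(n, angle) - _CROP_MARGIN)
        lo = (n - side) // 2
        img = img[lo:lo + side, lo:lo + side]
        tgt = tgt[lo:lo + side, lo:lo + side]
        img = sktransform.resize(img, (n, n), order=1, mode="edge",
                                 anti_aliasing=False, preserve_range=True)
        tgt = resize_mask(tgt, n)
    return np.ascontiguousarray(img), np.ascontiguousarray(tgt)


# ---------------------------------------------------------------------------
# Training data assembly


@dataclass
class TrainingPair:
    """One (image, per-pixel label map) example."""

    image: np.ndarray           # (H, W) float, [0, 255]
    labels: np.ndarray          # (H, W) int in {0, 1, 2}
    cube_id: str
    kind: str                   # "single" | "twoclass"


def as_training_pairs(
    single_class: list[EnFaceImage] | None = None,
    twoclass: list[TwoClassSample] | None = None,
    dataset_mix: str = "combined",
) -> list[TrainingPair]:
    """Convert dataset images into (image, label-map) training pairs.

    Single-class images give a whole-image constant label map (the weak
    label); two-class samples give the majority label with the minority
    label inside the thresholded blend target.
    """
    if dataset_mix not in DATASET_MIXES:
        raise ValueError(f"unknown dataset_mix {dataset_mix!r}")
    pairs: list[TrainingPair] = []
    if dataset_mix in ("single", "combined"):
        for img in single_class or []:
            if img.class_label not in CLASS_INDEX:
                raise ValueError(
                    f"single-class image with label {img.class_label!r}")
            labels = np.full(img.shape, CLASS_INDEX[img.class_label], dtype=np.int8)
            pairs.append(TrainingPair(img.pixels, labels, img.cube_id, "single"))
    if dataset_mix in ("twoclass", "combined"):
        for s in twoclass or []:
            labels = np.full(s.image.shape, CLASS_INDEX[s.majority_class],
                             dtype=np.int8)
            labels[s.target] = CLASS_INDEX[s.minority_class]
            pairs.append(TrainingPair(s.image.pixels, labels, s.cube_id,
                                      "twoclass"))
    return pairs


def build_network(config: TrainConfig) -> nn.EncoderDecoder:
    """Untrained network for a config: 1x1 input adapter, encoder-decoder
    at the configured scale, 3-class softmax head."""
    base, stages = nn.SCALE_PRESETS[config.backbone_scale]
    if config.base_channels is not None:
        base = config.base_channels
    return nn.EncoderDecoder(architecture=config.architecture,
                             base_channels=base, n_stages=stages,
                             n_classes=config.n_classes, seed=config.seed)


# ---------------------------------------------------------------------------
# Model / Results


class SegmentationModel:
    """Plexus segmenter specified by data and configuration; ``fit()``
    trains it and returns a :class:`SegmentationResults`.

    ``patient_of_cube`` plus ``split`` enable the hard patient-level
    leakage check: training (or validation) cubes whose patient is not in
    the expected split group abort the fit.
    """

    def __init__(self, train_pairs: list[TrainingPair],
                 val_pairs: list[TrainingPair] | None = None,
                 config: TrainConfig | None = None,
                 *, patient_of_cube: dict[str, str] | None = None,
                 split=None):
        if not train_pairs:
            raise ValueError("no training pairs")
        self.config = config or TrainConfig()
        self.train_pairs = train_pairs
        self.val_pairs = val_pairs or []
        if split is not None and patient_of_cube is not None:
            self._check_leakage(split, patient_of_cube)

    def _check_leakage(self, split, patient_of_cube) -> None:
        for pairs, group in ((self.train_pairs, "train"),
                             (self.val_pairs, "val")):
            for p in pairs:
                patient = patient_of_cube[p.cube_id]
                if split.group_of(patient) != group:
                    raise RuntimeError(
                        f"patient-level leakage: cube {p.cube_id} "
                        f"(patient {patient}, group "
                        f"{split.group_of(patient)}) used as {group} data")

    def _stack(self, pairs: list[TrainingPair]):
        size = self.config.input_size
        xs = np.stack([resize_for_model(p.image, size) for p in pairs])
        ys = np.stack([resize_mask(p.labels, size) for p in pairs])
        return xs.astype(np.float32) / 255.0, ys.astype(np.int64)

    def fit(self, seed: int | None = None, verbose: bool = False
            ) -> "SegmentationResults":
        """Train with mini-batch Adam on categorical cross-entropy.

        ``seed`` overrides ``config.seed`` and drives initialization,
        shuffling and augmentation; a given seed reproduces the identical
        history.  The returned results carry the best-validation-loss
        weights (final weights when no validation data was given).
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        rng = np.random.default_rng(cfg.seed)
        net = build_network(cfg)
        opt = nn.Adam(net, lr=cfg.max_learning_rate)
        x_train, y_train = self._stack(self.train_pairs)
        x_val, y_val = (self._stack(self.val_pairs) if self.val_pairs
                        else (None, None))
        n = len(x_train)
        steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
        total_steps = cfg.epochs * steps_per_epoch
        history: list[dict] = []
        best = (np.inf, net.get_weights(), 0)
        t0 = time.time()
        step = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(steps_per_epoch):
                idx = order[s * cfg.batch_size:(s + 1) * cfg.batch_size]
                xb = x_train[idx]
                yb = y_train[idx]
                if cfg.augment:
                    xb = xb.copy()
                    yb = yb.copy()
                    for k in range(len(idx)):
                        xb[k], yb[k] = augment(xb[k], yb[k], rng)
                loss, dlogits = nn.cross_entropy(
                    net.forward(xb[..., None], train=True), yb)
                net.zero_grad()
                net.backward(dlogits.astype(np.float32))
                opt.step(lr=_lr_at(cfg, step, total_steps))
                losses.append(loss)
                step += 1
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if x_val is not None and (
                    epoch % cfg.val_interval == cfg.val_interval - 1
                    or epoch == cfg.epochs - 1):
                logits = net.forward(x_val[..., None], train=False)
                vloss, _ = nn.cross_entropy(logits, y_val)
                rec["val_loss"] = vloss
                pred = logits.argmax(axis=-1)
                for cname, ci in CLASS_INDEX.items():
                    scores = [_dice_arrays(p == ci, t == ci)
                              for p, t in zip(pred, y_val)
                              if (t == ci).any()]
                    if scores:
                        rec[f"val_dice_{cname}"] = float(np.mean(scores))
                if vloss < best[0]:
                    best = (vloss, net.get_weights(), epoch)
            history.append(rec)
            if verbose and epoch % 10 == 0:
                logger.info("epoch %d: %s", epoch, rec)
        if x_val is not None and np.isfinite(best[0]):
            net.set_weights(best[1])
            best_epoch = best[2]
        else:
            best_epoch = cfg.epochs - 1
        return SegmentationResults(
            network=net, config=cfg,
            history=pd.DataFrame(history), best_epoch=best_epoch,
            train_seconds=time.time() - t0,
            n_train=len(self.train_pairs), n_val=len(self.val_pairs))


class SegmentationResults:
    """A fitted plexus segmenter: weights, history, prediction methods."""

    def __init__(self, network: nn.EncoderDecoder, config: TrainConfig,
                 history: pd.DataFrame, best_epoch: int,
                 train_seconds: float, n_train: int, n_val: int):
        self.network = network
        self.config = config
        self.history = history
        self.best_epoch = best_epoch
        self.train_seconds = train_seconds
        self.n_train = n_train
        self.n_val = n_val

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, images) -> np.ndarray:
        """Per-pixel class distributions (N, H, W, 3) at the images' own
        resolution (predictions made at the model input size and mapped
        back by nearest neighbor)."""
        arrs = [img.pixels if isinstance(img, EnFaceImage) else np.asarray(img)
                for img in images]
        size = self.config.input_size
        batch = np.stack([resize_for_model(a, size) for a in arrs])
        batch = batch.astype(np.float32) / 255.0
        probs = self.network.predict_proba(batch[..., None])
        out = []
        for a, p in zip(arrs, probs):
            if a.shape != (size, size):
                p = upsample_nearest(p, a.shape[0])
            out.append(p)
        return np.stack(out)

    def predict_labels(self, images) -> np.ndarray:
        """Argmax class map per image (ties resolve to the lower index,
        i.e. the anatomically shallower class)."""
        return self.predict_proba(images).argmax(axis=-1)

    # -- reporting ----------------------------------------------------------

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Plexus Segmentation Results",
            "=" * 46,
            f"{'architecture':<28}{cfg.architecture}",
            f"{'backbone scale':<28}{cfg.backbone_scale}",
            f"{'parameters':<28}{self.network.n_params}",
            f"{'dataset mix':<28}{cfg.dataset_mix}",
            f"{'train / val images':<28}{self.n_train} / {self.n_val}",
            f"{'epochs':<28}{cfg.epochs}",
            f"{'batch size':<28}{cfg.batch_size}",
            f"{'max learning rate':<28}{cfg.max_learning_rate:g}",
            f"{'seed':<28}{cfg.seed}",
            f"{'final training loss':<28}{self.final_loss:.4f}",
        ]
        if "val_loss" in self.history:
            vl = self.history["val_loss"].dropna()
            if len(vl):
                lines.append(f"{'best validation loss':<28}{vl.min():.4f} "
                             f"(epoch {self.best_epoch})")
        lines.append(f"{'training time':<28}{self.train_seconds:.1f} s")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint as .npz weights plus a JSON metadata sidecar."""
        import pathlib
        path = pathlib.Path(path)
        weights = self.network.get_weights()
        np.savez_compressed(path.with_suffix(".npz"),
                            **{f"w{i}": w for i, w in enumerate(weights)})
        meta = {
            "config": asdict(self.config), "best_epoch": self.best_epoch,
            "train_seconds": self.train_seconds, "n_train": self.n_train,
            "n_val": self.n_val,
            "history": self.history.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path) -> "SegmentationResults":
        import pathlib
        path = pathlib.Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = TrainConfig(**meta["config"])
        net = build_network(cfg)
        with np.load(path.with_suffix(".npz")) as z:
            net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
        return cls(network=net, config=cfg,
                   history=pd.DataFrame(meta["history"]),
                   best_epoch=meta["best_epoch"],
                   train_seconds=meta["train_seconds"],
                   n_train=meta["n_train"], n_val=meta["n_val"])


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    return 1.0 if denom == 0 else 2.0 * int((a & b).sum()) / denom


def _lr_at(cfg: TrainConfig, step: int, total_steps: int) -> float:
    if cfg.lr_schedule == "constant":
        return cfg.max_learning_rate
    # one-cycle: linear warmup over the first 30%, cosine decay after
    warm = max(1, int(0.3 * total_steps))
    if step < warm:
        return cfg.max_learning_rate * (step + 1) / warm
    frac = (step - warm) / max(1, total_steps - warm)
    return cfg.max_learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
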