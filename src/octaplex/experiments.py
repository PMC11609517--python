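"""End-to-end phantom study: cohort -> datasets -> split -> train -> Dice.

This is the desk-scale reproduction protocol.  A seeded phantom cohort is
generated, single-class and synthetic two-class datasets are built from
it, patients are split 60/20/20 into train/validation/test, a tiny
encoder-decoder is trained on the chosen dataset mix, and the fitted model
is scored on the reserved test images of both kinds.  Default problem
sizes (15 patients, 64-px en face images, 96 depth voxels, 300 epochs of
the addition-merge tiny network at batch 32 and max learning rate 1e-4
under a one-cycle schedule) keep a full study on one CPU in the minutes
range.  Raw (non-normalized) images form the training mix, with normalized
copies exercised by the dataset-construction ops, and geometric
augmentation is off at this scale: the synthetic data is already abundant,
and rotation resampling blurs 64-px textures enough to cost boundary
localization (see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blending import TwoClassSample, build_twoclass_dataset
from .enface import EnFaceImage, build_single_class_dataset
from .metrics import DiceReport, evaluate_model
from .model import (SegmentationModel, SegmentationResults, TrainConfig,
                    TrainingPair, as_training_pairs)
from .phantoms import PhantomCohort, generate_cohort
from .splits import SplitManifest, check_no_leakage, split_patients

logger = logging.getLogger(__name__)

DEFAULT_DIMS = (64, 64, 96)
DEFAULT_N_PATIENTS = 15


@dataclass
class StudyData:
    """Cohort, split, and grouped training/evaluation pairs."""

    cohort: PhantomCohort
    split: SplitManifest
    single_images: list[EnFaceImage]
    twoclass_samples: list[TwoClassSample]
    train_single: list[EnFaceImage]
    train_twoclass: list[TwoClassSample]
    val_single: list[EnFaceImage]
    val_twoclass: list[TwoClassSample]
    test_single: list[TrainingPair]
    test_twoclass: list[TrainingPair]


def _split_targets(n_patients: int) -> tuple[int, int, int]:
    """60/20/20 patient split (validation and test at least one patient)."""
    n_val = max(1, round(0.2 * n_patients))
    n_test = max(1, round(0.2 * n_patients))
    return n_patients - n_val - n_test, n_val, n_test


def build_study_data(
    cohort_seed: int = 42,
    *,
    n_patients: int = DEFAULT_N_PATIENTS,
    cubes_per_patient_range: tuple[int, int] = (1, 2),
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    split_targets: tuple[int, int, int] | None = None,
) -> StudyData:
    """Generate the phantom cohort and all derived datasets for one study."""
    cohort = generate_cohort(n_patients, cubes_per_patient_range, dims,
                             cohort_seed)
    split = split_patients(cohort, split_targets or _split_targets(n_patients),
                           seed=cohort_seed)
    singles = build_single_class_dataset(cohort, include_normalized=False)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cohort_seed, spawn_key=(7,)))
    twos = build_twoclass_dataset(singles, rng, include_normalized=False)

    patient_of_cube = cohort.patient_of_cube()
    group_of_cube = {c: split.group_of(p) for c, p in patient_of_cube.items()}

    def pick(items, group):
        return [x for x in items if group_of_cube[x.cube_id] == group]

    data = StudyData(
        cohort=cohort, split=split,
        single_images=singles, twoclass_samples=twos,
        train_single=pick(singles, "train"),
        train_twoclass=pick(twos, "train"),
        val_single=pick(singles, "val"),
        val_twoclass=pick(twos, "val"),
        test_single=as_training_pairs(
            single_class=pick(singles, "test"), dataset_mix="single"),
        test_twoclass=as_training_pairs(
            twoclass=pick(twos, "test"), dataset_mix="twoclass"),
    )
    check_no_leakage(
        split, patient_of_cube,
        [p.cube_id for p in data.train_single + data.train_twoclass],
        [p.cube_id for p in data.test_single + data.test_twoclass])
    return data


def train_on_study(
    data: StudyData,
    dataset_mix: str,
    train_seed: int,
    *,
    epochs: int = 300,
    architecture: str = "linknet_like",
    base_channels: int | None = 6,
    lr_schedule: str = "one_cycle",
    augment: bool = False,
    input_size: int | None = None,
) -> SegmentationResults:
    """Fit the tiny segmenter on one dataset mix of a study."""
    size = input_size or data.single_images[0].shape[0]
    config = TrainConfig(input_size=size, epochs=epochs,
                         architecture=architecture, backbone_scale="tiny",
                         base_channels=base_channels, lr_schedule=lr_schedule,
                         augment=augment, val_interval=25,
                         dataset_mix=dataset_mix, seed=train_seed)
    train_pairs = as_training_pairs(data.train_single, data.train_twoclass,
                                    dataset_mix)
    val_pairs = as_training_pairs(data.val_single, data.val_twoclass,
                                  dataset_mix)
    model = SegmentationModel(train_pairs, val_pairs, config,
                              patient_of_cube=data.cohort.patient_of_cube(),
                              split=data.split)
    return model.fit()


def run_dice_study(
    dataset_mix: str,
    cohort_seed: int = 42,
    train_seed: int = 0,
    *,
    epochs: int = 300,
    architecture: str = "linknet_like",
    data: StudyData | None = None,
) -> DiceReport:
    """One full train-and-evaluate pass; returns the Dice report."""
    if data is None:
        data = build_study_data(cohort_seed)
    results = train_on_study(data, dataset_mix, train_seed, epochs=epochs,
                             architecture=architecture)
    return evaluate_model(results, data.test_single, data.test_twoclass,
                          model_tag=architecture)
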