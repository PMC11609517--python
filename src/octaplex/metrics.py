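"""Dice evaluation in the layout of the study's score table.

A fitted model is evaluated separately on single-class and synthetic
two-class reserved test images.  Per image, the multiclass argmax
prediction is split one-vs-rest per class and scored with the Dice overlap
against the ground-truth mask.  A class is scored on an image only when it
is present in that image's ground truth: stray predicted pixels of an
absent class lower the present classes' overlap (their pixels are missing
from the correct mask) rather than contributing a hard zero for the absent
class — the convention consistent with published per-class scores on
single-class test sets, where each image's truth contains one class.  The
degenerate empty-vs-empty comparison is defined as 1.0.  Per-class scores
average uniformly over images; the per-kind average is the mean of the
three class means, and the combined simple average is the mean of the two
per-kind averages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CLASS_INDEX, SegmentationResults, TrainingPair
from .phantoms import PLEXUS_CLASSES

logger = logging.getLogger(__name__)


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class DiceReport:
    """Per-class and averaged Dice scores for the two test-set kinds."""

    single_class: dict[str, float]
    twoclass: dict[str, float]
    single_class_average: float
    twoclass_average: float
    combined_simple_average: float
    model_tag: str = ""
    dataset_mix: str = ""
    n_single: int = 0
    n_twoclass: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, scores, avg in (
                ("single_class", self.single_class, self.single_class_average),
                ("twoclass", self.twoclass, self.twoclass_average)):
            row = {"test_set": kind, **scores, "average": avg}
            rows.append(row)
        df = pd.DataFrame(rows)
        df["combined_simple_average"] = self.combined_simple_average
        df["model"] = self.model_tag
        df["dataset_mix"] = self.dataset_mix
        return df

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "single_class", "twoclass", "single_class_average",
            "twoclass_average", "combined_simple_average", "model_tag",
            "dataset_mix", "n_single", "n_twoclass")}
        return json.dumps(d, indent=2, sort_keys=True)

    def __str__(self) -> str:
        def fmt(scores, avg):
            cells = "  ".join(f"{scores.get(c, float('nan')):.4f}"
                              for c in PLEXUS_CLASSES)
            return f"{cells}  | avg {avg:.4f}"
        return (
            f"Dice report [{self.model_tag} / {self.dataset_mix}]\n"
            f"  classes: {'  '.join(PLEXUS_CLASSES)}\n"
            f"  single-class tests (n={self.n_single}):  "
            f"{fmt(self.single_class, self.single_class_average)}\n"
            f"  two-class tests    (n={self.n_twoclass}):  "
            f"{fmt(self.twoclass, self.twoclass_average)}\n"
            f"  combined simple average: {self.combined_simple_average:.4f}")


def _per_class_scores(results: SegmentationResults,
                      pairs: list[TrainingPair]) -> dict[str, float]:
    per_class: dict[str, list[float]] = {c: [] for c in PLEXUS_CLASSES}
    preds = results.predict_labels([p.image for p in pairs])
    for p, pred in zip(pairs, preds):
        truth = p.labels
        for cname, ci in CLASS_INDEX.items():
            if not (truth == ci).any():
                continue  # class not in this image's truth: not scored here
            per_class[cname].append(dice(pred == ci, truth == ci))
    return {c: float(np.mean(v)) for c, v in per_class.items() if v}


def evaluate_model(results: SegmentationResults,
                   single_tests: list[TrainingPair],
                   twoclass_tests: list[TrainingPair],
                   *, model_tag: str = "") -> DiceReport:
    """Score a fitted model on the two reserved test-image kinds."""
    if not single_tests and not twoclass_tests:
        raise ValueError("no test images supplied")
    single = _per_class_scores(results, single_tests) if single_tests else {}
    two = _per_class_scores(results, twoclass_tests) if twoclass_tests else {}
    s_avg = float(np.mean(list(single.values()))) if single else float("nan")
    t_avg = float(np.mean(list(two.values()))) if two else float("nan")
    parts = [a for a in (s_avg, t_avg) if np.isfinite(a)]
    combined = float(np.mean(parts)) if parts else float("nan")
    report = DiceReport(
        single_class=single, twoclass=two,
        single_class_average=s_avg, twoclass_average=t_avg,
        combined_simple_average=combined,
        model_tag=model_tag or results.config.architecture,
        dataset_mix=results.config.dataset_mix,
        n_single=len(single_tests), n_twoclass=len(twoclass_tests))
    logger.info("evaluation: %s", report)
    return report
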