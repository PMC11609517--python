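"""Patient-level dataset partitioning.

Cubes are split into training / validation / reserved-test groups at the
patient level: every patient's cubes land in exactly one group, so no eye
ever contributes to both training and evaluation.  Balance criteria — both
eyes represented per group, healthy and diseased patients per group, and
cube-rich patients spread across groups — are met by seeded constrained
randomization (largest-cube-count patients placed first, round-robin).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .phantoms import PhantomCohort

logger = logging.getLogger(__name__)

GROUPS = ("train", "val", "test")

#: Training patients are tagged into this many sub-groups (kept in the
#: manifest for completeness; training consumes their union).
N_TRAIN_SUBGROUPS = 4


class SplitInfeasibleError(ValueError):
    """Raised when the requested split constraints cannot be satisfied."""


@dataclass
class SplitManifest:
    """Patient -> group assignment plus per-group composition summaries."""

    assignment: dict[str, str]
    cube_counts: dict[str, int]
    eye_counts: dict[str, dict[str, int]]
    health_counts: dict[str, dict[str, int]]
    train_subgroup: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        for pid, grp in self.assignment.items():
            if grp not in GROUPS:
                raise ValueError(f"patient {pid} assigned to unknown group {grp!r}")

    def patients(self, group: str) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g == group)

    def group_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def to_json(self) -> str:
        return json.dumps({
            "assignment": self.assignment,
            "cube_counts": self.cube_counts,
            "eye_counts": self.eye_counts,
            "health_counts": self.health_counts,
            "train_subgroup": self.train_subgroup,
            "seed": self.seed,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        return cls(assignment=d["assignment"], cube_counts=d["cube_counts"],
                   eye_counts=d["eye_counts"], health_counts=d["health_counts"],
                   train_subgroup={k: int(v) for k, v in d["train_subgroup"].items()},
                   seed=int(d["seed"]))


def _group_stats(cohort: PhantomCohort, assignment: dict[str, str]):
    cube_counts = {g: 0 for g in GROUPS}
    eye_counts = {g: {"OD": 0, "OS": 0} for g in GROUPS}
    health = {g: {"healthy": 0, "diseased": 0} for g in GROUPS}
    for p in cohort.patients:
        g = assignment[p.patient_id]
        health[g]["diseased" if p.disease_flag else "healthy"] += 1
        for eye, n in p.cube_counts.items():
            cube_counts[g] += n
            eye_counts[g][eye] += n
    return cube_counts, eye_counts, health


def _balance_feasible(cohort: PhantomCohort, targets) -> dict[str, bool]:
    """Which balance constraints can this cohort/targets combination meet?"""
    n_od_patients = sum(1 for p in cohort.patients if p.cube_counts.get("OD", 0))
    n_os_patients = sum(1 for p in cohort.patients if p.cube_counts.get("OS", 0))
    n_healthy = sum(1 for p in cohort.patients if not p.disease_flag)
    n_diseased = sum(1 for p in cohort.patients if p.disease_flag)
    return {
        "eyes": n_od_patients >= 3 and n_os_patients >= 3,
        "health": (n_healthy >= 3 and n_diseased >= 3
                   and all(t >= 2 for t in targets)),
    }


def split_patients(
    cohort: PhantomCohort,
    group_patient_targets: tuple[int, int, int],
    seed: int,
    *,
    require_balance: bool | str = "auto",
    max_restarts: int = 500,
) -> SplitManifest:
    """Seeded constrained randomization of patients into train/val/test.

    ``group_patient_targets`` fixes the patient count per group (the study
    design used 21/6/6).  Patients are ordered by descending cube count and
    dealt round-robin with seeded tie shuffling, which spreads cube-rich
    patients across groups; assignments violating eye or health balance are
    redrawn.  ``require_balance='auto'`` enforces each balance constraint
    only when the cohort can satisfy it; ``True`` makes infeasibility an
    error; ``False`` skips the balance checks.
    """
    targets = tuple(int(t) for t in group_patient_targets)
    if len(targets) != 3 or any(t < 1 for t in targets):
        raise SplitInfeasibleError(f"invalid group targets {targets}")
    if sum(targets) != len(cohort.patients):
        raise SplitInfeasibleError(
            f"targets {targets} sum to {sum(targets)} but the cohort has "
            f"{len(cohort.patients)} patients")

    feasible = _balance_feasible(cohort, targets)
    if require_balance is True:
        for name, ok in feasible.items():
            if not ok:
                raise SplitInfeasibleError(
                    f"balance constraint '{name}' unsatisfiable: the cohort "
                    f"cannot give every group both categories")
        check = {"eyes": True, "health": True}
    elif require_balance == "auto":
        check = feasible
    else:
        check = {"eyes": False, "health": False}

    rng = np.random.default_rng(seed)
    total_cubes = {p.patient_id: sum(p.cube_counts.values())
                   for p in cohort.patients}

    # 'auto' relaxes constraints progressively if the randomization cannot
    # satisfy them (the a-priori feasibility screen is necessary, not
    # sufficient, for small cohorts)
    attempts = [check]
    if require_balance != True:  # noqa: E712  (tri-state option)
        if check["eyes"]:
            attempts.append({**check, "eyes": False})
        if check["health"]:
            attempts.append({"eyes": False, "health": False})

    last_violation = "no assignment attempted"
    for attempt_no, check in enumerate(attempts):
        if attempt_no > 0:
            logger.warning("split: relaxing balance constraints to %s after "
                           "exhausted restarts (%s)", check, last_violation)
        manifest = _try_assign(cohort, targets, rng, check, total_cubes,
                               max_restarts, seed)
        if manifest is not None:
            return manifest
        last_violation = _LAST_VIOLATION[0]
    raise SplitInfeasibleError(
        f"no assignment satisfying the balance constraints found in "
        f"{max_restarts} restarts; last violation: {last_violation}")


_LAST_VIOLATION = ["none"]


def _try_assign(cohort, targets, rng, check, total_cubes, max_restarts, seed):
    for _ in range(max_restarts):
        order = list(cohort.patient_ids)
        rng.shuffle(order)
        order.sort(key=lambda pid: -total_cubes[pid])  # stable: ties shuffled
        slots = {g: t for g, t in zip(GROUPS, targets)}
        assignment: dict[str, str] = {}
        groups_cycle = [g for g in GROUPS]
        i = 0
        for pid in order:
            for _ in range(len(GROUPS)):
                g = groups_cycle[i % len(GROUPS)]
                i += 1
                if slots[g] > 0:
                    assignment[pid] = g
                    slots[g] -= 1
                    break
        cube_counts, eye_counts, health = _group_stats(cohort, assignment)
        ok = True
        if check["eyes"]:
            for g in GROUPS:
                if eye_counts[g]["OD"] < 1 or eye_counts[g]["OS"] < 1:
                    ok = False
                    _LAST_VIOLATION[0] = f"group {g} missing an eye"
        if ok and check["health"]:
            for g in GROUPS:
                if min(health[g].values()) < 1:
                    ok = False
                    _LAST_VIOLATION[0] = (
                        f"group {g} missing a healthy or diseased patient")
        if ok:
            train_patients = [p for p in order if assignment[p] == "train"]
            subgroup = {pid: (k % N_TRAIN_SUBGROUPS) + 1
                        for k, pid in enumerate(train_patients)}
            logger.info("split (seed=%d): cubes per group %s", seed, cube_counts)
            return SplitManifest(assignment=assignment, cube_counts=cube_counts,
                                 eye_counts=eye_counts, health_counts=health,
                                 train_subgroup=subgroup, seed=seed)
    return None


def check_no_leakage(manifest: SplitManifest,
                     patient_of_cube: dict[str, str],
                     train_cube_ids, eval_cube_ids) -> None:
    """Raise if any evaluation cube shares a patient with a training cube."""
    train_patients = {patient_of_cube[c] for c in train_cube_ids}
    for c in eval_cube_ids:
        p = patient_of_cube[c]
        if p in train_patients:
            raise RuntimeError(
                f"patient-level leakage: cube {c} of patient {p} appears on "
                f"both sides of the split")
    for c in train_cube_ids:
        if manifest.group_of(patient_of_cube[c]) != "train":
            raise RuntimeError(
                f"cube {c} used for training but its patient is assigned to "
                f"{manifest.group_of(patient_of_cube[c])}")
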