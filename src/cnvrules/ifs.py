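"""Incremental feature selection over an mRMR-ranked feature list.

Stage 1 evaluates nested prefixes of the ranked list on a coarse grid
(step 10, i.e. top 10, top 20, ...) by cross-validated multiclass MCC.
From that curve the highest point (max MCC, smallest k among ties) and a
turning point (smallest k within ``delta`` of the max) are read off; stage
2 rescans [1, turning point rounded up to the next coarse-grid boundary]
at step 1, and its highest point is the final optimum.

Fold assignment is computed once per dataset + seed and reused at every
subset size, so curve differences reflect feature content only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dataio import LabeledDataset
from .evalcore import SubsetEvaluation, cross_validate, stratified_kfold
from .relevance import RankedFeatures

__all__ = [
    "IFSCurve",
    "TwoStageIFSReport",
    "ifs_scan",
    "find_highest_point",
    "find_turning_point",
    "find_knee_point",
    "two_stage_ifs",
]


@dataclass
class IFSCurve:
    """Ordered subset evaluations at strictly increasing subset sizes."""

    evaluations: list[SubsetEvaluation]
    step: int
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        ks = self.ks
        if len(ks) == 0:
            raise ValueError("empty IFS curve")
        if np.any(np.diff(ks) <= 0):
            raise ValueError("subset sizes must be strictly increasing")

    @property
    def ks(self) -> np.ndarray:
        return np.array([e.subset_size for e in self.evaluations])

    @property
    def mccs(self) -> np.ndarray:
        return np.array([e.mcc for e in self.evaluations])

    def to_dataframe(self) -> pd.DataFrame:
        accs = np.vstack([e.class_accuracy for e in self.evaluations])
        df = pd.DataFrame({"k": self.ks, "mcc": self.mccs})
        for i in range(accs.shape[1]):
            df[f"class{i}_accuracy"] = accs[:, i]
        return df


def _grid(interval: tuple[int, int], step: int) -> list[int]:
    lo, hi = interval
    if step < 1 or lo < 1 or hi < lo:
        raise ValueError(f"invalid grid: interval {interval}, step {step}")
    start = step * math.ceil(lo / step)
    ks = list(range(start, hi + 1, step))
    if not ks:
        # step exceeds the interval: evaluate its upper end once
        ks = [hi]
    return ks


def ifs_scan(
    dataset: LabeledDataset,
    ranked: RankedFeatures,
    interval: tuple[int, int] | None = None,
    step: int = 10,
    classifier: str = "svm",
    smote_policy: str = "train_folds_only",
    seed: int = 0,
    cv_k: int = 10,
    n_jobs: int = 1,
    ripper_config=None,
) -> IFSCurve:
    """Evaluate top-k prefixes of the ranked list on a k grid."""
    if interval is None:
        interval = (1, len(ranked))
    if interval[1] > len(ranked):
        raise ValueError(
            f"interval {interval} exceeds ranked list length {len(ranked)}"
        )
    ks = _grid(interval, step)
    folds = None
    if smote_policy != "before_split":
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            folds = stratified_kfold(dataset.y, k=cv_k, seed=seed)

    def _one(k: int) -> SubsetEvaluation:
        return cross_validate(
            dataset,
            ranked.top(k),
            classifier=classifier,
            smote_policy=smote_policy,
            k=cv_k,
            seed=seed,
            folds=folds,
            ripper_config=ripper_config,
        )

    if n_jobs == 1:
        evals = [_one(k) for k in ks]
    else:
        evals = Parallel(n_jobs=n_jobs)(delayed(_one)(k) for k in ks)
    return IFSCurve(list(evals), step, tuple(interval))


def find_highest_point(curve: IFSCurve) -> tuple[int, float]:
    """(k*, MCC*): maximal MCC, smallest k among ties."""
    mccs = curve.mccs
    i = int(np.argmax(mccs))  # argmax returns the first max -> smallest k
    return int(curve.ks[i]), float(mccs[i])


def find_turning_point(curve: IFSCurve, delta: float = 0.05) -> tuple[int, float]:
    """Smallest grid k whose MCC is within ``delta`` of the maximum."""
    _, best = find_highest_point(curve)
    for e in curve.evaluations:
        if e.mcc >= best - delta:
            return e.subset_size, float(e.mcc)
    raise AssertionError("unreachable: the highest point always qualifies")


def find_knee_point(curve: IFSCurve) -> tuple[int, float]:
    """Alternative turning-point strategy: maximum chord distance.

    The point furthest above the straight line joining the curve's first
    and last grid points; a geometric "knee" detector for curves that rise
    steeply then plateau. Falls back to the highest point on curves with a
    single grid point.
    """
    ks = curve.ks.astype(float)
    mccs = curve.mccs
    if len(ks) < 3:
        return find_highest_point(curve)
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = mccs - (mccs[0] + x * (mccs[-1] - mccs[0]))
    i = int(np.argmax(y))
    return int(curve.ks[i]), float(mccs[i])


@dataclass
class TwoStageIFSReport:
    """Both IFS curves with the selected points and run settings."""

    stage1: IFSCurve
    stage1_highest: tuple[int, float]
    turning_point: tuple[int, float]
    stage2: IFSCurve
    optimum: tuple[int, float]
    optimal_features: list[str]
    classifier: str
    smote_policy: str
    seed: int
    delta: float
    stage1_step: int

    def summary_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "stage1_highest_mcc": self.stage1_highest[1],
            "stage1_highest_k": self.stage1_highest[0],
            "turning_mcc": self.turning_point[1],
            "turning_k": self.turning_point[0],
            "stage2_optimum_mcc": self.optimum[1],
            "stage2_optimum_k": self.optimum[0],
        }


def two_stage_ifs(
    dataset: LabeledDataset,
    ranked: RankedFeatures,
    classifier: str = "svm",
    smote_policy: str = "train_folds_only",
    stage1_step: int = 10,
    delta: float = 0.05,
    seed: int = 0,
    cv_k: int = 10,
    n_jobs: int = 1,
    ripper_config=None,
) -> TwoStageIFSReport:
    """Coarse scan, turning point, fine rescan, final optimum."""
    if len(ranked) == 0:
        raise ValueError("ranked feature list is empty")
    stage1 = ifs_scan(
        dataset, ranked, (1, len(ranked)), stage1_step, classifier, smote_policy,
        seed, cv_k, n_jobs, ripper_config,
    )
    highest = find_highest_point(stage1)
    turning = find_turning_point(stage1, delta)
    # fine interval: turning point rounded up to the next coarse boundary
    hi = min(stage1_step * math.ceil(turning[0] / stage1_step), len(ranked))
    stage2 = ifs_scan(
        dataset, ranked, (1, hi), 1, classifier, smote_policy, seed, cv_k, n_jobs,
        ripper_config,
    )
    optimum = find_highest_point(stage2)
    return TwoStageIFSReport(
        stage1=stage1,
        stage1_highest=highest,
        turning_point=turning,
        stage2=stage2,
        optimum=optimum,
        optimal_features=ranked.top(optimum[0]),
        classifier=classifier,
        smote_policy=smote_policy,
        seed=seed,
        delta=delta,
        stage1_step=stage1_step,
    )
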