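"""Feature relevance: discretization, mutual information, MI filtering, mRMR.

The selection pipeline's first two stages. Continuous signals are
discretized per feature into three bins around mean +/- alpha*sd, feature
importance is the plug-in mutual information (in bits) between the binned
feature and the class label, features at or below an MI threshold are
discarded, and survivors are greedily ranked by the
minimum-redundancy-maximum-relevance criterion (difference form MID by
default, quotient form MIQ available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import LabeledDataset

__all__ = [
    "DiscretizationScheme",
    "RankedFeatures",
    "discretize",
    "mutual_information",
    "feature_mi",
    "mi_filter",
    "mrmr_rank",
]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Three-bin discretization: below mean - alpha*sd, within, above mean + alpha*sd."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def discretize(values: Sequence[float], scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Bin a real vector into {-1, 0, +1} around its own mean +/- alpha*sd.

    A constant vector (sd = 0) falls entirely into the middle bin.
    """
    scheme = scheme or DiscretizationScheme()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    mu = x.mean()
    sd = x.std()
    out = np.zeros(x.shape, dtype=np.int8)
    out[x < mu - scheme.alpha * sd] = -1
    out[x > mu + scheme.alpha * sd] = 1
    return out


def _encode(x: np.ndarray) -> tuple[np.ndarray, int]:
    levels, inv = np.unique(x, return_inverse=True)
    return inv, len(levels)


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information in bits between two categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be non-empty 1-D vectors of equal length")
    xi, nx = _encode(x)
    yi, ny = _encode(y)
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])))
    return max(mi, 0.0)  # clip float round-off below zero


def feature_mi(
    dataset: LabeledDataset, scheme: DiscretizationScheme | None = None
) -> pd.Series:
    """MI (bits) of every discretized feature against the class label,
    in panel order."""
    scheme = scheme or DiscretizationScheme()
    yi, _ = _encode(dataset.y)
    mis = np.empty(dataset.n_features)
    for j in range(dataset.n_features):
        mis[j] = mutual_information(discretize(dataset.signal.values[:, j], scheme), yi)
    return pd.Series(mis, index=dataset.signal.marker_ids, name="mi_bits")


def mi_filter(
    dataset: LabeledDataset,
    scheme: DiscretizationScheme | None = None,
    threshold: float = 0.01,
) -> pd.Series:
    """Keep features whose label MI is strictly greater than ``threshold``.

    Returns the surviving features' MI values in panel order; emits a
    warning (and returns an empty series) when nothing survives, which
    halts the downstream pipeline.
    """
    mis = feature_mi(dataset, scheme)
    survivors = mis[mis > threshold]
    if survivors.empty:
        warnings.warn(
            f"no features exceed the MI threshold {threshold}; selection cannot proceed",
            RuntimeWarning,
            stacklevel=2,
        )
    return survivors


@dataclass
class RankedFeatures:
    """mRMR-ordered marker ids with their relevance and selection-time score."""

    marker_ids: list[str]
    relevance: np.ndarray  # MI(feature; label) in bits, in rank order
    scores: np.ndarray  # mRMR criterion value at the step the feature was picked
    variant: str = "MID"

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids in ranking")
        self.relevance = np.asarray(self.relevance, float)
        self.scores = np.asarray(self.scores, float)

    def __len__(self) -> int:
        return len(self.marker_ids)

    def top(self, k: int) -> list[str]:
        return self.marker_ids[:k]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "marker_id": self.marker_ids,
                "relevance_bits": self.relevance,
                "score": self.scores,
            }
        )


def mrmr_rank(
    dataset: LabeledDataset,
    scheme: DiscretizationScheme | None = None,
    survivors: Sequence[str] | None = None,
    variant: str = "MID",
    top_n: int | None = None,
) -> RankedFeatures:
    """Greedy minimum-redundancy-maximum-relevance ranking.

    The first feature maximizes relevance I(f; label); each later pick
    maximizes I(f; label) - mean_s I(f; s) over already-selected s (MID)
    or the quotient I(f; label) / mean_s I(f; s) (MIQ). Ties break by
    panel order. Pairwise redundancy MIs are computed lazily, one new
    column per greedy step.
    """
    if variant not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR variant {variant!r}")
    scheme = scheme or DiscretizationScheme()
    ids = list(survivors) if survivors is not None else list(dataset.signal.marker_ids)
    if not ids:
        raise ValueError("no surviving features to rank")
    if top_n is None:
        top_n = len(ids)
    elif top_n > len(ids):
        warnings.warn(
            f"top_n={top_n} exceeds {len(ids)} survivors; truncating", RuntimeWarning,
            stacklevel=2,
        )
        top_n = len(ids)

    cols = dataset.signal.column_indices(ids)
    disc = np.column_stack(
        [discretize(dataset.signal.values[:, j], scheme) for j in cols]
    )
    yi, _ = _encode(dataset.y)
    d = len(ids)
    rel = np.array([mutual_information(disc[:, j], yi) for j in range(d)])

    selected: list[int] = []
    red_sum = np.zeros(d)
    remaining = np.ones(d, dtype=bool)
    sel_scores: list[float] = []
    eps = np.finfo(float).tiny
    for _ in range(top_n):
        if not selected:
            score = rel.copy()
        else:
            red_mean = red_sum / len(selected)
            if variant == "MID":
                score = rel - red_mean
            else:
                score = rel / np.maximum(red_mean, eps)
        score = np.where(remaining, score, -np.inf)
        pick = int(np.argmax(score))  # first max -> panel-order tie-break
        selected.append(pick)
        sel_scores.append(float(score[pick]))
        remaining[pick] = False
        if len(selected) < top_n:
            new_col = disc[:, pick]
            for j in np.nonzero(remaining)[0]:
                red_sum[j] += mutual_information(disc[:, j], new_col)
    return RankedFeatures(
        [ids[j] for j in selected], rel[selected], np.array(sel_scores), variant
    )
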