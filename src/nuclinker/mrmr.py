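"""Minimum-redundancy maximum-relevance feature ranking.

Features are discretized once into three states at mean +/- t*std, the
class label is used as-is, and the greedy MID criterion (relevance minus
mean redundancy, both plug-in mutual information) orders the features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .matrix import FeatureMatrix

LOW, MID, HIGH = 0, 1, 2


def discretize(values: np.ndarray, t: float = 1.0, ddof: int = 1) -> np.ndarray:
    """Map each value to LOW / MID / HIGH at the mean +/- t*std boundaries.

    The interval [mean - t*std, mean + t*std] is closed, so boundary
    values are MID; a zero-variance feature is all MID.  ``ddof=1``
    (sample std) is the default; pass ``ddof=0`` for population std.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty feature")
    mean = values.mean()
    std = values.std(ddof=ddof) if values.size > ddof else 0.0
    states = np.full(values.shape, MID, dtype=np.int8)
    if std > 0:
        states[values < mean - t * std] = LOW
        states[values > mean + t * std] = HIGH
    return states


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    return np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """Plug-in mutual information of two discrete variables (0*log0 = 0)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("need at least one sample")
    counts = _contingency(x, y)
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    # fsum makes the result independent of term order, so MI(x, y) and
    # MI(y, x) are bit-identical
    terms = pxy[nz] * np.log(pxy[nz] / (px * py)[nz])
    mi = math.fsum(terms.tolist()) / math.log(base)
    return max(mi, 0.0)


@dataclass
class RankedFeatureList:
    """Greedy mRMR ordering plus the relevance-only (MaxRel) ordering."""

    order: list[str]
    mrmr_scores: list[float]
    relevance: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.order) != len(self.mrmr_scores):
            raise ValueError("order and scores differ in length")

    @property
    def maxrel_order(self) -> list[str]:
        names = list(self.relevance)
        rel = np.array([self.relevance[n] for n in names])
        return [names[i] for i in np.argsort(-rel, kind="stable")]

    def prefix(self, k: int) -> list[str]:
        return self.order[:k]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        mrmr = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.order,
                "score": self.mrmr_scores,
            }
        )
        maxrel = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.maxrel_order,
                "relevance": [self.relevance[n] for n in self.maxrel_order],
            }
        )
        return mrmr, maxrel

    def write_tables(self, prefix: str | Path) -> tuple[Path, Path]:
        mrmr, maxrel = self.to_frames()
        p1 = Path(f"{prefix}mrmr_list.tsv")
        p2 = Path(f"{prefix}maxrel_list.tsv")
        mrmr.to_csv(p1, sep="\t", index=False, float_format="%.6f")
        maxrel.to_csv(p2, sep="\t", index=False, float_format="%.6f")
        return p1, p2

    @classmethod
    def read_order(cls, path: str | Path) -> list[str]:
        """Feature order from a written mRMR list table."""
        df = pd.read_csv(path, sep="\t")
        return [str(f) for f in df["feature"]]


def mrmr_rank(
    matrix: FeatureMatrix, t: float = 1.0, ddof: int = 1, base: float = 2.0
) -> RankedFeatureList:
    """Greedy MID ranking of all features.

    Step 1 picks the most relevant feature; each later step picks the
    candidate maximizing relevance - mean MI with the already-selected
    set.  Ties break toward the smaller original column index.
    """
    if matrix.n_features < 1:
        raise FormatError("need at least one feature")
    labels = matrix.labels
    if len(np.unique(labels)) < 2:
        raise FormatError("both classes must be present to rank features")
    names = matrix.family_names
    nf = matrix.n_features
    states = [discretize(matrix.values[:, j], t=t, ddof=ddof) for j in range(nf)]
    relevance = np.array([mutual_information(states[j], labels, base=base) for j in range(nf)])

    pair_mi = np.full((nf, nf), np.nan)

    def redundancy(j: int, k: int) -> float:
        if np.isnan(pair_mi[j, k]):
            pair_mi[j, k] = pair_mi[k, j] = mutual_information(states[j], states[k], base=base)
        return pair_mi[j, k]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(nf))
    while remaining:
        best_j, best_score = None, -math.inf
        for j in remaining:
            if selected:
                red = sum(redundancy(j, k) for k in selected) / len(selected)
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score:
                best_j, best_score = j, score
        assert best_j is not None
        selected.append(best_j)
        scores.append(best_score)
        remaining.remove(best_j)
    return RankedFeatureList(
        order=[names[j] for j in selected],
        mrmr_scores=scores,
        relevance={names[j]: float(relevance[j]) for j in range(nf)},
    )
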