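"""Cosine-distance nearest-neighbor classification with jackknife evaluation.

Distance D(x, y) = 1 - <x, y> / (||x|| ||y||); smaller is more similar.
Zero-norm convention: D(0, y) = 1 for y != 0 and D(0, 0) = 0, keeping the
leave-one-out pass total and deterministic on all-zero rows (short linkers).
Nearest-neighbor ties break toward the smallest training index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrix import NEGATIVE_LABEL, POSITIVE_LABEL, FeatureMatrix

DEFAULT_BLOCK = 2048


@dataclass(frozen=True)
class AccuracyReport:
    n_pos: int
    n_neg: int
    correct_pos: int
    correct_neg: int

    @property
    def acc_pos(self) -> float:
        return self.correct_pos / self.n_pos if self.n_pos else float("nan")

    @property
    def acc_neg(self) -> float:
        return self.correct_neg / self.n_neg if self.n_neg else float("nan")

    @property
    def acc_overall(self) -> float:
        return (self.correct_pos + self.correct_neg) / (self.n_pos + self.n_neg)

    def to_dict(self) -> dict[str, float | int]:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "correct_pos": self.correct_pos,
            "correct_neg": self.correct_neg,
            "acc_pos": self.acc_pos,
            "acc_neg": self.acc_neg,
            "acc_overall": self.acc_overall,
        }


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx = np.sqrt(np.dot(x, x))
    ny = np.sqrt(np.dot(y, y))
    if nx == 0.0 and ny == 0.0:
        return 0.0
    if nx == 0.0 or ny == 0.0:
        return 1.0
    return 1.0 - np.dot(x, y) / (nx * ny)


def _distance_block(Xq: np.ndarray, X: np.ndarray, nq: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Pairwise D for a block of queries against all rows, zero-norm rules applied."""
    qz = nq == 0.0
    z = n == 0.0
    denom = np.outer(np.where(qz, 1.0, nq), np.where(z, 1.0, n))
    D = 1.0 - (Xq @ X.T) / denom
    if qz.any() or z.any():
        D[qz, :] = 1.0
        D[:, z] = 1.0
        if qz.any() and z.any():
            D[np.ix_(qz, z)] = 0.0
    return D


def predict(
    train: FeatureMatrix,
    query: np.ndarray,
    features: Sequence[str] | None = None,
) -> int:
    """Label of the nearest training sample over the restricted columns."""
    idx = train.feature_indices(features)
    if idx.size == 0:
        raise ValueError("empty feature subset")
    X = train.values[:, idx]
    q = np.asarray(query, dtype=float).reshape(1, -1)
    if q.shape[1] == train.n_features and len(idx) != train.n_features:
        q = q[:, idx]
    if q.shape[1] != len(idx):
        raise ValueError(f"query has {q.shape[1]} values, expected {len(idx)}")
    norms = np.sqrt(np.einsum("ij,ij->i", X, X))
    D = _distance_block(q, X, np.sqrt(np.einsum("ij,ij->i", q, q)), norms)[0]
    return int(train.labels[int(np.argmin(D))])


def jackknife_predictions(
    matrix: FeatureMatrix,
    features: Sequence[str] | None = None,
    block_size: int = DEFAULT_BLOCK,
) -> np.ndarray:
    """Leave-one-out nearest-neighbor prediction for every sample.

    Computed in row blocks; decisions are identical to the naive
    double-loop formulation (same distance expression, argmin ties to the
    smallest remaining index).
    """
    idx = matrix.feature_indices(features)
    if idx.size == 0:
        raise ValueError("empty feature subset")
    if matrix.n_samples < 2:
        raise ValueError("jackknife needs at least 2 samples")
    X = np.ascontiguousarray(matrix.values[:, idx])
    n = matrix.n_samples
    norms = np.sqrt(np.einsum("ij,ij->i", X, X))
    preds = np.empty(n, dtype=int)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        D = _distance_block(X[start:stop], X, norms[start:stop], norms)
        D[np.arange(stop - start), np.arange(start, stop)] = np.inf  # exclude self
        preds[start:stop] = matrix.labels[np.argmin(D, axis=1)]
    return preds


def report_from_predictions(labels: np.ndarray, preds: np.ndarray) -> AccuracyReport:
    pos = labels == POSITIVE_LABEL
    neg = labels == NEGATIVE_LABEL
    return AccuracyReport(
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
        correct_pos=int((preds[pos] == POSITIVE_LABEL).sum()),
        correct_neg=int((preds[neg] == NEGATIVE_LABEL).sum()),
    )


def jackknife(
    matrix: FeatureMatrix,
    features: Sequence[str] | None = None,
    block_size: int = DEFAULT_BLOCK,
) -> AccuracyReport:
    """Leave-one-out accuracy over the restricted feature columns."""
    preds = jackknife_predictions(matrix, features, block_size=block_size)
    return report_from_predictions(matrix.labels, preds)


def write_report(report: AccuracyReport, path: str | Path) -> None:
    d = report.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(d) + "\n")
        fh.write("\t".join(str(v) for v in d.values()) + "\n")
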