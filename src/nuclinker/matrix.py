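"""The labeled feature matrix: length-normalized family counts per sequence.

File dialect: one sample per line, tab-separated; first column the class
label (1 = nucleosome, 2 = linker), remaining columns the per-family
values.  An optional first header line carries the family names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, LabelError, ParseError, RecordError
from .intervals import Label, SequenceSample
from .motifs import MotifFamily, scan_family_hits

POSITIVE_LABEL = 1  # nucleosome core
NEGATIVE_LABEL = 2  # linker


@dataclass
class FeatureMatrix:
    """samples x families table of non-negative, length-normalized counts."""

    values: np.ndarray
    labels: np.ndarray
    family_names: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D array")
        n, f = self.values.shape
        if len(self.labels) != n:
            raise FormatError(f"{n} rows but {len(self.labels)} labels")
        if len(self.family_names) != f:
            raise FormatError(f"{f} columns but {len(self.family_names)} family names")
        if len(set(self.family_names)) != f:
            raise FormatError("duplicate family names")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise FormatError(f"{n} rows but {len(self.sample_ids)} sample ids")
        bad = set(np.unique(self.labels)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise LabelError(f"labels must be 1 or 2, found {sorted(bad)}")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise FormatError("feature values must be finite and non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_indices(self, features: Sequence[str] | None) -> np.ndarray:
        """Column indices for the named features (None -> all columns)."""
        if features is None:
            return np.arange(self.n_features)
        lookup = {name: i for i, name in enumerate(self.family_names)}
        missing = [f for f in features if f not in lookup]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        return np.array([lookup[f] for f in features], dtype=int)

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        idx = self.feature_indices(features)
        return FeatureMatrix(
            self.values[:, idx], self.labels.copy(), list(features), list(self.sample_ids)
        )

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.feature_indices([feature])[0]]


def build_matrix(
    samples: Sequence[SequenceSample], families: Sequence[MotifFamily]
) -> FeatureMatrix:
    """Scan every sample against every family and normalize by length.

    value[i][j] = hits(sample_i, family_j) / length_i; labels follow the
    sample labels (POSITIVE -> 1, NEGATIVE -> 2); column order is the
    input family order.
    """
    if not samples:
        raise FormatError("no samples")
    for i, s in enumerate(samples):
        if s.length == 0:
            raise RecordError(f"sample {i} ({s.id!r}) has zero length")
    values = np.empty((len(samples), len(families)), dtype=float)
    for i, s in enumerate(samples):
        for j, fam in enumerate(families):
            values[i, j] = scan_family_hits(s.sequence, fam) / s.length
    labels = np.array(
        [POSITIVE_LABEL if s.label is Label.POSITIVE else NEGATIVE_LABEL for s in samples]
    )
    return FeatureMatrix(values, labels, [f.name for f in families], [s.id for s in samples])


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read the tab-separated labeled matrix dialect."""
    lines = Path(path).read_text().splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    family_names: list[str] | None = None
    first_cells = rows[0][1].split("\t")
    try:
        float(first_cells[0])
    except ValueError:
        family_names = [c.strip() for c in first_cells[1:]]
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: header but no data rows")
    labels: list[int] = []
    data: list[list[float]] = []
    width: int | None = None
    for lineno, line in rows:
        cells = line.split("\t")
        try:
            label = int(float(cells[0]))
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric label {cells[0]!r}") from None
        if label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise LabelError(f"line {lineno}: label {label} not in {{1, 2}}")
        try:
            feats = [float(c) for c in cells[1:]]
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric feature cell") from None
        if width is None:
            width = len(feats)
        elif len(feats) != width:
            raise ParseError(f"line {lineno}: expected {width} features, got {len(feats)}")
        labels.append(label)
        data.append(feats)
    if family_names is None:
        family_names = [f"f{j + 1}" for j in range(width or 0)]
    elif len(family_names) != width:
        raise ParseError(f"header names {len(family_names)} columns, data has {width}")
    return FeatureMatrix(np.array(data, dtype=float), np.array(labels), family_names)


def write_matrix(matrix: FeatureMatrix, path: str | Path, header: bool = True) -> None:
    """Write the matrix using shortest round-trip float formatting."""
    with open(path, "w") as fh:
        if header:
            fh.write("label\t" + "\t".join(matrix.family_names) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(str(int(label)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
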