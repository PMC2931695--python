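"""Point-biserial association of each feature with the nucleosome/linker class.

r_pb = (M1 - M0) / s_n * sqrt(p * q), with M1/M0 the class means
(nucleosome coded high), s_n the population (divisor n) standard
deviation over all samples, and p, q the class sample proportions.  This
is algebraically the Pearson correlation against 0/1-coded labels.
Significance uses t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantFeatureError, FormatError
from .matrix import NEGATIVE_LABEL, POSITIVE_LABEL, FeatureMatrix

FORMING = "FORMING"
INHIBITING = "INHIBITING"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


def point_biserial(values: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation, positive when the class-1 mean is higher."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels differ in length")
    pos = labels == POSITIVE_LABEL
    neg = labels == NEGATIVE_LABEL
    if not pos.any() or not neg.any():
        raise FormatError("both classes must be present")
    s_n = values.std(ddof=0)
    if s_n == 0.0:
        raise ConstantFeatureError("feature is constant; r_pb undefined")
    n = values.size
    p = pos.sum() / n
    q = neg.sum() / n
    return float((values[pos].mean() - values[neg].mean()) / s_n * math.sqrt(p * q))


def biserial_test(r_pb: float, n: int) -> tuple[float, float]:
    """(t statistic, two-tailed p) for H0: r_pb = 0, on n - 2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r_pb) >= 1.0:
        return math.copysign(math.inf, r_pb), 0.0
    t = r_pb * math.sqrt(n - 2) / math.sqrt(1.0 - r_pb * r_pb)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return t, float(p)


@dataclass(frozen=True)
class BiserialResult:
    feature: str
    r_pb: float
    m_pos: float
    m_neg: float
    s_n: float
    p_prop: float
    q_prop: float
    t_stat: float
    p_value: float
    call: str


@dataclass
class BiserialTable:
    results: list[BiserialResult]

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, feature: str) -> BiserialResult:
        for r in self.results:
            if r.feature == feature:
                return r
        raise KeyError(feature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature for r in self.results],
                "r_pb": [r.r_pb for r in self.results],
                "t": [r.t_stat for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "call": [r.call for r in self.results],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        # very small p-values print as 0, as conventional in summary tables
        df["p_value"] = [0.0 if p < 5e-324 else p for p in df["p_value"]]
        df.to_csv(path, sep="\t", index=False)


def classify_features(
    matrix: FeatureMatrix,
    features: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> BiserialTable:
    """One BiserialResult per feature, sorted by descending r_pb.

    FORMING: r_pb > 0 and p < alpha; INHIBITING: r_pb < 0 and p < alpha;
    otherwise NOT_SIGNIFICANT.
    """
    names = list(features) if features is not None else list(matrix.family_names)
    matrix.feature_indices(names)  # validate early
    labels = matrix.labels
    pos = labels == POSITIVE_LABEL
    neg = labels == NEGATIVE_LABEL
    n = matrix.n_samples
    results = []
    for name in names:
        v = matrix.column(name)
        r = point_biserial(v, labels)
        t, p = biserial_test(r, n)
        if p < alpha and r > 0:
            call = FORMING
        elif p < alpha and r < 0:
            call = INHIBITING
        else:
            call = NOT_SIGNIFICANT
        results.append(
            BiserialResult(
                feature=name,
                r_pb=r,
                m_pos=float(v[pos].mean()),
                m_neg=float(v[neg].mean()),
                s_n=float(v.std(ddof=0)),
                p_prop=float(pos.sum() / n),
                q_prop=float(neg.sum() / n),
                t_stat=t,
                p_value=p,
                call=call,
            )
        )
    results.sort(key=lambda r: -r.r_pb)
    return BiserialTable(results)
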