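"""Incremental feature selection: jackknife accuracy over nested mRMR prefixes."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix
from .mrmr import RankedFeatureList
from .nna import DEFAULT_BLOCK, AccuracyReport, jackknife


@dataclass(frozen=True)
class IFSRecord:
    size: int
    features: tuple[str, ...]
    report: AccuracyReport


@dataclass
class IFSCurve:
    records: list[IFSRecord]

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records, start=1):
            if rec.size != i or len(rec.features) != i:
                raise ValueError(f"record {i} is not the size-{i} prefix")
            if i > 1 and rec.features[: i - 1] != self.records[i - 2].features:
                raise ValueError(f"record {i} does not extend record {i - 1}")

    @property
    def optimal_size(self) -> int:
        """Smallest prefix size attaining the maximum overall accuracy."""
        accs = [rec.report.acc_overall for rec in self.records]
        return int(np.argmax(accs)) + 1  # argmax takes the first maximum

    @property
    def optimal_features(self) -> tuple[str, ...]:
        return self.records[self.optimal_size - 1].features

    @property
    def optimal_accuracy(self) -> float:
        return self.records[self.optimal_size - 1].report.acc_overall

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": [r.size for r in self.records],
                "acc_pos": [r.report.acc_pos for r in self.records],
                "acc_neg": [r.report.acc_neg for r in self.records],
                "acc_overall": [r.report.acc_overall for r in self.records],
                "added_feature": [r.features[-1] for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ifs_curve(
    matrix: FeatureMatrix,
    ranking: RankedFeatureList | Sequence[str],
    block_size: int = DEFAULT_BLOCK,
) -> IFSCurve:
    """Jackknife every nested prefix of the ranked feature list."""
    order = list(ranking.order) if isinstance(ranking, RankedFeatureList) else list(ranking)
    if sorted(order) != sorted(matrix.family_names):
        raise ValueError("ranking does not cover exactly the matrix's features")
    records = []
    for k in range(1, len(order) + 1):
        prefix = tuple(order[:k])
        records.append(IFSRecord(k, prefix, jackknife(matrix, prefix, block_size=block_size)))
    return IFSCurve(records)


def plot_curve(curve: IFSCurve, path: str | Path) -> None:
    """Overall accuracy vs prefix size, vertex annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = [r.size for r in curve.records]
    accs = [r.report.acc_overall for r in curve.records]
    h = curve.optimal_size
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sizes, accs, marker="o", ms=3)
    ax.plot([h], [curve.optimal_accuracy], marker="*", ms=14, color="red")
    ax.annotate(
        f"vertex: {curve.optimal_accuracy:.2%} @ {h}",
        xy=(h, curve.optimal_accuracy),
        xytext=(5, -12),
        textcoords="offset points",
    )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("overall jackknife accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
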