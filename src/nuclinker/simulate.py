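"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators: a two-class labeled count matrix (Poisson hits, length
normalization, a controllable informative/noise feature split) and a toy
genome with planted non-overlapping core tracks and class-dependent motif
densities.  Everything is driven by one seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CORE_LENGTH, GenomicInterval, IntervalSet, Role
from .matrix import NEGATIVE_LABEL, POSITIVE_LABEL, FeatureMatrix
from .motifs import ConsensusMotif, IUPAC_CODES, MotifFamily


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class length-normalized count matrix.

    ``informative`` lists (feature index, expected hits/bp in the
    positive class, expected hits/bp in the negative class); all other
    features draw from ``background_rate`` in both classes.  Positive
    samples have fixed length (147 bp); negative lengths follow a shifted
    geometric law with the given minimum and mean.
    """

    n_pos: int
    n_neg: int
    n_features: int
    informative: tuple[tuple[int, float, float], ...] = ()
    background_rate: float = 0.01
    pos_length: int = CORE_LENGTH
    neg_length_min: int = 6
    neg_length_mean: float = 38.0
    dispersion: float | None = None  # None -> Poisson; else negative binomial
    seed: int = 0

    def __post_init__(self) -> None:
        idx = [i for i, _, _ in self.informative]
        if len(set(idx)) != len(idx):
            raise ValueError("informative feature indices must be distinct")
        if any(i < 0 or i >= self.n_features for i in idx):
            raise ValueError("informative feature index out of range")
        if any(rp < 0 or rn < 0 for _, rp, rn in self.informative) or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.neg_length_mean < self.neg_length_min:
            raise ValueError("negative mean length below minimum")


def _neg_lengths(spec: SyntheticSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    span = spec.neg_length_mean - spec.neg_length_min + 1
    return spec.neg_length_min - 1 + rng.geometric(1.0 / span, size=size)


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, dispersion: float | None
) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(lam)
    # NB with mean lam and variance lam * (1 + lam / dispersion)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = dispersion / (dispersion + lam)
    out = np.where(lam > 0, rng.negative_binomial(dispersion, np.where(lam > 0, p, 1.0)), 0)
    return out


def generate_matrix(spec: SyntheticSpec) -> FeatureMatrix:
    """Draw the labeled matrix described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    rates = np.full((2, spec.n_features), spec.background_rate)  # row 0: pos, row 1: neg
    for j, rate_pos, rate_neg in spec.informative:
        rates[0, j] = rate_pos
        rates[1, j] = rate_neg
    if not rates.any():
        warnings.warn("all rates are zero; the matrix is degenerate", stacklevel=2)
    lengths = np.concatenate(
        [
            np.full(spec.n_pos, spec.pos_length, dtype=int),
            _neg_lengths(spec, rng, spec.n_neg),
        ]
    )
    cls = np.concatenate([np.zeros(spec.n_pos, dtype=int), np.ones(spec.n_neg, dtype=int)])
    lam = rates[cls] * lengths[:, None]
    counts = _draw_counts(rng, lam, spec.dispersion)
    values = counts / lengths[:, None]
    labels = np.where(cls == 0, POSITIVE_LABEL, NEGATIVE_LABEL)
    names = [f"F{j + 1}" for j in range(spec.n_features)]
    return FeatureMatrix(values, labels, names)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern)


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a toy genome with planted cores and motifs."""

    chrom_lengths: Mapping[str, int]
    families: tuple[MotifFamily, ...] = ()
    rate_core: float = 0.0  # planted motifs per bp inside cores
    rate_linker: float = 0.0  # planted motifs per bp inside linkers
    linker_mean: float = 38.0
    linker_min: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(L < 200 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 200 bp")
        if self.linker_mean < self.linker_min:
            raise ValueError("linker spacing model incompatible with minimum")


def generate_genome(
    spec: GenomeSpec,
) -> tuple[dict[str, str], IntervalSet, IntervalSet]:
    """Random genome plus the planted core and linker interval sets.

    Cores are 147 bp, non-overlapping, separated by geometric linkers of
    at least ``linker_min`` bp; motifs (a random member consensus,
    concretely instantiated) are written into cores and linkers at the
    class-dependent per-bp rates.
    """
    rng = np.random.default_rng(spec.seed)
    span = spec.linker_mean - spec.linker_min + 1
    genomes: dict[str, str] = {}
    cores: list[GenomicInterval] = []
    linkers: list[GenomicInterval] = []
    for chrom, length in spec.chrom_lengths.items():
        seq = rng.choice(list("ACGT"), size=length)
        pos = 1 + int(spec.linker_min - 1 + rng.geometric(1.0 / span))
        prev_core: GenomicInterval | None = None
        while pos + CORE_LENGTH - 1 <= length:
            core = GenomicInterval(chrom, pos, pos + CORE_LENGTH - 1)
            cores.append(core)
            if prev_core is not None:
                linkers.append(GenomicInterval(chrom, prev_core.end + 1, core.start - 1))
            prev_core = core
            gap = int(spec.linker_min - 1 + rng.geometric(1.0 / span))
            pos = core.end + 1 + gap
        # plant motifs region by region
        if spec.families:
            regions = [(iv, spec.rate_core) for iv in cores if iv.chrom == chrom]
            regions += [(iv, spec.rate_linker) for iv in linkers if iv.chrom == chrom]
            for iv, rate in regions:
                n_mot = rng.poisson(rate * iv.length)
                for _ in range(n_mot):
                    fam = spec.families[rng.integers(len(spec.families))]
                    member = fam.members[rng.integers(len(fam.members))]
                    if not isinstance(member, ConsensusMotif):
                        continue  # only consensus members can be planted
                    word = _instantiate(member.pattern, rng)
                    if len(word) > iv.length:
                        continue
                    start0 = iv.start - 1 + int(rng.integers(iv.length - len(word) + 1))
                    seq[start0 : start0 + len(word)] = list(word)
        genomes[chrom] = "".join(seq)
    return genomes, IntervalSet(cores, role=Role.CORE), IntervalSet(linkers, role=Role.LINKER)


def write_genome_fixture(
    spec: GenomeSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write genome.fasta, cores.tsv and linkers.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, cores, linkers = generate_genome(spec)
    fasta = out / "genome.fasta"
    with open(fasta, "w") as fh:
        for chrom, seq in genomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    cores_path = out / "cores.tsv"
    linkers_path = out / "linkers.tsv"
    cores.to_tsv(cores_path)
    linkers.to_tsv(linkers_path)
    return fasta, cores_path, linkers_path
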