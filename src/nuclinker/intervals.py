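"""Genomic intervals for nucleosome cores and the linkers between them.

Coordinates are 1-based and inclusive throughout ([start, end], length =
end - start + 1), matching the yeast site-table convention.  BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from .errors import CoordinateError, FormatError, RecordError

CORE_LENGTH = 147
DEFAULT_MIN_LINKER = 6


class Role(Enum):
    CORE = "core"
    LINKER = "linker"


class Label(Enum):
    """Sample class: POSITIVE = nucleosome core, NEGATIVE = linker."""

    POSITIVE = 1
    NEGATIVE = 2


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise RecordError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise RecordError(
                f"end < start for interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class IntervalSet:
    """An ordered collection of intervals sharing a role (CORE or LINKER)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    role: Role = Role.CORE

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def to_tsv(self, path: str | Path) -> None:
        """Write a 1-based inclusive chrom/start/end table."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\n")
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    def to_bed(self, path: str | Path) -> None:
        """Write BED (0-based half-open)."""
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


@dataclass(frozen=True)
class SequenceSample:
    """A labeled DNA sequence extracted for one interval."""

    id: str
    label: Label
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _split_rows(text: str) -> list[tuple[int, list[str]]]:
    lines = [ln for ln in text.splitlines()]
    rows: list[tuple[int, list[str]]] = []
    delim = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        rows.append((lineno, [c.strip() for c in line.split(delim)]))
    return rows


def load_core_sites(source: str | Path | io.TextIOBase, role: Role = Role.CORE) -> IntervalSet:
    """Parse a chrom/start/end coordinate table into a sorted IntervalSet.

    The delimiter (tab or comma) is auto-detected and an optional header
    line is recognized by non-numeric start/end fields.  Rows with a
    non-numeric position or too few columns are rejected; their row
    numbers are reported in a single warning.  A row with end < start
    raises :class:`RecordError` naming the row.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    rows = _split_rows(text)
    if rows:
        first = rows[0][1]
        if len(first) >= 3 and not (first[1].lstrip("-").isdigit() and first[2].lstrip("-").isdigit()):
            rows = rows[1:]  # header line
    intervals: list[GenomicInterval] = []
    bad_rows: list[int] = []
    for lineno, cells in rows:
        if len(cells) < 3:
            bad_rows.append(lineno)
            continue
        chrom = cells[0]
        try:
            start, end = int(float(cells[1])), int(float(cells[2]))
        except ValueError:
            bad_rows.append(lineno)
            continue
        if end < start:
            raise RecordError(f"row {lineno}: end < start ({chrom}:{start}-{end})")
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except RecordError as exc:
            raise RecordError(f"row {lineno}: {exc}") from None
    if not rows and not intervals and text.strip():
        raise FormatError("no parsable rows found")
    if bad_rows:
        warnings.warn(
            f"rejected {len(bad_rows)} malformed row(s): {bad_rows[:20]}",
            stacklevel=2,
        )
    return IntervalSet(intervals, role=role)


def derive_linkers(
    cores: IntervalSet,
    min_len: int = DEFAULT_MIN_LINKER,
    max_len: int | None = None,
) -> IntervalSet:
    """Gaps between successive cores on each chromosome, as LINKER intervals.

    For each successive pair of cores the candidate linker is
    (prev.end + 1, next.start - 1).  Overlapping or book-ended cores give
    no linker; gaps shorter than ``min_len`` (or longer than ``max_len``,
    if set) are dropped.  Segments before the first and after the last
    core of a chromosome are never emitted.
    """
    if cores.role is not Role.CORE:
        raise ValueError("derive_linkers expects a CORE IntervalSet")
    linkers: list[GenomicInterval] = []
    prev: GenomicInterval | None = None
    for iv in cores:
        if prev is not None and iv.chrom == prev.chrom:
            gap_start, gap_end = prev.end + 1, iv.start - 1
            gap_len = gap_end - gap_start + 1
            if gap_len >= min_len and (max_len is None or gap_len <= max_len):
                linkers.append(GenomicInterval(iv.chrom, gap_start, gap_end))
        prev = iv
    return IntervalSet(linkers, role=Role.LINKER)


def load_genome(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Read a (multi-)FASTA into an uppercase name -> sequence dict."""
    if isinstance(source, Mapping):
        return {name: seq.upper() for name, seq in source.items()}
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")
    }


def extract_sequences(
    intervals: IntervalSet, genome: str | Path | Mapping[str, str]
) -> list[SequenceSample]:
    """Forward-strand, uppercase sequences for every interval.

    Sample ids are ``chrom:start-end``; labels follow the set's role
    (CORE -> POSITIVE, LINKER -> NEGATIVE).
    """
    seqs = load_genome(genome)
    label = Label.POSITIVE if intervals.role is Role.CORE else Label.NEGATIVE
    samples: list[SequenceSample] = []
    for iv in intervals:
        if iv.chrom not in seqs:
            raise CoordinateError(f"chromosome {iv.chrom!r} not in genome")
        chrom_seq = seqs[iv.chrom]
        if iv.end > len(chrom_seq):
            raise CoordinateError(
                f"interval {iv.name} extends past chromosome end ({len(chrom_seq)} bp)"
            )
        samples.append(SequenceSample(iv.name, label, chrom_seq[iv.start - 1 : iv.end]))
    return samples


def write_fasta(samples: Iterable[SequenceSample], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")
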