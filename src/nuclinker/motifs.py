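"""Motif-family scanning: a documented stand-in for a commercial TFBS scanner.

Families group member motifs (IUPAC consensus strings or position weight
matrices).  A family "hit" is a (position, strand) pair at which at least
one member matches; overlapping hits count, a palindromic match counts on
both strands, and 'N' bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import FormatError

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# base -> bit; anything else (incl. N in the *sequence*) carries no bit and
# can never satisfy a pattern position.
_SEQ_BITS = np.zeros(256, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _SEQ_BITS[ord(_b)] = 1 << _i


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode_bits(seq: str) -> np.ndarray:
    return _SEQ_BITS[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC consensus pattern."""

    id: str
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC_CODES)
        if not pat or bad:
            raise FormatError(f"motif {self.id!r}: invalid IUPAC pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def match_starts(self, seq: str) -> np.ndarray:
        """0-based start positions of all (overlapping) matches in seq."""
        L = len(self.pattern)
        if L > len(seq):
            return np.empty(0, dtype=np.intp)
        masks = np.array(
            [sum(1 << _BASE_INDEX[b] for b in IUPAC_CODES[c]) for c in self.pattern],
            dtype=np.uint8,
        )
        bits = _encode_bits(seq)
        windows = np.lib.stride_tricks.sliding_window_view(bits, L)
        ok = ((windows & masks) != 0).all(axis=1)
        return np.flatnonzero(ok)


@dataclass(frozen=True)
class PWMMotif:
    """A probability matrix scored as log2-odds against a uniform background.

    ``matrix`` has shape (4, L) in A/C/G/T row order; a window matches when
    its summed log2(p / 0.25) score reaches ``threshold``.  'N' forces a
    -inf contribution.
    """

    id: str
    matrix: tuple[tuple[float, ...], ...]
    threshold: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] == 0 or (m < 0).any():
            raise FormatError(f"motif {self.id!r}: PWM must be 4 x L and non-negative")

    def __len__(self) -> int:
        return len(self.matrix[0])

    @property
    def _scores(self) -> np.ndarray:
        m = np.asarray(self.matrix, dtype=float)
        m = m / m.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore"):
            s = np.log2(np.maximum(m, 1e-12) / 0.25)
        # 5th row = everything that is not A/C/G/T
        return np.vstack([s, np.full((1, s.shape[1]), -np.inf)])

    def match_starts(self, seq: str) -> np.ndarray:
        L = len(self)
        if L > len(seq):
            return np.empty(0, dtype=np.intp)
        codes = np.full(len(seq), 4, dtype=np.intp)
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for b, i in _BASE_INDEX.items():
            codes[arr == ord(b)] = i
        scores = self._scores
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        vals = scores[windows, np.arange(L)].sum(axis=1)
        return np.flatnonzero(vals >= self.threshold)


Motif = Union[ConsensusMotif, PWMMotif]


@dataclass(frozen=True)
class MotifFamily:
    name: str
    members: tuple[Motif, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"family {self.name!r} has no members")


def scan_family_hits(sequence: str, family: MotifFamily) -> int:
    """Number of (position, strand) pairs matched by >=1 family member.

    Both strands are scanned (the reverse strand by scanning the reverse
    complement); a member longer than the sequence contributes nothing.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    total = 0
    for strand_seq in (sequence, reverse_complement(sequence)):
        starts: set[int] = set()
        for member in family.members:
            starts.update(member.match_starts(strand_seq).tolist())
        total += len(starts)
    return total


def read_motif_table(path: str | Path) -> list[MotifFamily]:
    """Load a family/member table.

    Tab-separated columns: ``family``, ``member_id``, ``pattern`` and an
    optional 4th column.  A plain IUPAC string is a consensus member.  A
    PWM member writes the pattern cell as semicolon-separated columns of
    four comma-separated A,C,G,T weights, with the threshold in the 4th
    column.
    """
    families: dict[str, list[Motif]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if lineno == 1 and cells[0].lower() == "family":
            continue
        if len(cells) < 3:
            raise FormatError(f"line {lineno}: expected family, member_id, pattern")
        fam, member_id, pattern = cells[0], cells[1], cells[2]
        if ";" in pattern or "," in pattern:
            cols = [tuple(float(x) for x in col.split(",")) for col in pattern.split(";")]
            if any(len(c) != 4 for c in cols):
                raise FormatError(f"line {lineno}: PWM columns need 4 weights")
            threshold = float(cells[3]) if len(cells) > 3 and cells[3] else 0.0
            motif: Motif = PWMMotif(member_id, tuple(zip(*cols)), threshold)
        else:
            motif = ConsensusMotif(member_id, pattern)
        families.setdefault(fam, []).append(motif)
    if not families:
        raise FormatError(f"{path}: no motif records")
    return [MotifFamily(name, tuple(members)) for name, members in families.items()]


def write_motif_table(families: Iterable[MotifFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmember_id\tpattern\tthreshold\n")
        for fam in families:
            for m in fam.members:
                if isinstance(m, ConsensusMotif):
                    fh.write(f"{fam.name}\t{m.id}\t{m.pattern}\t\n")
                else:
                    cols = ";".join(
                        ",".join(repr(float(m.matrix[r][c])) for r in range(4))
                        for c in range(len(m))
                    )
                    fh.write(f"{fam.name}\t{m.id}\t{cols}\t{m.threshold!r}\n")
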