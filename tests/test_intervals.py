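import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nuclinker import (
    GenomicInterval,
    IntervalSet,
    Label,
    Role,
    derive_linkers,
    extract_sequences,
    load_core_sites,
)
from nuclinker.errors import CoordinateError, RecordError
from nuclinker.intervals import write_fasta, load_genome


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    def test_length(self):
        assert iv("chrI", 1, 147).length == 147

    def test_end_before_start_rejected(self):
        with pytest.raises(RecordError):
            iv("chrI", 10, 5)

    def test_start_below_one_rejected(self):
        with pytest.raises(RecordError):
            iv("chrI", 0, 5)


class TestLoadCoreSites:
    def test_empty_table(self):
        assert len(load_core_sites(io.StringIO(""))) == 0

    def test_sorting_contract(self):
        table = "chrI\t100\t246\nchrI\t50\t196\n"
        s = load_core_sites(io.StringIO(table))
        assert [(i.chrom, i.start, i.end) for i in s] == [
            ("chrI", 50, 196),
            ("chrI", 100, 246),
        ]

    def test_header_detected(self):
        s = load_core_sites(io.StringIO("chrom\tstart\tend\nchrI\t1\t147\n"))
        assert len(s) == 1 and s[0].start == 1

    def test_csv_delimiter(self):
        s = load_core_sites(io.StringIO("chrI,1,147\nchrI,160,306\n"))
        assert len(s) == 2

    def test_malformed_rows_rejected_with_numbers(self):
        table = "chrI\t1\t147\nchrI\tfoo\t300\nchrI\t400\n"
        with pytest.warns(UserWarning, match=r"\[2, 3\]"):
            s = load_core_sites(io.StringIO(table))
        assert len(s) == 1

    def test_end_before_start_names_row(self):
        with pytest.raises(RecordError, match="row 2"):
            load_core_sites(io.StringIO("chrI\t1\t147\nchrI\t300\t200\n"))


class TestDeriveLinkers:
    def test_gap_arithmetic(self):
        cores = IntervalSet([iv("chrI", 1, 147), iv("chrI", 160, 306)])
        linkers = derive_linkers(cores)
        assert len(linkers) == 1
        assert (linkers[0].start, linkers[0].end, linkers[0].length) == (148, 159, 12)

    def test_minimum_length_filter(self):
        cores = IntervalSet([iv("chrI", 1, 147), iv("chrI", 152, 298)])
        assert len(derive_linkers(cores)) == 0  # gap of 4 < 6

    def test_book_ended_cores(self):
        cores = IntervalSet([iv("chrI", 1, 147), iv("chrI", 148, 294)])
        assert len(derive_linkers(cores, min_len=1)) == 0

    def test_overlapping_cores(self):
        cores = IntervalSet([iv("chrI", 1, 147), iv("chrI", 100, 246)])
        assert len(derive_linkers(cores, min_len=1)) == 0

    def test_no_terminal_gaps_and_per_chromosome(self):
        cores = IntervalSet(
            [iv("chrI", 100, 246), iv("chrI", 300, 446), iv("chrII", 50, 196)]
        )
        linkers = derive_linkers(cores, min_len=1)
        assert [(l.chrom, l.start, l.end) for l in linkers] == [("chrI", 247, 299)]

    def test_max_len_cap(self):
        cores = IntervalSet([iv("chrI", 1, 147), iv("chrI", 1000, 1146)])
        assert len(derive_linkers(cores, max_len=100)) == 0
        assert len(derive_linkers(cores)) == 1

    def test_idempotent_under_input_reordering(self):
        rows = [iv("chrI", 400, 546), iv("chrI", 1, 147), iv("chrI", 200, 346)]
        a = derive_linkers(IntervalSet(rows))
        b = derive_linkers(IntervalSet(rows[::-1]))
        assert a.intervals == b.intervals

    def test_role_guard(self):
        with pytest.raises(ValueError):
            derive_linkers(IntervalSet([], role=Role.LINKER))


@st.composite
def core_sets(draw):
    """Non-overlapping sorted cores on one chromosome."""
    n = draw(st.integers(min_value=2, max_value=12))
    gaps = draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
    cores, pos = [], 1
    for g in gaps:
        pos += g
        cores.append(GenomicInterval("chrI", pos, pos + 146))
        pos += 147
    return IntervalSet(cores)


@given(core_sets())
@settings(max_examples=50, deadline=None)
def test_complementarity_and_conservation(cores):
    linkers = derive_linkers(cores, min_len=1, max_len=None)
    pieces = sorted(list(cores) + list(linkers), key=lambda i: i.start)
    span_start, span_end = cores[0].start, cores[len(cores) - 1].end
    # tiling without overlap from first core start to last core end
    assert pieces[0].start == span_start
    for a, b in zip(pieces, pieces[1:]):
        assert b.start == a.end + 1
    assert pieces[-1].end == span_end
    # length conservation
    span = span_end - span_start + 1
    assert sum(l.length for l in linkers) == span - sum(c.length for c in cores)


class TestExtractSequences:
    GENOME = {"chrI": "ACGTACGTAA", "chr2": "AAACCC"}

    def test_coordinate_convention(self):
        s = extract_sequences(IntervalSet([iv("chrI", 1, 4)]), self.GENOME)
        assert s[0].sequence == "ACGT"

    def test_direct_indexing(self):
        s = extract_sequences(IntervalSet([iv("chr2", 4, 6)]), self.GENOME)
        assert s[0].sequence == "CCC"

    def test_length_conservation(self):
        genome = {"chrI": "A" * 200}
        s = extract_sequences(IntervalSet([iv("chrI", 10, 156)]), genome)
        assert s[0].length == 147

    def test_ids_and_labels(self):
        cores = extract_sequences(IntervalSet([iv("chrI", 1, 4)]), self.GENOME)
        assert cores[0].id == "chrI:1-4" and cores[0].label is Label.POSITIVE
        linkers = extract_sequences(
            IntervalSet([iv("chrI", 1, 4)], role=Role.LINKER), self.GENOME
        )
        assert linkers[0].label is Label.NEGATIVE

    def test_uppercase(self):
        s = extract_sequences(IntervalSet([iv("chrI", 1, 4)]), {"chrI": "acgt"})
        assert s[0].sequence == "ACGT"

    def test_out_of_bounds_names_interval(self):
        with pytest.raises(CoordinateError, match="chr2:4-99"):
            extract_sequences(IntervalSet([iv("chr2", 4, 99)]), self.GENOME)

    def test_missing_chromosome(self):
        with pytest.raises(CoordinateError, match="chrX"):
            extract_sequences(IntervalSet([iv("chrX", 1, 2)]), self.GENOME)


def test_fasta_round_trip(tmp_path):
    from nuclinker import SequenceSample

    samples = [
        SequenceSample("a", Label.POSITIVE, "ACGT" * 40),
        SequenceSample("b", Label.NEGATIVE, "TTTTTT"),
    ]
    path = tmp_path / "x.fasta"
    write_fasta(samples, path)
    back = load_genome(path)
    assert back == {"a": "ACGT" * 40, "b": "TTTTTT"}


def test_tsv_and_bed_output(tmp_path):
    s = IntervalSet([iv("chrI", 1, 147)])
    tsv, bed = tmp_path / "s.tsv", tmp_path / "s.bed"
    s.to_tsv(tsv)
    s.to_bed(bed)
    assert tsv.read_text() == "chrom\tstart\tend\nchrI\t1\t147\n"
    assert bed.read_text() == "chrI\t0\t147\n"  # 0-based half-open
    assert len(load_core_sites(tsv)) == 1
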