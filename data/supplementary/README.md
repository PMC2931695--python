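# Supplementary data drop-in directory

The full-data acceptance checks (tests/test_acceptance.py criteria 1-3 and
scripts/acceptance.py targets t1-t6) reproduce numbers published for the
original ~103k-sequence yeast dataset. The required files are distributed
as journal supplementary material and are not redistributable with this
repository; this directory ships empty apart from this README.

To run the full-data checks, place here:

- `TableS8.txt` - the labeled feature-vector matrix: one sample per line,
  tab-separated; first column 1 (nucleosome) or 2 (linker), then 35
  length-normalized family-frequency columns. An optional first header
  line may carry the family names.
- `family_names.txt` - required only if `TableS8.txt` is headerless:
  whitespace-separated family names (e.g. `F$GATA`), one per matrix
  column, in column order. The published matrix column order follows the
  supplementary mRMR output table.
- `TableS4.tsv` - the nucleosome core site table converted to plain text:
  three delimited columns (chromosome, start, end; 1-based inclusive),
  optional header. The original distribution is an .xls workbook; export
  it as TSV/CSV.

Without these files the corresponding acceptance tests fail with an
explanatory message and `scripts/acceptance.py` omits the affected
targets.
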