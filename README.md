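# nuclinker

Pipeline for asking which transcription-factor binding-site (TFBS)
families discriminate nucleosome-core DNA from linker DNA:

1. **interval prep** — load nucleosome-core coordinates (1-based
   inclusive), derive linkers as the gaps between successive cores
   (default minimum 6 bp), and extract both sequence classes from a
   genome FASTA;
2. **featurize** — count motif-family hits per sequence on both strands
   (a documented stand-in for commercial matrix scanners; IUPAC consensus
   or PWM members), normalize by sequence length, and emit a labeled
   matrix (label 1 = nucleosome, 2 = linker);
3. **mRMR ranking** — greedy minimum-redundancy maximum-relevance
   ordering (MID criterion) using plug-in mutual information over features
   discretized into three states at mean ± t·std (t = 1 by default);
4. **IFS** — jackknife (leave-one-out) evaluation of a cosine-distance
   nearest-neighbor classifier on every nested prefix of the ranking; the
   curve's vertex is the optimal feature subset;
5. **biserial stats** — point-biserial correlation with a t-test to call
   each selected family nucleosome-forming (r > 0, p < 0.05) or
   nucleosome-inhibiting (r < 0, p < 0.05);
6. **simulate** — synthetic two-class count matrices (Poisson or
   negative-binomial) and toy genomes with planted core tracks and
   motifs, for testing every stage without external data.

## CLI

Every stage is exposed through one entry point:

```sh
nuclinker prep --cores sites.tsv --genome genome.fasta --min-linker 6 --out-dir prep/
nuclinker featurize --sequences prep/cores.fasta prep/linkers.fasta \
    --motifs motifs.tsv --out matrix.tsv
nuclinker rank --matrix matrix.tsv --t 1 --out-prefix mrmr_
nuclinker ifs --matrix matrix.tsv --ranking mrmr_mrmr_list.tsv --out ifs.tsv --plot ifs.png
nuclinker evaluate --matrix matrix.tsv --features F\$GATA,F\$YGCR --report report.tsv
nuclinker stats --matrix matrix.tsv --alpha 0.05 --out calls.tsv
nuclinker simulate matrix --spec spec.toml --out matrix.tsv
nuclinker simulate genome --spec genome.toml --out-dir fixtures/
```

### File formats

- **Coordinate tables**: TSV or CSV (auto-detected), columns
  chromosome / start / end, 1-based inclusive, optional header. BED
  exports are 0-based half-open.
- **Motif table**: tab-separated `family`, `member_id`, `pattern`
  (+ optional `threshold`). A plain IUPAC string defines a consensus
  member; a PWM member writes semicolon-separated columns of four
  comma-separated A,C,G,T weights with its log2-odds threshold in the
  fourth column. Scanning conventions: hits are (position, strand) pairs
  matched by any member, overlaps count, palindromes count once per
  strand, `N` in the sequence never matches.
- **Feature matrix**: tab-separated; first column the label (1/2), then
  one length-normalized value per family; optional header line with
  family names. Written values use shortest round-trip formatting, so
  write-then-read is exact.
- **Simulation specs**: TOML mirroring `SyntheticSpec` / `GenomeSpec`
  (see `tests/test_cli.py` for worked examples).

## Conventions worth knowing

- Cosine distance D = 1 − x·y/(‖x‖‖y‖) with the zero-norm convention
  D(0, y) = 1 for y ≠ 0 and D(0, 0) = 0 (all-zero rows arise for short
  linkers); nearest-neighbor ties break toward the smallest training
  index. Blocked evaluation makes identical decisions to the naive
  double loop.
- Discretization uses the sample standard deviation (ddof = 1) by
  default and a closed interval at the boundaries; the class label is
  never discretized.
- Point-biserial uses the population (divisor n) standard deviation and
  class sample proportions, making it exactly the Pearson correlation
  with 0/1-coded labels (nucleosome = 1).
- mRMR tie-breaks are deterministic by original column order; the
  ranking is invariant to the mutual-information log base.
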