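# mitocapture

A toolkit for mitochondrial target-capture phylogenomics on reference-mapped
consensus data. From per-sample consensus calls with per-position read
coverage it builds a cleaned, reference-anchored multi-taxon alignment
together with a binary (0/1) indel character matrix, and provides the
downstream analyses that this kind of dataset supports:

- **simdata** — a synthetic capture-experiment generator (multi-contig
  reference, substitutions + non-overlapping indels along a known tree,
  regional capture dropout that grows with distance from the reference taxon,
  optional introgression), with exact truth bookkeeping so every downstream
  stage is testable without any external data.
- **tiling** — long-range-PCR amplicon window planning (minimum window count
  per contig within a 10–12 kb band, minimal overlap), BED output.
- **alignment** — coverage-threshold masking (default 20×), removal of short
  called islands stranded in missing regions, column assembly (all reference
  positions plus insertion column blocks), and simple indel coding: each
  determinate gap run or insertion is one presence/absence character;
  ambiguous-boundary runs are handled by a `to-missing` policy.
- **variants** — SNP-site and segregating-indel counts, intraspecific
  polymorphism counts, and between-group mean pairwise distance tables
  (raw and per-site, pairwise deletion throughout).
- **introgression** — plurality population consensuses and ABBA-BABA counting
  over pooled SNP + indel characters, with exact binomial sign tests and a
  block bootstrap for D.
- **phylogeny** — Jukes–Cantor distances, deterministic neighbor joining,
  Fitch parsimony with random-addition + NNI heuristic search, and a pooled
  column bootstrap with supports mapped onto the best tree.
- **dating** — penalized-likelihood chronograms on a fixed topology under
  fossil min/max calibrations (Poisson branch likelihood + rate-smoothing
  penalty), cross-validated smoothing selection, and bootstrap age intervals
  with least-squares branch-length refits.

## CLI

```bash
mitocapture simulate --seed 1 --n-taxa 12 --ref-len 100000 --out-dir sim/
mitocapture tile contigs.tsv --min-len 10000 --max-len 12000
mitocapture align --reference sim/reference.fasta --threshold 20 \
    --out-dir aln/ sim/*.consensus.fasta
mitocapture stats aln/alignment.fasta --indels aln/indels.tsv
mitocapture groupdist aln/alignment.fasta --indels aln/indels.tsv --groups groups.yaml
mitocapture abbababa aln/alignment.fasta --indels aln/indels.tsv --groups roles.yaml
mitocapture tree aln/alignment.fasta --indels aln/indels.tsv --method mp --bootstrap 100
mitocapture date tree.nwk --calibrations cal.yaml --n-sites 900000 --smoothing auto
```

Group files are YAML mappings of label → taxon list; calibration files are
YAML lists of `{leaves: [...], min: Mya, max: Mya}` entries constraining the
MRCA of the named leaves.

## Conventions

- Coordinates are 0-based, half-open, on the concatenated reference.
- `?` is the canonical missing symbol; `N` on input is mapped to `?`.
- A SNP is a column with ≥ 2 distinct A/C/G/T states (multi-allelic columns
  count once); gaps are never nucleotide states, indel signal lives in the
  0/1 characters.
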