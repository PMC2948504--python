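# cotscan

Seed-table siRNA off-target search, **common-off-target (cot) group**
analysis and clean dsRNA region-pair design for long-dsRNA RNAi
experiments (*Drosophila*/*C. elegans*-style screens).

## The problem

In fly and worm RNAi, a gene is silenced with a long (300–800 bp) dsRNA
that DICER chops into ~21-nt siRNAs. Each siRNA can also silence
*off-target* genes that align to it gaplessly with up to 3 mismatches.
The standard control — repeating the experiment with a second,
non-overlapping dsRNA from the same gene — silently fails when two
different regions of the gene each contain an siRNA hitting the **same**
off-target gene: both constructs then reproduce the same off-target
phenotype, which is indistinguishable from an on-target effect.

`cotscan` quantifies and avoids this failure mode:

* **cot-group** — two or more siRNA start sites on one source gene's
  cDNA whose ≤3-mismatch hits land in the same off-target gene. Per
  gene it reports the group count, the maximum group size, and the
  coverage `100 · Σ_g |g| · L / len(cDNA)` (L = 21; may exceed 100% when
  sites belong to several groups).
* **clean regions** — maximal cDNA intervals that never fully contain
  two member sites of any one group.
* **dsRNA pair design** — two non-overlapping regions (default
  300–800 bp, optionally avoiding UTRs) whose off-target gene sets are
  provably disjoint, ranked by combined length.

## The algorithm

Targets (per-gene pre-mRNA, or mature transcripts) are indexed in a
word-size-9 *seed table*: every 9-nt word, 2-bit encoded into a key
space of 4⁹ = 262,144, maps to its exact locations. A 21-nt query is
split into two 9-nt children plus a 3-nt remainder; for every mismatch
budget partition i + j ≤ k, child variants at Hamming distance exactly
i and j (generated as XOR deltas on the encoding) are looked up and
joined where *left location + 9 = right location*; candidates are then
verified in full. The search is **complete and sound** for gapless
alignments at k ≤ 3 and is continuously cross-checked in the test suite
against a brute-force position-by-position Hamming scan (also available
as `--engine naive`).

Because no public activity table exists, siRNA filtering ships as
pluggable named schemes: `none` (keep everything; always used for the
design disjointness guarantee) and `default-v1` (GC 0.30–0.60, no
homopolymer ≥ 5, A/T at sense position 19; pass at ≥ 2 of 3 points —
a documented stand-in).

## Worked example

Generate a 6-gene synthetic genome in which two 21-mers of `gene000`
(cDNA starts 100 and 700) are planted into an exon of `gene003`, and two
more (250, 500) into an intron of `gene004`:

```sh
cotscan fixtures --spec ex_spec.yaml --seed 11 --out ex
cotscan index --fasta ex/genome.fa --gff ex/genes.gff3 --mode premrna
```
```json
{"word_size": 9, "mode": "premrna", "n_records": 6,
 "total_target_length": 7112, "n_locations": 7064,
 "n_occupied_keys": 6918, "key_space": 262144}
```

Scan the source gene (pre-mRNA mode, every siRNA kept):

```sh
cotscan scan gene000 --fasta ex/genome.fa --gff ex/genes.gff3 \
        --mode premrna --scheme none --out-dir ex/scan
```
```text
gene     n_cot_groups  max_group_size  coverage_percent  gene_length  mode     scheme
gene000  2             19              78.2037           913          premrna  none

source_gene  offtarget_gene  size  member_starts
gene000      gene003         19    97,98,...,109,698,...,703
gene000      gene004         15    249,...,254,497,...,505
```

Both planted cot-groups are recovered (member starts are 1-based; the
runs around each planted start are the windows overlapping the planted
site, which also align within 3 mismatches). Coverage is
(19 + 15)·21/913 = 78.2%. Now design two clean dsRNAs:

```sh
cotscan design gene000 --fasta ex/genome.fa --gff ex/genes.gff3 \
        --mode premrna --min-dsrna 250 --max-dsrna 500 --out-dir ex/design
```
```text
gene000  117  617  pair1_region1  0  +
gene000  617  913  pair1_region2  0  +
```

Region 1 `[117, 617)` truncates every `gene003` site on the left (its
off-target set is `{gene004}`) while region 2 `[617, 913)` contains only
`gene003` sites — disjoint sets, so no off-target gene can be silenced
by both dsRNAs. Infeasible genes instead produce a structured
`"feasible": false` report naming the blocking off-target genes.

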