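# Methods

## Model and scope

`cotscan` models RNAi off-targeting purely at the sequence level: an
siRNA silences a gene if some window of that gene's RNA aligns to the
siRNA gaplessly with at most `k` mismatches (Hamming distance; no
indels, no scoring matrix, no seed-region weighting, no expression or
structure terms). A long dsRNA is treated as the set of all `L`-nt
windows of the amplicon it spans. These are deliberate simplifications:
the quantity of interest — whether two independent dsRNAs can share an
off-target gene — is a worst-case sequence property, and every extra
biological filter only removes hits. Defaults are `L = 21`, `k = 3`,
word size 9.

Two target representations are supported per gene. `premrna` mode
searches the full unspliced genomic span (introns included), reflecting
evidence that the silencing machinery can engage unspliced transcripts;
`mature` mode searches spliced transcripts only. Hits are annotated
`exon`/`intron` per position; a hit straddling an exon/intron boundary
is classified intron-touching and removed by the intron filter, because
no mature transcript contains that window.

## Seed-table search

The index stores, for every 9-nt word of every target record, its exact
location. Words are 2-bit encoded (A=0, C=1, G=2, T=3, first base most
significant), giving a 4⁹ = 262,144 key space; the implementation keeps
a sorted key array with a parallel global-position array rather than a
hash table, so a lookup is two binary searches and a slice. Only the
sense strand of each record is indexed; the query is searched in both
orientations instead, which is equivalent and halves the index.
Windows containing N are skipped, not errors.

A 21-nt query splits into children at offsets 0 and 9 plus a 3-nt
remainder. For every budget split i + j ≤ k the children's Hamming
balls of radius i and j are enumerated — a variant at distance exactly
d is the word XORed with d non-zero 2-bit deltas at d distinct
positions, so the per-(word-size, d) delta masks are precomputed once
and a child's variant set is a single vectorized XOR — looked up, and
joined on *left + 9 = right*. Every candidate locus is then verified by
direct comparison of the whole window, which both settles the remainder
(budget k − i − j) and assigns the true mismatch count; loci reachable
through several (i, j) partitions collapse to one hit. Completeness
follows because a hit with child distances (a, b) and remainder r,
a + b + r ≤ k, is found by the partition i = a, j = b; soundness is the
final verification. Records are laid out in one global coordinate
system with 32-nt gaps so a join can never bridge two records.

The brute-force scan (`search_naive`, CLI `--engine naive`) is a
first-class implementation with the identical contract, used as the
independent oracle in the test suite and acceptance script. k is capped
at 4: variant enumeration grows as C(9,d)·3^d and the two-child
pigeonhole argument needs a + b ≤ k with both children only 9 nt.

## siRNA enumeration and scoring

Every `L`-window of the representative cDNA is a candidate; for
multi-isoform genes the longest mature transcript is the default
representative (a policy, selectable per transcript). Activity
filtering is a named, versioned scheme so results are reproducible:

* `none` — all candidates pass (score 0). Conservative baseline.
* `default-v1` — one point each for GC fraction in [0.30, 0.60], no
  homopolymer run ≥ 5, and A/T at sense position 19 (a proxy for the
  thermodynamic-asymmetry rule favouring antisense-strand loading);
  pass at ≥ 2 points. This is a documented stand-in, not a published
  rule set; it exists to exercise the filtering stage and can be
  replaced without touching the pipeline.

Filtering can only shrink the hit list, so cot statistics are always
also computable under `none`; the dsRNA design guarantee (below) uses
`none` unconditionally, since a "predicted inactive" siRNA may be
active after all.

## Cot-groups, clean regions, design

Hits are aggregated at gene level (any transcript or locus of gene X
counts as X; orientation does not affect membership). A cot-group is a
(source gene, off-target gene) pair with ≥ 2 distinct member starts.
Per-gene statistics: group count, maximum group size, and coverage
`100 · Σ size · L / len(cDNA)` (members counted per group, so > 100% is
possible).

Clean regions are maximal intervals containing no two member *sites*
(`[start, start+L)`) of one group; it suffices to forbid consecutive
member pairs, and the maximal intervals fall out of a sweep over the
pair constraints. A site partially overlapping a region boundary does
not count as inside: a truncated window cannot be produced from that
amplicon.

Pair design searches candidate regions anchored at member-site
boundaries (plus derived points one min/max length away, deterministically
thinned to ≤ 80 boundaries per segment), scores each ordered
non-overlapping pair by the bitwise intersection of its regions'
off-target gene masks, and returns up to `n_choices` disjoint pairs
ranked by descending combined length (ties: leftmost region 1, then
region 2). Only genes hit from ≥ 2 distinct starts can appear in both
regions of a pair, so the group-derived start→gene map is exactly
sufficient for the disjointness decision; tests re-verify every emitted
pair against full off-target sets recomputed with the naive engine.
With `avoid_utr`, regions are confined to non-UTR segments of the cDNA.
When no pair is feasible the result names the blocking off-target
genes, ordered by how many candidate pairs they invalidated. The
boundary-anchored search is a heuristic in one direction only: an
emitted pair is always valid, while a reported infeasibility means no
pair exists on the examined boundary grid.

## Randomized-genome expectation

The expected number of ≤k-mismatch matches of a random L-mer against S
scanned windows of an i.i.d. uniform genome is
`S · Σ_{i≤k} C(L,i) 3^i / 4^L` (doubled when both strands are scanned).
At L = 21, k = 3 the Hamming ball holds 37,864 of 4.4 × 10¹² words —
about 8.6 × 10⁻⁹ per window — which is why shared off-targets in real
genomes are a property of sequence relatedness, not chance. The formula
ignores edge effects and the dependence between overlapping windows; it
is validated term-by-term against exhaustive enumeration at L ≤ 8 and
by Monte-Carlo against a 1 Mb random genome.

## Synthetic fixtures

The generator emulates exactly what the analysis consumes: multi-exon
genes (random strand, UTRs at the cDNA ends, i.i.d. background of
configurable composition) laid out on a contig, written as standard
FASTA + GFF3, plus planted copies of chosen source-gene 21-mers at an
exact Hamming distance, in a chosen region class and orientation, with
a machine-readable truth table. It is not a biological genome
simulator: no codon structure, splice-site motifs, repeat families or
homologous gene pairs. Passing recovery tests therefore demonstrates
the correctness of the search and grouping machinery, not performance
on real genomes, where hit densities are far higher and dominated by
genuine sequence families.

Two facts shape the recovery assertions. First, a window shifted d nt
from a planted start still matches the planted locus whenever its d
flank comparisons cost ≤ k mismatches — always for d ≤ k with an exact
plant — so recovered member sets are supersets of the planted starts;
recovery is asserted as containment plus the requirement that every
member overlap a planted site. Second, the default fixture scale
(≈ 450–700 nt cDNAs, ≤ 10 genes) keeps the analytic background
expectation per gene pair below 0.01, so "no spurious groups" is a
meaningful assertion rather than a coin flip.

## Numerical and interface choices

* Coordinates are 0-based half-open internally, 1-based in all reports.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configurations give
  byte-identical outputs.
* Data reports (TSV/BED) contain no timestamps or engine tags, so the
  seeded and naive engines — and repeated runs — are byte-comparable;
  the resolved configuration, tool version, config hash and timestamp
  live in a sibling `run_config.json`.
* Bundle input: the gene-map TSV needs optional `exon_lens`/
  `intron_lens` columns to place introns for multi-exon genes; without
  them such genes refuse premrna-mode region labelling with a pointer
  to FASTA+GFF3 input. Single-exon genes need no extra columns.
* Problem sizes in the acceptance script (50 spaces × 200 queries for
  the oracle check; 1 Mb Monte-Carlo genome; ≤ 10-gene fixtures) were
  chosen so the whole recomputation finishes in about a minute on one
  core while every check retains its discriminating power.

## Known limitations

Gapless Hamming matching only (a bulged or G:U-wobbled site is
invisible); no miRNA-like seed-region weighting; transcript isoforms
reduce to one representative cDNA per gene for enumeration; the
activity scheme is a stand-in; the pair-design search is boundary-grid
complete, not exhaustive over all real-valued boundaries.
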