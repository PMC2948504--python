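"""Common-off-target (cot) groups, per-gene statistics, clean regions and
dsRNA pair design.

A *cot-group* is the central statistic: two or more siRNAs derived from
one source gene that all hit the same off-target gene.  Two independent,
non-overlapping dsRNAs drawn from regions that each contain a member of
the same cot-group can silence that off-target in both experiments and
so mimic an on-target phenotype.  This module:

* forms cot-groups from an off-target hit table;
* computes per-gene summary statistics (group count, maximum group
  size, and the fraction of the cDNA covered by group members);
* derives maximal "clean" intervals that never fully contain two member
  sites of any one group;
* designs pairs of dsRNA regions (default 300-800 bp) whose off-target
  gene sets are provably disjoint, optionally avoiding UTRs;
* gives the closed-form expected number of <=k-mismatch matches of a
  random L-mer against a random genome (the Hamming-ball expectation).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import pandas as pd

from .genome import GeneSequences, Interval, ValidationError
from .search import DEFAULT_SIRNA_LENGTH
from .sirna import OffTargetHit

__all__ = [
    "CotGroup",
    "CotStats",
    "DsRNAPair",
    "DesignResult",
    "form_cot_groups",
    "cot_stats",
    "clean_regions",
    "design_dsrna_pairs",
    "hamming_ball_size",
    "expected_random_matches",
    "groups_table",
    "cot_report_row",
]

DEFAULT_MIN_DSRNA = 300
DEFAULT_MAX_DSRNA = 800


@dataclass(frozen=True)
class CotGroup:
    """siRNA start sites on one source gene sharing one off-target gene."""

    source_gene: str
    offtarget_gene: str
    members: tuple[int, ...]  # sorted distinct cDNA start offsets

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a cot-group needs >= 2 members")
        if list(self.members) != sorted(set(self.members)):
            raise ValidationError("members must be sorted and distinct")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CotStats:
    """Per-gene cot summary."""

    gene: str
    n_cot_groups: int
    max_group_size: int
    coverage_percent: float  # 100 * sum(size)*L / gene_length; may exceed 100
    gene_length: int


@dataclass(frozen=True)
class DsRNAPair:
    """Two non-overlapping cDNA regions with disjoint off-target gene sets."""

    gene: str
    region1: Interval
    region2: Interval
    shared_offtargets: tuple[str, ...] = ()

    @property
    def combined_length(self) -> int:
        return (self.region1[1] - self.region1[0]) + (self.region2[1] - self.region2[0])


@dataclass
class DesignResult:
    """Outcome of dsRNA pair design: pairs, or a structured infeasibility report."""

    gene: str
    pairs: list[DsRNAPair]
    feasible: bool
    blocking_genes: tuple[str, ...] = ()
    options: dict = field(default_factory=dict)


def form_cot_groups(hits: Iterable[OffTargetHit]) -> list[CotGroup]:
    """Group hits by (source gene, off-target gene); keep groups of >=2 starts.

    Hits are aggregated at gene level: several transcripts or loci of the
    same off-target gene collapse, and a start counts once per off-target
    gene regardless of orientation.
    """
    members: dict[tuple[str, str], set[int]] = {}
    for h in hits:
        members.setdefault((h.source_gene, h.target_gene), set()).add(h.sirna_start)
    out = [
        CotGroup(src, tgt, tuple(sorted(starts)))
        for (src, tgt), starts in members.items()
        if len(starts) >= 2
    ]
    out.sort(key=lambda g: (g.source_gene, g.offtarget_gene))
    return out


def cot_stats(
    groups: Sequence[CotGroup],
    gene: str,
    gene_length: int,
    L: int = DEFAULT_SIRNA_LENGTH,
) -> CotStats:
    """Summary statistics for one source gene's cot-groups.

    Coverage multiplies the total member count by the siRNA length and
    divides by the cDNA length; overlapping members are counted per
    group, so values above 100% are possible for repeat-rich genes.
    """
    if gene_length < L:
        raise ValidationError(f"gene_length {gene_length} < siRNA length {L}")
    for g in groups:
        if g.source_gene != gene:
            raise ValidationError(
                f"group for {g.source_gene!r} passed to stats of {gene!r}"
            )
    total_members = sum(g.size for g in groups)
    return CotStats(
        gene=gene,
        n_cot_groups=len(groups),
        max_group_size=max((g.size for g in groups), default=0),
        coverage_percent=100.0 * total_members * L / gene_length,
        gene_length=gene_length,
    )


# ---------------------------------------------------------------------------
# clean regions
# ---------------------------------------------------------------------------


def _pair_constraints(groups: Sequence[CotGroup]) -> list[tuple[int, int]]:
    """Consecutive member pairs (m_i, m_{i+1}) over all groups.

    An interval fully containing two member sites of a group necessarily
    contains a consecutive pair, so these suffice as constraints.
    """
    cons = set()
    for g in groups:
        for a, b in zip(g.members, g.members[1:]):
            cons.add((a, b))
    return sorted(cons)


def clean_regions(
    groups: Sequence[CotGroup],
    gene_length: int,
    L: int = DEFAULT_SIRNA_LENGTH,
    utr_mask: Sequence[Interval] | None = None,
) -> list[Interval]:
    """Maximal intervals that never fully contain two members of one group.

    A member site is the window [start, start+L); an interval [S, E) is
    dirty iff S <= m_i and E >= m_j + L for two members m_i < m_j of the
    same group.  With ``utr_mask`` the result is additionally intersected
    with the complement of the masked intervals.
    """
    cons = _pair_constraints(groups)
    if not cons:
        regions = [(0, gene_length)]
    else:
        starts = sorted({0, *(a + 1 for a, _ in cons)})
        regions = []
        prev_end = -1
        for s in starts:
            if s >= gene_length:
                continue
            active = [b + L - 1 for a, b in cons if a >= s]
            e = min([gene_length, *active])
            if e > s and e > prev_end:
                regions.append((s, e))
                prev_end = e
    if utr_mask:
        regions = _subtract_intervals(regions, sorted(utr_mask))
    return regions


def _subtract_intervals(
    regions: Sequence[Interval], mask: Sequence[Interval]
) -> list[Interval]:
    out: list[Interval] = []
    for s, e in regions:
        cur = s
        for ms, me in mask:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# dsRNA pair design
# ---------------------------------------------------------------------------


def _site_gene_masks(
    groups: Sequence[CotGroup],
) -> tuple[list[int], list[int], dict[str, int]]:
    """Sorted member starts with off-target gene bitmasks."""
    gene_bit: dict[str, int] = {}
    site_mask: dict[int, int] = {}
    for g in groups:
        bit = gene_bit.setdefault(g.offtarget_gene, len(gene_bit))
        for m in g.members:
            site_mask[m] = site_mask.get(m, 0) | (1 << bit)
    starts = sorted(site_mask)
    return starts, [site_mask[s] for s in starts], gene_bit


def _region_mask(
    starts: list[int], masks: list[int], region: Interval, L: int
) -> int:
    """OR of gene masks over member sites wholly inside the region.

    A site partially overlapping the boundary is NOT in the region: its
    full L-mer cannot arise from a dsRNA amplicon that truncates it.
    """
    lo = bisect_left(starts, region[0])
    hi = bisect_right(starts, region[1] - L)
    out = 0
    for i in range(lo, hi):
        out |= masks[i]
    return out


def _candidate_boundaries(
    seg: Interval,
    starts: list[int],
    L: int,
    min_len: int,
    max_len: int,
    cap: int = 80,
) -> list[int]:
    base = {seg[0], seg[1]}
    for s in starts:
        if seg[0] <= s <= seg[1]:
            base.add(s)
        if seg[0] <= s + L <= seg[1]:
            base.add(s + L)
    # derived points let complementary region pairs meet at a boundary
    pts = set(base)
    for p in base:
        for q in (p + min_len, p + max_len, p - min_len, p - max_len):
            if seg[0] <= q <= seg[1]:
                pts.add(q)
    out = sorted(pts)
    if len(out) > cap:  # thin deterministically, keeping the segment ends
        step = (len(out) - 1) / (cap - 1)
        kept = {out[min(len(out) - 1, int(round(i * step)))] for i in range(cap)}
        kept.update((out[0], out[-1]))
        out = sorted(kept)
    return out


def design_dsrna_pairs(
    gene: GeneSequences | str,
    groups: Sequence[CotGroup],
    gene_length: int | None = None,
    L: int = DEFAULT_SIRNA_LENGTH,
    min_len: int = DEFAULT_MIN_DSRNA,
    max_len: int = DEFAULT_MAX_DSRNA,
    n_choices: int = 5,
    avoid_utr: bool = False,
    utr_intervals: Sequence[Interval] | None = None,
) -> DesignResult:
    """Design up to ``n_choices`` non-overlapping dsRNA region pairs whose
    off-target gene sets are disjoint.

    ``groups`` must come from scheme "none" hits (every enumerable siRNA
    counts): a predicted-inactive siRNA may be active after all, so the
    disjointness guarantee is made against the full window set.  Only
    genes hit from >=2 distinct starts can ever appear in both regions
    of a pair, so the cot-group content fully determines disjointness.

    Pairs are ranked by descending combined length, ties broken by the
    leftmost region1 then region2 start.  When no feasible pair exists
    the result lists the blocking off-target genes.
    """
    if isinstance(gene, GeneSequences):
        gene_id = gene.gene_id
        glen = len(gene.cdna)
        utrs = gene.utr_intervals() if avoid_utr and utr_intervals is None else utr_intervals
    else:
        gene_id = gene
        if gene_length is None:
            raise ValidationError("gene_length required when gene is given by id")
        glen = gene_length
        utrs = utr_intervals
    options = {
        "min_len": min_len,
        "max_len": max_len,
        "n_choices": n_choices,
        "avoid_utr": avoid_utr,
        "L": L,
    }

    segments: list[Interval] = [(0, glen)]
    if avoid_utr and utrs:
        segments = _subtract_intervals(segments, sorted(utrs))
    segments = [s for s in segments if s[1] - s[0] >= min_len]
    if not segments or glen < 2 * min_len:
        return DesignResult(gene_id, [], False, (), options)

    starts, masks, gene_bit = _site_gene_masks(groups)
    bit_gene = {b: g for g, b in gene_bit.items()}

    # candidate regions: anchored left/right at member-site breakpoints
    regions: set[Interval] = set()
    for seg in segments:
        pts = _candidate_boundaries(seg, starts, L, min_len, max_len)
        for a in pts:
            b_full = min(a + max_len, seg[1])
            if b_full - a >= min_len:
                regions.add((a, b_full))
                regions.add((a, a + min_len))
        for e in pts:
            a = max(e - max_len, seg[0])
            if e - a >= min_len:
                regions.add((a, e))
    region_list = sorted(regions)
    region_mask = {r: _region_mask(starts, masks, r, L) for r in region_list}

    valid: list[tuple[int, int, int, Interval, Interval]] = []
    blockers: dict[str, int] = {}
    for i, r1 in enumerate(region_list):
        for r2 in region_list:
            if r2[0] < r1[1] or r1 == r2:
                continue
            inter = region_mask[r1] & region_mask[r2]
            if inter == 0:
                combined = (r1[1] - r1[0]) + (r2[1] - r2[0])
                valid.append((-combined, r1[0], r2[0], r1, r2))
            else:
                b = 0
                while inter:
                    if inter & 1:
                        g = bit_gene[b]
                        blockers[g] = blockers.get(g, 0) + 1
                    inter >>= 1
                    b += 1

    if not valid:
        blocking = tuple(sorted(blockers, key=lambda g: (-blockers[g], g)))
        return DesignResult(gene_id, [], False, blocking, options)

    valid.sort()
    pairs: list[DsRNAPair] = []
    seen: set[tuple[Interval, Interval]] = set()
    for _, _, _, r1, r2 in valid:
        if (r1, r2) in seen:
            continue
        seen.add((r1, r2))
        pairs.append(DsRNAPair(gene_id, r1, r2))
        if len(pairs) >= n_choices:
            break
    return DesignResult(gene_id, pairs, True, (), options)


# ---------------------------------------------------------------------------
# randomized-genome expectation
# ---------------------------------------------------------------------------


def hamming_ball_size(L: int, k: int) -> int:
    """Number of distinct L-mers within Hamming distance k of a fixed L-mer."""
    if not (0 <= k <= L):
        raise ValueError(f"k {k} outside [0, {L}]")
    return sum(comb(L, i) * 3**i for i in range(k + 1))


def expected_random_matches(
    L: int, k: int, genome_size: int, both_strands: bool = True
) -> float:
    """Expected <=k-mismatch matches of a random L-mer vs an i.i.d. genome.

    E = S * sum_{i<=k} C(L,i) 3^i / 4^L with S the number of scanned
    windows (doubled when both strands are searched).  An approximation:
    edge effects and overlap dependence between windows are ignored.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    windows = genome_size * (2 if both_strands else 1)
    return windows * hamming_ball_size(L, k) / 4**L


# ---------------------------------------------------------------------------
# report helpers
# ---------------------------------------------------------------------------


def groups_table(groups: Sequence[CotGroup]) -> pd.DataFrame:
    """Groups TSV: member starts are reported 1-based."""
    return pd.DataFrame(
        [
            {
                "source_gene": g.source_gene,
                "offtarget_gene": g.offtarget_gene,
                "size": g.size,
                "member_starts": ",".join(str(m + 1) for m in g.members),
            }
            for g in groups
        ],
        columns=["source_gene", "offtarget_gene", "size", "member_starts"],
    )


def cot_report_row(
    stats: CotStats, mode: str, scheme: str
) -> dict:
    return {
        "gene": stats.gene,
        "n_cot_groups": stats.n_cot_groups,
        "max_group_size": stats.max_group_size,
        "coverage_percent": round(stats.coverage_percent, 4),
        "gene_length": stats.gene_length,
        "mode": mode,
        "scheme": scheme,
    }
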