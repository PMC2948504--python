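"""siRNA enumeration, activity scoring, and gene-level off-target mapping.

Every 21-nt window of a gene's cDNA is a potential siRNA (DICER products
from a long dsRNA tile the amplicon); each window is scored by a named,
pluggable activity scheme, and every retained siRNA is searched against
the target space (pre-mRNA or mature mode) in both orientations for
gapless alignments with up to k mismatches.  Hits to the source gene
itself are removed; remaining hits are annotated with the off-target
gene and with the exon/intron region they fall in.

Scoring schemes
---------------
``none``        every candidate passes (score 0) -- used for conservative
                cot statistics and always for dsRNA-pair disjointness.
``default-v1``  a documented stand-in filter (the original activity
                table is not public): one point each for (a) GC fraction
                in [0.30, 0.60], (b) no homopolymer run >= 5, (c) A or T
                at sense position 19 of the 21-mer (5' antisense-end
                thermodynamic asymmetry proxy); pass at >= 2 points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .genome import ConfigurationError
from .index import SeedIndex, TargetSpace
from .search import (
    DEFAULT_MAX_MISMATCHES,
    DEFAULT_SIRNA_LENGTH,
    MatchHit,
    search,
    search_naive,
)

__all__ = [
    "SiRNACandidate",
    "OffTargetHit",
    "SCHEMES",
    "score_sirna",
    "enumerate_sirnas",
    "map_offtargets",
    "filter_intron_hits",
    "hits_table",
]

REGION_EXON = "exon"
REGION_INTRON = "intron"


@dataclass(frozen=True)
class SiRNACandidate:
    """One 21-nt window of a source gene's cDNA."""

    source_gene: str
    start: int  # 0-based offset on the cDNA
    sequence: str
    score: float = 0.0
    passed_filter: bool = True


@dataclass(frozen=True)
class OffTargetHit:
    """A gapless <=k-mismatch alignment of a source siRNA to another gene."""

    source_gene: str
    sirna_start: int
    sirna_sequence: str
    score: float
    target_gene: str
    seq_id: str
    offset: int
    mismatches: int
    orientation: str
    region: str  # 'exon' | 'intron'

    def key(self) -> tuple:
        return (
            self.source_gene,
            self.sirna_start,
            self.seq_id,
            self.offset,
            self.orientation,
        )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _scheme_none(seq: str) -> tuple[float, bool]:
    return 0.0, True


def _scheme_default_v1(seq: str) -> tuple[float, bool]:
    points = 0
    if 0.30 <= _gc_fraction(seq) <= 0.60:
        points += 1
    if _max_homopolymer_run(seq) < 5:
        points += 1
    if len(seq) >= 19 and seq[18] in "AT":
        points += 1
    return float(points), points >= 2


SCHEMES: dict[str, Callable[[str], tuple[float, bool]]] = {
    "none": _scheme_none,
    "default-v1": _scheme_default_v1,
}


def score_sirna(candidate: SiRNACandidate | str, scheme: str = "default-v1") -> tuple[float, bool]:
    """Score one siRNA under a named scheme; returns (score, passed)."""
    if scheme not in SCHEMES:
        raise ConfigurationError(
            f"unknown scoring scheme {scheme!r}; available: {sorted(SCHEMES)}"
        )
    seq = candidate if isinstance(candidate, str) else candidate.sequence
    return SCHEMES[scheme](seq)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def enumerate_sirnas(
    cdna: str,
    source_gene: str,
    L: int = DEFAULT_SIRNA_LENGTH,
    scheme: str = "none",
) -> list[SiRNACandidate]:
    """All L-nt windows of a cDNA, scored; windows containing N are skipped."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scoring scheme {scheme!r}")
    if len(cdna) < L:
        warnings.warn(
            f"cDNA of {source_gene} shorter than siRNA length {L}; no candidates",
            stacklevel=2,
        )
        return []
    score_fn = SCHEMES[scheme]
    out: list[SiRNACandidate] = []
    for start in range(len(cdna) - L + 1):
        seq = cdna[start : start + L]
        if "N" in seq:
            continue
        score, passed = score_fn(seq)
        out.append(SiRNACandidate(source_gene, start, seq, score, passed))
    return out


# ---------------------------------------------------------------------------
# off-target mapping
# ---------------------------------------------------------------------------


def _hit_region(ts: TargetSpace, hit: MatchHit, L: int) -> str:
    rec = ts.record(hit.seq_id)
    if rec.exon_mask is None:
        return REGION_EXON
    window = rec.exon_mask[hit.offset : hit.offset + L]
    return REGION_EXON if bool(window.all()) else REGION_INTRON


def map_offtargets(
    cands: Iterable[SiRNACandidate],
    idx: SeedIndex | None,
    ts: TargetSpace,
    k: int = DEFAULT_MAX_MISMATCHES,
    mode: str | None = None,
    engine: str = "seeded",
    both_query_orientations: bool = True,
) -> list[OffTargetHit]:
    """Map every passing candidate's off-target hits, excluding the source gene.

    ``engine`` selects the seed-join search ("seeded") or the brute-force
    scan ("naive"); both produce identical output.
    """
    if mode is not None and mode != ts.mode:
        raise ConfigurationError(
            f"requested mode {mode!r} but target space is {ts.mode!r}"
        )
    if engine not in ("seeded", "naive"):
        raise ConfigurationError(f"unknown engine {engine!r}")
    if engine == "seeded":
        if idx is None or idx.ts is not ts:
            raise ConfigurationError("seed index does not match the target space")

    out: list[OffTargetHit] = []
    for cand in cands:
        if not cand.passed_filter:
            continue
        if engine == "seeded":
            hits = search(cand.sequence, idx, ts, k, both_query_orientations)
        else:
            hits = search_naive(cand.sequence, ts, k, both_query_orientations)
        L = len(cand.sequence)
        for h in hits:
            target_gene = ts.gene_of(h.seq_id)
            if target_gene == cand.source_gene:
                continue
            out.append(
                OffTargetHit(
                    source_gene=cand.source_gene,
                    sirna_start=cand.start,
                    sirna_sequence=cand.sequence,
                    score=cand.score,
                    target_gene=target_gene,
                    seq_id=h.seq_id,
                    offset=h.offset,
                    mismatches=h.mismatches,
                    orientation=h.orientation,
                    region=_hit_region(ts, h, L),
                )
            )
    out.sort(key=OffTargetHit.key)
    return out


def filter_intron_hits(hits: Sequence[OffTargetHit]) -> list[OffTargetHit]:
    """Keep only hits whose aligned window lies entirely in exonic sequence.

    Hits straddling an exon/intron boundary are classified intron-touching
    at annotation time and are removed here: a straddling site does not
    exist in any mature transcript.
    """
    return [h for h in hits if h.region == REGION_EXON]


def hits_table(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    """Detailed hit table with 1-based positions for TSV export."""
    return pd.DataFrame(
        [
            {
                "source_gene": h.source_gene,
                "sirna_start": h.sirna_start + 1,
                "sequence": h.sirna_sequence,
                "score": h.score,
                "target_gene": h.target_gene,
                "seq_id": h.seq_id,
                "target_pos": h.offset + 1,
                "mismatches": h.mismatches,
                "orientation": h.orientation,
                "region": h.region,
            }
            for h in hits
        ],
        columns=[
            "source_gene",
            "sirna_start",
            "sequence",
            "score",
            "target_gene",
            "seq_id",
            "target_pos",
            "mismatches",
            "orientation",
            "region",
        ],
    )
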