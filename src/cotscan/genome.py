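"""Gene models and per-gene RNA sequences.

Reads a genome FASTA plus GFF3 gene models (gene -> mRNA -> exon /
five_prime_UTR / three_prime_UTR) and derives, for every gene, its two
target representations used throughout the pipeline:

* ``premrna`` -- the unspliced, strand-corrected genomic span of the gene
  (introns included), with a per-position exon/intron map;
* ``mature`` -- one spliced, strand-corrected cDNA per transcript, with a
  per-position CDS/UTR5/UTR3 map.

All coordinates are 0-based half-open internally; user-facing reports
convert to 1-based inclusive at the formatting boundary.

Alternatively a pre-built "bundle" (mature FASTA + pre-mRNA FASTA + a
gene-map TSV) can be loaded without any GFF3.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "GffParseError",
    "ValidationError",
    "ConfigurationError",
    "Interval",
    "TranscriptModel",
    "GeneModel",
    "GeneSequences",
    "reverse_complement",
    "load_gene_models",
    "extract_sequences",
    "load_bundle",
]


class GffParseError(ValueError):
    """Structural problem in a GFF3 file (e.g. dangling Parent link)."""


class ValidationError(ValueError):
    """An input violates a model invariant (bounds, alphabet, containment)."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration."""


Interval = tuple[int, int]  # 0-based half-open

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA_ALPHABET = frozenset("ACGTNacgtn")


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case-preserving; N -> N)."""
    bad = set(s) - _DNA_ALPHABET
    if bad:
        raise ValidationError(f"non-ACGTN characters in sequence: {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _check_intervals_sorted_disjoint(ivs: Iterable[Interval], what: str) -> None:
    prev_end = None
    for s, e in ivs:
        if e <= s:
            raise ValidationError(f"{what}: empty or inverted interval ({s},{e})")
        if prev_end is not None and s < prev_end:
            raise ValidationError(f"{what}: intervals overlap or are unsorted at ({s},{e})")
        prev_end = e


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: its exons and (possibly empty) UTR intervals.

    Exons are genomic 0-based half-open intervals stored in ascending
    genomic order; 5'->3' assembly is strand-aware downstream.
    """

    transcript_id: str
    exons: tuple[Interval, ...]
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        _check_intervals_sorted_disjoint(self.exons, f"transcript {self.transcript_id} exons")
        for kind, ivs in (("utr5", self.utr5), ("utr3", self.utr3)):
            for s, e in ivs:
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise ValidationError(
                        f"transcript {self.transcript_id}: {kind} interval ({s},{e}) "
                        "not contained in any exon"
                    )

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: genomic span, strand and its transcripts."""

    gene_id: str
    chrom: str
    strand: str
    span: Interval
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        s0, e0 = self.span
        if e0 <= s0:
            raise ValidationError(f"gene {self.gene_id}: empty span")
        for t in self.transcripts:
            for s, e in t.exons:
                if s < s0 or e > e0:
                    raise ValidationError(
                        f"gene {self.gene_id}: exon ({s},{e}) of {t.transcript_id} "
                        f"outside gene span ({s0},{e0})"
                    )

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class GeneSequences:
    """Strand-corrected sequences of one gene plus region maps.

    ``premrna`` runs 5'->3' in the gene's orientation and covers the whole
    genomic span; ``premrna_exon`` marks, per position, whether it is
    exonic in *any* transcript.  ``mature`` maps transcript_id to the
    spliced cDNA; ``mature_regions`` labels each cDNA position 'CDS',
    'UTR5' or 'UTR3'.
    """

    gene_id: str
    strand: str
    premrna: str
    premrna_exon: np.ndarray | None
    mature: dict[str, str]
    mature_regions: dict[str, np.ndarray]
    default_transcript: str

    @property
    def cdna(self) -> str:
        """The representative (longest) mature transcript sequence."""
        return self.mature[self.default_transcript]

    @property
    def cdna_regions(self) -> np.ndarray:
        return self.mature_regions[self.default_transcript]

    def utr_intervals(self, transcript_id: str | None = None) -> list[Interval]:
        """UTR-labelled intervals on the mature cDNA, 0-based half-open."""
        labels = self.mature_regions[transcript_id or self.default_transcript]
        out: list[Interval] = []
        i, n = 0, len(labels)
        while i < n:
            if labels[i] != "CDS":
                j = i
                while j < n and labels[j] == labels[i]:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out


# ---------------------------------------------------------------------------
# GFF3 + FASTA loading
# ---------------------------------------------------------------------------

_UTR5_TYPES = ("five_prime_UTR",)
_UTR3_TYPES = ("three_prime_UTR",)


def load_gene_models(fasta_path: str | Path, gff_path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models and validate them against the FASTA contigs.

    Raises :class:`GffParseError` for dangling Parent links and
    :class:`ValidationError` for coordinate violations.
    """
    import gffutils
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta_path))
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    known_ids = {f.id for f in db.all_features()}
    for ftype in ("mRNA", "exon", *_UTR5_TYPES, *_UTR3_TYPES):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents:
                raise GffParseError(f"{ftype} feature {f.id or f} has no Parent attribute")
            for pid in parents:
                if pid not in known_ids:
                    raise GffParseError(
                        f"{ftype} feature {f.id or f} references unknown Parent {pid!r}"
                    )

    contigs = set(fa.keys())
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.seqid not in contigs:
            raise ValidationError(f"gene {g.id}: contig {g.seqid!r} not in FASTA")
        span: Interval = (g.start - 1, g.end)
        if span[1] > len(fa[g.seqid]):
            raise ValidationError(f"gene {g.id}: span exceeds contig {g.seqid} length")
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = sorted((f.start - 1, f.end) for f in db.children(t, featuretype="exon"))
            utr5 = sorted(
                (f.start - 1, f.end)
                for ft in _UTR5_TYPES
                for f in db.children(t, featuretype=ft)
            )
            utr3 = sorted(
                (f.start - 1, f.end)
                for ft in _UTR3_TYPES
                for f in db.children(t, featuretype=ft)
            )
            transcripts.append(
                TranscriptModel(t.id, tuple(exons), tuple(utr5), tuple(utr3))
            )
        if not transcripts:
            raise GffParseError(f"gene {g.id}: no mRNA children")
        genes.append(GeneModel(g.id, g.seqid, g.strand, span, tuple(transcripts)))
    return genes


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from pyfaidx.Fasta or a plain dict."""
    seq = genome[chrom][start:end]
    return str(seq).upper()


def _contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_sequences(gene: GeneModel, genome) -> GeneSequences:
    """Derive the mature and pre-mRNA sequences (5'->3') of one gene.

    ``genome`` may be a :class:`pyfaidx.Fasta` handle or any mapping of
    contig name to sequence string.
    """
    s0, e0 = gene.span
    if s0 < 0 or e0 > _contig_length(genome, gene.chrom):
        raise ValidationError(f"gene {gene.gene_id}: span outside contig bounds")
    raw = _fetch(genome, gene.chrom, s0, e0)
    bad = set(raw) - set("ACGTN")
    if bad:
        raise ValidationError(f"gene {gene.gene_id}: non-ACGTN characters {sorted(bad)!r}")

    minus = gene.strand == "-"
    premrna = reverse_complement(raw) if minus else raw

    mask = np.zeros(e0 - s0, dtype=bool)
    for t in gene.transcripts:
        for s, e in t.exons:
            mask[s - s0 : e - s0] = True
    premrna_exon = mask[::-1].copy() if minus else mask

    mature: dict[str, str] = {}
    regions: dict[str, np.ndarray] = {}
    for t in gene.transcripts:
        plus_seq = "".join(raw[s - s0 : e - s0] for s, e in t.exons)
        genomic_pos = np.concatenate([np.arange(s, e) for s, e in t.exons])
        if minus:
            seq = reverse_complement(plus_seq)
            genomic_pos = genomic_pos[::-1]
        else:
            seq = plus_seq
        labels = np.full(len(seq), "CDS", dtype="U4")
        for name, ivs in (("UTR5", t.utr5), ("UTR3", t.utr3)):
            for us, ue in ivs:
                labels[(genomic_pos >= us) & (genomic_pos < ue)] = name
        mature[t.transcript_id] = seq
        regions[t.transcript_id] = labels

    default = max(mature, key=lambda tid: (len(mature[tid]), tid))
    return GeneSequences(
        gene_id=gene.gene_id,
        strand=gene.strand,
        premrna=premrna,
        premrna_exon=premrna_exon,
        mature=mature,
        mature_regions=regions,
        default_transcript=default,
    )


# ---------------------------------------------------------------------------
# Bundle input (pre-extracted sequences, no GFF3)
# ---------------------------------------------------------------------------


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_bundle(
    mature_fasta: str | Path, premrna_fasta: str | Path, genemap_tsv: str | Path
) -> list[GeneSequences]:
    """Load a transcriptome bundle: mature + pre-mRNA FASTA and a gene map.

    The gene map is a TSV with columns ``gene_id, transcript_id, n_exons,
    utr5_len, utr3_len`` plus optional ``exon_lens`` / ``intron_lens``
    (comma-joined 5'->3' lengths).  Without the optional columns the
    exon/intron layout of a multi-exon gene is underdetermined, so such
    genes are loaded with ``premrna_exon=None`` and refuse premrna-mode
    region labelling downstream.
    """
    mat = _read_fasta(mature_fasta)
    pre = _read_fasta(premrna_fasta)

    out: list[GeneSequences] = []
    with open(genemap_tsv, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gid = row["gene_id"]
            tid = row["transcript_id"]
            n_exons = int(row["n_exons"])
            utr5_len = int(row["utr5_len"])
            utr3_len = int(row["utr3_len"])
            mseq = mat.get(f"{gid}|{tid}") or mat.get(gid)
            pseq = pre.get(gid)
            if mseq is None or pseq is None:
                raise ValidationError(f"bundle: missing FASTA record for gene {gid}")
            if n_exons == 1:
                if mseq != pseq:
                    raise ValidationError(
                        f"bundle: single-exon gene {gid} has mature != premrna"
                    )
                exon_mask = np.ones(len(pseq), dtype=bool)
            elif row.get("exon_lens") and row.get("intron_lens"):
                exon_lens = [int(x) for x in row["exon_lens"].split(",")]
                intron_lens = [int(x) for x in row["intron_lens"].split(",")]
                if len(exon_lens) != n_exons or len(intron_lens) != n_exons - 1:
                    raise ValidationError(f"bundle: gene {gid}: inconsistent exon/intron lens")
                if sum(exon_lens) + sum(intron_lens) != len(pseq):
                    raise ValidationError(f"bundle: gene {gid}: lens do not sum to premrna")
                exon_mask = np.zeros(len(pseq), dtype=bool)
                pos = 0
                for i, el in enumerate(exon_lens):
                    exon_mask[pos : pos + el] = True
                    pos += el
                    if i < n_exons - 1:
                        pos += intron_lens[i]
            else:
                exon_mask = None
            labels = np.full(len(mseq), "CDS", dtype="U4")
            if utr5_len:
                labels[:utr5_len] = "UTR5"
            if utr3_len:
                labels[len(mseq) - utr3_len :] = "UTR3"
            out.append(
                GeneSequences(
                    gene_id=gid,
                    strand="+",
                    premrna=pseq,
                    premrna_exon=exon_mask,
                    mature={tid: mseq},
                    mature_regions={tid: labels},
                    default_transcript=tid,
                )
            )
    return out
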