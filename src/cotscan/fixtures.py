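"""Deterministic synthetic genomes with planted off-target structure.

Generates a small multi-gene genome (FASTA + GFF3) in which chosen
21-mers of a source gene's cDNA are copied -- with an exact number of
mismatches, in either orientation -- into exon, intron or UTR sequence
of other genes.  The planted copies are the ground truth for recovery
tests: the pipeline must find exactly the planted cot-groups and, on
background this small, nothing else.

Background sequence is i.i.d. by the given base composition, matching
the randomized-genome assumption behind the analytic expectation in
:func:`cotscan.cot.expected_random_matches`.  Identical specs (including
the seed) produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GeneSequences,
    Interval,
    TranscriptModel,
    ValidationError,
    extract_sequences,
    reverse_complement,
)
from .search import DEFAULT_SIRNA_LENGTH

__all__ = [
    "GenerationError",
    "PlantSpec",
    "FixtureSpec",
    "Fixture",
    "mutate_with_hamming",
    "generate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(ValueError):
    """A fixture spec cannot be realized (e.g. target region too short)."""


@dataclass(frozen=True)
class PlantSpec:
    """Copy source-gene 21-mers into a region of another gene.

    ``source_starts[i]`` is a 0-based cDNA offset; the copied window is
    mutated to Hamming distance exactly ``mismatches_each[i]`` and
    written into the target gene's ``target_region`` ('exon' = coding
    exon, 'intron', or 'utr'), reverse-complemented when ``orientation``
    is 'revcomp'.
    """

    source_gene: int
    source_starts: tuple[int, ...]
    target_gene: int
    target_region: str = "exon"
    mismatches_each: tuple[int, ...] = ()
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if self.target_region not in ("exon", "intron", "utr"):
            raise ValidationError(f"unknown target_region {self.target_region!r}")
        if self.orientation not in ("sense", "revcomp"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.mismatches_each and len(self.mismatches_each) != len(self.source_starts):
            raise ValidationError("mismatches_each must match source_starts in length")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic genome.

    Defaults give ~8 genes of 400-700 nt mature length with 2-3 exons,
    40-nt UTRs and uniform base composition: small enough that the
    analytic background expectation per gene pair stays below 0.01 at
    L=21, k=3, so planted structure is recovered without noise.
    """

    seed: int = 0
    n_genes: int = 8
    gene_length_range: tuple[int, int] = (400, 700)  # mature (cDNA) length
    exons_per_gene_range: tuple[int, int] = (2, 3)
    intron_length_range: tuple[int, int] = (80, 160)
    utr_lengths: tuple[int, int] = (40, 40)
    planted_repeats: tuple[PlantSpec, ...] = ()
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sirna_length: int = DEFAULT_SIRNA_LENGTH
    intergenic_length: int = 100
    contig: str = "chr1"


@dataclass
class Fixture:
    """Generated genome plus models, sequences and the planted truth table."""

    spec: FixtureSpec
    contigs: dict[str, str]
    genes: list[GeneModel]
    sequences: dict[str, GeneSequences]
    truth: pd.DataFrame
    paths: dict[str, Path] | None = None

    def gene_id(self, i: int) -> str:
        return self.genes[i].gene_id

    def planted_cot_truth(self) -> set[tuple[str, str, tuple[int, ...]]]:
        """Expected cot-groups: (source gene, target gene, sorted member starts)."""
        expected: dict[tuple[str, str], set[int]] = {}
        for row in self.truth.itertuples():
            expected.setdefault((row.source_gene, row.target_gene), set()).add(
                row.source_start
            )
        return {
            (s, t, tuple(sorted(m)))
            for (s, t), m in expected.items()
            if len(m) >= 2
        }


def mutate_with_hamming(
    s: str, m: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> str:
    """A sequence at Hamming distance exactly m from s (deterministic by seed)."""
    if m > len(s):
        raise ValidationError(f"cannot place {m} mismatches in {len(s)} nt")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, np.uint8)
    for b, c in zip(b"ACGT", range(4)):
        lut[b] = c
    vals = lut[codes]
    if (vals == 255).any():
        raise ValidationError("mutate_with_hamming requires pure ACGT input")
    positions = rng.choice(len(s), size=m, replace=False)
    deltas = rng.integers(1, 4, size=m)  # XOR by 1..3 always changes the base
    vals[positions] ^= deltas.astype(np.uint8)
    return _BASES[vals].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# structural plan per gene
# ---------------------------------------------------------------------------


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    utr5_len: int
    utr3_len: int
    premrna: np.ndarray  # mutable uint8 ASCII array, gene 5'->3'
    used: list[Interval] = field(default_factory=list)

    @property
    def mature_len(self) -> int:
        return sum(self.exon_lens)

    def exon_intervals_pre(self) -> list[Interval]:
        """Exon intervals in gene-oriented pre-mRNA coordinates."""
        out, pos = [], 0
        for i, el in enumerate(self.exon_lens):
            out.append((pos, pos + el))
            pos += el
            if i < len(self.intron_lens):
                pos += self.intron_lens[i]
        return out

    def intron_intervals_pre(self) -> list[Interval]:
        out, pos = [], 0
        for i, el in enumerate(self.exon_lens):
            pos += el
            if i < len(self.intron_lens):
                out.append((pos, pos + self.intron_lens[i]))
                pos += self.intron_lens[i]
        return out

    def mat2pre(self) -> np.ndarray:
        """Pre-mRNA coordinate of every mature position (5'->3')."""
        return np.concatenate(
            [np.arange(s, e) for s, e in self.exon_intervals_pre()]
        )

    def region_intervals(self, region: str, L: int) -> list[Interval]:
        """Candidate pre-mRNA intervals of a region type, each >= L long."""
        m2p = self.mat2pre()
        if region == "intron":
            ivs = self.intron_intervals_pre()
        elif region == "utr":
            ivs = []
            if self.utr5_len:
                ivs.append((int(m2p[0]), int(m2p[self.utr5_len - 1]) + 1))
            if self.utr3_len:
                ivs.append(
                    (int(m2p[self.mature_len - self.utr3_len]), int(m2p[-1]) + 1)
                )
        else:  # coding exon: exonic minus UTR, split at introns
            cds = m2p[self.utr5_len : self.mature_len - self.utr3_len]
            ivs = _contiguous_runs(cds)
        return [iv for iv in ivs if iv[1] - iv[0] >= L]


def _contiguous_runs(positions: np.ndarray) -> list[Interval]:
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(positions) - 1]])
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def _plan_mature(plan: _GenePlan) -> str:
    parts = [plan.premrna[s:e] for s, e in plan.exon_intervals_pre()]
    return np.concatenate(parts).tobytes().decode("ascii")


def _random_dna(rng: np.random.Generator, n: int, p: tuple[float, ...]) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=list(p))]


def _build_plan(spec: FixtureSpec, rng: np.random.Generator, i: int) -> _GenePlan:
    L = spec.sirna_length
    utr5, utr3 = spec.utr_lengths
    mat_len = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
    min_exon = max(utr5, utr3) + L + 10
    n_ex = int(
        rng.integers(spec.exons_per_gene_range[0], spec.exons_per_gene_range[1] + 1)
    )
    while n_ex > 1 and mat_len < n_ex * min_exon:
        n_ex -= 1
    leftover = mat_len - n_ex * min_exon
    extra = rng.multinomial(leftover, [1 / n_ex] * n_ex) if leftover > 0 else [0] * n_ex
    exon_lens = [min_exon + int(x) for x in extra]
    intron_lens = [
        int(rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1))
        for _ in range(n_ex - 1)
    ]
    strand = "+" if rng.integers(2) == 0 else "-"
    total = sum(exon_lens) + sum(intron_lens)
    premrna = _random_dna(rng, total, spec.base_composition).copy()
    return _GenePlan(
        gene_id=f"gene{i:03d}",
        strand=strand,
        exon_lens=exon_lens,
        intron_lens=intron_lens,
        utr5_len=min(utr5, exon_lens[0] - 1),
        utr3_len=min(utr3, exon_lens[-1] - 1),
        premrna=premrna,
    )


def _apply_plant(
    plans: list[_GenePlan],
    plant: PlantSpec,
    rng: np.random.Generator,
    L: int,
) -> list[dict]:
    if plant.source_gene == plant.target_gene:
        raise GenerationError("plants must target a different gene than their source")
    src = plans[plant.source_gene]
    tgt = plans[plant.target_gene]
    mature = _plan_mature(src)
    mismatches = plant.mismatches_each or tuple(0 for _ in plant.source_starts)
    candidates = tgt.region_intervals(plant.target_region, L)
    if not candidates:
        raise GenerationError(
            f"no {plant.target_region} interval of >= {L} nt in {tgt.gene_id} "
            f"for plant from {src.gene_id}"
        )
    rows = []
    for start, m in zip(plant.source_starts, mismatches):
        if start < 0 or start + L > len(mature):
            raise GenerationError(
                f"source start {start} outside cDNA of {src.gene_id} (len {len(mature)})"
            )
        window = mature[start : start + L]
        mutated = mutate_with_hamming(window, m, rng=rng)
        insert = reverse_complement(mutated) if plant.orientation == "revcomp" else mutated
        pos = None
        for _ in range(200):
            iv = candidates[int(rng.integers(len(candidates)))]
            p = int(rng.integers(iv[0], iv[1] - L + 1))
            if all(p + L <= s or p >= e for s, e in tgt.used):
                pos = p
                break
        if pos is None:  # tight regions: fall back to first free slot
            for iv in candidates:
                for p in range(iv[0], iv[1] - L + 1):
                    if all(p + L <= s or p >= e for s, e in tgt.used):
                        pos = p
                        break
                if pos is not None:
                    break
        if pos is None:
            raise GenerationError(
                f"could not place plant into {tgt.gene_id} {plant.target_region} "
                "without overlap"
            )
        tgt.premrna[pos : pos + L] = np.frombuffer(insert.encode("ascii"), np.uint8)
        tgt.used.append((pos, pos + L))
        rows.append(
            {
                "source_gene": src.gene_id,
                "source_start": int(start),
                "target_gene": tgt.gene_id,
                "mismatches": int(m),
                "region": plant.target_region,
                "orientation": plant.orientation,
                "target_premrna_pos": pos,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _assemble(
    spec: FixtureSpec, plans: list[_GenePlan], rng: np.random.Generator
) -> tuple[str, list[GeneModel]]:
    chunks: list[np.ndarray] = []
    models: list[GeneModel] = []
    cursor = 0
    gap = spec.intergenic_length
    for plan in plans:
        chunks.append(_random_dna(rng, gap, spec.base_composition))
        cursor += gap
        glen = len(plan.premrna)
        span: Interval = (cursor, cursor + glen)
        if plan.strand == "+":
            genomic = plan.premrna
            to_genomic = lambda s, e, c=cursor: (c + s, c + e)
        else:
            rc = reverse_complement(plan.premrna.tobytes().decode("ascii"))
            genomic = np.frombuffer(rc.encode("ascii"), np.uint8)
            to_genomic = lambda s, e, c=cursor, g=glen: (c + g - e, c + g - s)
        chunks.append(genomic)
        cursor += glen

        exons = sorted(to_genomic(s, e) for s, e in plan.exon_intervals_pre())
        m2p = plan.mat2pre()
        utr5_ivs = []
        utr3_ivs = []
        if plan.utr5_len:
            s, e = int(m2p[0]), int(m2p[plan.utr5_len - 1]) + 1
            utr5_ivs.append(to_genomic(s, e))
        if plan.utr3_len:
            s = int(m2p[plan.mature_len - plan.utr3_len])
            e = int(m2p[-1]) + 1
            utr3_ivs.append(to_genomic(s, e))
        transcript = TranscriptModel(
            transcript_id=f"{plan.gene_id}-RA",
            exons=tuple(exons),
            utr5=tuple(sorted(utr5_ivs)),
            utr3=tuple(sorted(utr3_ivs)),
        )
        models.append(
            GeneModel(plan.gene_id, spec.contig, plan.strand, span, (transcript,))
        )
    chunks.append(_random_dna(rng, gap, spec.base_composition))
    contig_seq = np.concatenate(chunks).tobytes().decode("ascii")
    return contig_seq, models


def _write_fasta(path: Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s0, e0 = g.span
            fh.write(
                f"{g.chrom}\tcotscan\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ts = min(s for s, _ in t.exons)
                te = max(e for _, e in t.exons)
                fh.write(
                    f"{g.chrom}\tcotscan\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tcotscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for ftype, ivs in (
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for s, e in ivs:
                        fh.write(
                            f"{g.chrom}\tcotscan\t{ftype}\t{s + 1}\t{e}\t.\t"
                            f"{g.strand}\t.\tParent={t.transcript_id}\n"
                        )


def generate(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Generate the fixture; optionally write FASTA + GFF3 + truth TSV."""
    rng = np.random.default_rng(spec.seed)
    plans = [_build_plan(spec, rng, i) for i in range(spec.n_genes)]
    truth_rows: list[dict] = []
    for plant in spec.planted_repeats:
        truth_rows.extend(_apply_plant(plans, plant, rng, spec.sirna_length))
    contig_seq, models = _assemble(spec, plans, rng)
    contigs = {spec.contig: contig_seq}
    sequences = {m.gene_id: extract_sequences(m, contigs) for m in models}

    # planted copies must be present verbatim in the target's pre-mRNA
    for plan, model in zip(plans, models):
        expect = plan.premrna.tobytes().decode("ascii")
        assert sequences[model.gene_id].premrna == expect

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "source_gene",
            "source_start",
            "target_gene",
            "mismatches",
            "region",
            "orientation",
            "target_premrna_pos",
        ],
    )
    paths = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff": out / "genes.gff3",
            "truth": out / "truth.tsv",
        }
        _write_fasta(paths["fasta"], contigs)
        _write_gff3(paths["gff"], models)
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return Fixture(spec, contigs, models, sequences, truth, paths)
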