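"""Shared helpers: random target spaces, toy annotation files, hit factories."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pytest

from cotscan import OffTargetHit, Record, TargetSpace

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def random_space(
    rng: np.random.Generator,
    n_records: int = 5,
    rec_len: int = 3000,
    mode: str = "premrna",
) -> TargetSpace:
    """An i.i.d. random target space, one gene per record, no region maps."""
    recs = [
        Record(f"r{i}", f"g{i}", random_dna(rng, rec_len), None)
        for i in range(n_records)
    ]
    return TargetSpace(mode, recs)


def make_hit(
    src: str = "gA",
    start: int = 0,
    tgt: str = "gB",
    seq_id: str | None = None,
    offset: int = 0,
    mismatches: int = 0,
    orientation: str = "sense",
    region: str = "exon",
) -> OffTargetHit:
    return OffTargetHit(
        source_gene=src,
        sirna_start=start,
        sirna_sequence="A" * 21,
        score=0.0,
        target_gene=tgt,
        seq_id=seq_id or tgt,
        offset=offset,
        mismatches=mismatches,
        orientation=orientation,
        region=region,
    )


TOY_FASTA = ">ctg\n" + "\n".join(textwrap.wrap("ACGTACGTACGTACGTACGT" * 10, 60)) + "\n"

TOY_GFF = """\
##gff-version 3
ctg\ttest\tgene\t1\t200\t.\t{strand}\t.\tID=geneA
ctg\ttest\tmRNA\t1\t150\t.\t{strand}\t.\tID=geneA-RA;Parent=geneA
ctg\ttest\texon\t1\t50\t.\t{strand}\t.\tParent=geneA-RA
ctg\ttest\texon\t101\t150\t.\t{strand}\t.\tParent=geneA-RA
"""


@pytest.fixture
def toy_annotation(tmp_path: Path):
    """Writes a 200-nt contig with one 2-exon plus-strand gene."""

    def _write(strand: str = "+", gff_text: str | None = None):
        fasta = tmp_path / "toy.fa"
        gff = tmp_path / "toy.gff3"
        fasta.write_text(TOY_FASTA)
        gff.write_text(gff_text if gff_text is not None else TOY_GFF.format(strand=strand))
        return fasta, gff

    return _write
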