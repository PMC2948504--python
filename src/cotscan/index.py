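"""Word-size-9 seed table over a target space of per-gene RNA sequences.

Every overlapping 9-nt word of every target record is 2-bit encoded
(A=0, C=1, G=2, T=3; first base most significant) and stored with its
exact location, giving a key space of 4^9 = 262,144 possible words.
Lookups answer "at which (record, offset) does this word occur?" in
O(log n).  Only the sense strand of each record is indexed; query
orientation is handled on the search side.  Windows containing N are
skipped, not indexed.

The index is held in memory as sorted numpy arrays (word codes plus a
parallel array of global positions), which is both compact and fast to
join on for the mismatch search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .genome import ConfigurationError, GeneSequences

__all__ = [
    "AmbiguousBaseError",
    "Location",
    "Record",
    "TargetSpace",
    "SeedIndex",
    "DEFAULT_WORD_SIZE",
    "encode_word",
    "decode_word",
    "seq_to_codes",
    "build_target_space",
    "build_index",
]

DEFAULT_WORD_SIZE = 9

# base -> 2-bit code; N -> 4 (never matches); anything else -> 255 (invalid)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _LUT[_b] = _c
    _LUT[_b + 32] = _c  # lowercase
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4

_BASES = "ACGT"


class AmbiguousBaseError(ValueError):
    """The word contains N (or another ambiguity code) and cannot be 2-bit encoded."""


def seq_to_codes(s: str) -> np.ndarray:
    """uint8 codes for a DNA string: A..T -> 0..3, N -> 4; others error."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _LUT[arr]
    if (codes == 255).any():
        bad = sorted(set(s) - set("ACGTNacgtn"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad!r}")
    return codes


def encode_word(s: str) -> int:
    """2-bit encode a DNA word; bijection onto [0, 4^len)."""
    codes = seq_to_codes(s)
    if (codes >= 4).any():
        raise AmbiguousBaseError(f"word {s!r} contains ambiguous bases")
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


def decode_word(code: int, word_size: int) -> str:
    """Inverse of :func:`encode_word` at the given word size."""
    if not (0 <= code < 4**word_size):
        raise ValueError(f"code {code} out of range for word_size {word_size}")
    out = []
    for shift in range(2 * (word_size - 1), -2, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


class Location(NamedTuple):
    """One occurrence of a word: target record and 0-based offset."""

    seq_id: str
    offset: int


@dataclass
class Record:
    """One target record: a gene (premrna mode) or transcript (mature mode)."""

    seq_id: str
    gene_id: str
    seq: str
    exon_mask: np.ndarray | None  # per-position exonic flag; None => all exonic


class TargetSpace:
    """The indexed collection of per-gene target sequences."""

    def __init__(self, mode: str, records: Iterable[Record]):
        if mode not in ("premrna", "mature"):
            raise ConfigurationError(f"unknown target-space mode {mode!r}")
        self.mode = mode
        self.records: list[Record] = list(records)
        self._by_id: dict[str, Record] = {}
        for r in self.records:
            if r.seq_id in self._by_id:
                raise ValueError(f"duplicate record seq_id {r.seq_id!r}")
            self._by_id[r.seq_id] = r
        self._codes: list[np.ndarray | None] = [None] * len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, seq_id: str) -> Record:
        return self._by_id[seq_id]

    def gene_of(self, seq_id: str) -> str:
        return self._by_id[seq_id].gene_id

    def codes(self, i: int) -> np.ndarray:
        """Cached uint8 base codes of record i."""
        if self._codes[i] is None:
            self._codes[i] = seq_to_codes(self.records[i].seq)
        return self._codes[i]

    @property
    def total_length(self) -> int:
        return sum(len(r.seq) for r in self.records)


def build_target_space(
    genes: Iterable[GeneSequences],
    mode: str,
    transcript: str | None = None,
) -> TargetSpace:
    """Assemble a TargetSpace from per-gene sequences.

    premrna mode: one record per gene (full unspliced span, exon mask
    attached).  mature mode: one record per transcript, all positions
    exonic by construction; ``transcript`` restricts every gene to one
    named transcript (default: all transcripts).
    """
    records: list[Record] = []
    for gs in genes:
        if mode == "premrna":
            if gs.premrna_exon is None:
                raise ConfigurationError(
                    f"gene {gs.gene_id}: exon/intron layout unknown "
                    "(bundle without exon_lens/intron_lens); use FASTA+GFF3 input "
                    "or mature mode"
                )
            records.append(Record(gs.gene_id, gs.gene_id, gs.premrna, gs.premrna_exon))
        else:
            for tid, seq in sorted(gs.mature.items()):
                if transcript is not None and tid != transcript:
                    continue
                records.append(Record(f"{gs.gene_id}|{tid}", gs.gene_id, seq, None))
    return TargetSpace(mode, records)


_RECORD_GAP = 32  # > query length; joins can never bridge two records


class SeedIndex:
    """Sorted-array seed table mapping word code -> occurrence locations.

    Records are laid out in one global coordinate system separated by
    gaps wider than any query, so global positions translate uniquely
    back to (record, offset) and cross-record seed joins are impossible.
    """

    def __init__(self, ts: TargetSpace, word_size: int = DEFAULT_WORD_SIZE):
        if not (4 <= word_size <= 15):
            raise ConfigurationError(
                f"word_size {word_size} outside supported range [4, 15]"
            )
        if not ts.records:
            raise ValueError("target space has no records")
        self.ts = ts
        self.word_size = word_size

        w = word_size
        starts: list[int] = []
        pos_chunks: list[np.ndarray] = []
        key_chunks: list[np.ndarray] = []
        global_parts: list[np.ndarray] = []
        gap = np.full(_RECORD_GAP, 255, dtype=np.uint8)
        cursor = 0
        for i, rec in enumerate(ts.records):
            codes = ts.codes(i)
            starts.append(cursor)
            global_parts.append(codes)
            n = len(codes) - w + 1
            if n > 0:
                vals = np.zeros(n, dtype=np.int64)
                valid = np.ones(n, dtype=bool)
                for j in range(w):
                    c = codes[j : j + n]
                    valid &= c < 4
                    vals = vals * 4 + (c & 3).astype(np.int64)
                key_chunks.append(vals[valid])
                pos_chunks.append(cursor + np.flatnonzero(valid).astype(np.int64))
            cursor += len(codes)
            global_parts.append(gap)
            cursor += _RECORD_GAP

        self._rec_starts = np.asarray(starts, dtype=np.int64)
        self._rec_lens = np.asarray([len(r.seq) for r in ts.records], dtype=np.int64)
        self._global_codes = np.concatenate(global_parts)

        if key_chunks:
            keys = np.concatenate(key_chunks)
            pos = np.concatenate(pos_chunks)
            order = np.lexsort((pos, keys))
            self._keys = keys[order]
            self._pos = pos[order]
        else:
            self._keys = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)

    # -- statistics ---------------------------------------------------------

    @property
    def key_space(self) -> int:
        """Number of representable word keys: 4^word_size."""
        return 4**self.word_size

    @property
    def n_locations(self) -> int:
        return len(self._pos)

    @property
    def n_occupied_keys(self) -> int:
        return len(np.unique(self._keys))

    def stats(self) -> dict:
        return {
            "word_size": self.word_size,
            "mode": self.ts.mode,
            "n_records": len(self.ts),
            "total_target_length": self.ts.total_length,
            "n_locations": self.n_locations,
            "n_occupied_keys": self.n_occupied_keys,
            "key_space": self.key_space,
        }

    # -- queries ------------------------------------------------------------

    def locate(self, global_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Translate global positions to (record index, offset) arrays."""
        rec = np.searchsorted(self._rec_starts, global_pos, side="right") - 1
        return rec, global_pos - self._rec_starts[rec]

    def lookup_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All stored global positions for an array of word codes.

        Returns (positions, owner) where owner[i] indexes the input code
        that produced positions[i].
        """
        lo = np.searchsorted(self._keys, codes, side="left")
        hi = np.searchsorted(self._keys, codes, side="right")
        cnt = hi - lo
        nz = cnt > 0
        if not nz.any():
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        l, c = lo[nz], cnt[nz]
        total = int(c.sum())
        base = np.repeat(l, c)
        within = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(c) - c, c)
        pos = self._pos[base + within]
        owner = np.repeat(np.flatnonzero(nz), c)
        return pos, owner

    def lookup(self, word: str) -> list[Location]:
        """Exact locations of one word; empty list when absent."""
        if len(word) != self.word_size:
            raise ValueError(
                f"word length {len(word)} != index word_size {self.word_size}"
            )
        code = encode_word(word)
        pos, _ = self.lookup_codes(np.asarray([code], dtype=np.int64))
        rec, off = self.locate(np.sort(pos))
        return [
            Location(self.ts.records[int(r)].seq_id, int(o)) for r, o in zip(rec, off)
        ]


def build_index(ts: TargetSpace, word_size: int = DEFAULT_WORD_SIZE) -> SeedIndex:
    """Build the seed table over a target space."""
    return SeedIndex(ts, word_size)
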