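"""Gapless <=k-mismatch search of short queries via seed joining.

A 21-nt query is split into two 9-nt child words plus a 3-nt remainder.
For every mismatch-budget partition (i, j) with i + j <= k, all word
variants at Hamming distance exactly i (left child) and exactly j
(right child) are looked up in the seed table, and a candidate locus is
kept wherever a left-child location + 9 coincides with a right-child
location.  Candidates are then verified by direct comparison of the
full query window, which settles the remainder and the true mismatch
count; loci reachable through several partitions collapse to one hit.

Variant enumeration exploits the 2-bit encoding: substituting base b by
b XOR d (d in {1,2,3}) always changes the base, so the variants of a
word at distance exactly d are the word XORed with every combination of
d non-zero 2-bit deltas at d distinct positions.  These delta masks
depend only on (word_size, d) and are precomputed once.

``search_naive`` is the brute-force position-by-position Hamming scan:
the independent oracle for tests and the CLI's ``--engine naive``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genome import ConfigurationError, reverse_complement
from .index import SeedIndex, TargetSpace, decode_word, encode_word, seq_to_codes

__all__ = [
    "DEFAULT_SIRNA_LENGTH",
    "DEFAULT_MAX_MISMATCHES",
    "QueryPlan",
    "MatchHit",
    "split_query",
    "enumerate_variants",
    "search",
    "search_naive",
]

DEFAULT_SIRNA_LENGTH = 21
DEFAULT_MAX_MISMATCHES = 3
_MAX_SUPPORTED_K = 4  # variant enumeration beyond this explodes combinatorially

SENSE = "sense"
REVCOMP = "revcomp"


@dataclass(frozen=True)
class QueryPlan:
    """Decomposition of a query into word-size children plus a remainder."""

    query: str
    parts: tuple[tuple[int, str], ...]  # (offset-in-query, word)
    remainder: tuple[int, str]  # (offset, substring); substring may be ''
    k: int | None = None


@dataclass(frozen=True)
class MatchHit:
    """One gapless alignment of a query to a target record."""

    seq_id: str
    offset: int
    mismatches: int
    orientation: str  # 'sense' | 'revcomp'

    def key(self) -> tuple:
        return (self.seq_id, self.offset, self.orientation)


def split_query(q: str, word_size: int) -> QueryPlan:
    """Tile a query into contiguous word-size parts plus the remainder."""
    if len(q) < word_size:
        raise ValueError(f"query length {len(q)} < word_size {word_size}")
    nparts = len(q) // word_size
    parts = tuple(
        (i * word_size, q[i * word_size : (i + 1) * word_size]) for i in range(nparts)
    )
    rem_off = nparts * word_size
    return QueryPlan(query=q, parts=parts, remainder=(rem_off, q[rem_off:]))


@lru_cache(maxsize=None)
def _xor_deltas(word_size: int, d: int) -> np.ndarray:
    """XOR masks turning a word code into every code at distance exactly d."""
    if d == 0:
        return np.zeros(1, dtype=np.int64)
    masks = []
    for positions in itertools.combinations(range(word_size), d):
        shifts = [2 * (word_size - 1 - p) for p in positions]
        for deltas in itertools.product((1, 2, 3), repeat=d):
            m = 0
            for s, dv in zip(shifts, deltas):
                m |= dv << s
            masks.append(m)
    return np.asarray(masks, dtype=np.int64)


def enumerate_variants(word: str, max_mm: int) -> list[tuple[str, int]]:
    """All distinct words within Hamming distance max_mm, with exact distances."""
    if not (0 <= max_mm <= len(word)):
        raise ValueError(f"max_mm {max_mm} outside [0, {len(word)}]")
    code = encode_word(word)
    w = len(word)
    out: list[tuple[str, int]] = []
    for d in range(max_mm + 1):
        for m in _xor_deltas(w, d):
            out.append((decode_word(code ^ int(m), w), d))
    return out


def _variant_codes(code: int, word_size: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, exact distances) of all variants within distance k."""
    kk = min(k, word_size)
    chunks = [code ^ _xor_deltas(word_size, d) for d in range(kk + 1)]
    dists = [np.full(len(c), d, dtype=np.int64) for d, c in enumerate(chunks)]
    return np.concatenate(chunks), np.concatenate(dists)


def _query_codes(q: str) -> np.ndarray | None:
    codes = seq_to_codes(q)
    if (codes >= 4).any():
        return None
    return codes


def _candidate_starts(
    q: str, idx: SeedIndex, k: int
) -> np.ndarray:
    """Global candidate start positions for one query orientation."""
    w = idx.word_size
    p1 = encode_word(q[:w])
    c1, d1lab = _variant_codes(p1, w, k)
    pos1, own1 = idx.lookup_codes(c1)
    if len(q) < 2 * w:
        return pos1[d1lab[own1] <= k]
    p2 = encode_word(q[w : 2 * w])
    c2, d2lab = _variant_codes(p2, w, k)
    pos2, own2 = idx.lookup_codes(c2)
    if len(pos1) == 0 or len(pos2) == 0:
        return np.empty(0, dtype=np.int64)
    # each locus matches exactly one variant word, so positions are unique
    common, i1, i2 = np.intersect1d(
        pos1, pos2 - w, assume_unique=True, return_indices=True
    )
    budget_ok = d1lab[own1[i1]] + d2lab[own2[i2]] <= k
    return common[budget_ok]


def _verify(
    starts: np.ndarray, qcodes: np.ndarray, idx: SeedIndex, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bounds-check candidates and count true mismatches over the window."""
    L = len(qcodes)
    rec, off = idx.locate(starts)
    ok = (off >= 0) & (off + L <= idx._rec_lens[rec])
    starts = starts[ok]
    if len(starts) == 0:
        return starts, np.empty(0, dtype=np.int64)
    windows = idx._global_codes[starts[:, None] + np.arange(L)]
    mism = (windows != qcodes).sum(axis=1)
    keep = mism <= k
    return starts[keep], mism[keep]


def search(
    q: str,
    idx: SeedIndex,
    ts: TargetSpace | None = None,
    k: int = DEFAULT_MAX_MISMATCHES,
    both_query_orientations: bool = True,
) -> list[MatchHit]:
    """All gapless alignments of ``q`` with at most ``k`` mismatches.

    Complete and sound for any k <= 4 (guaranteed by budget-partition
    enumeration plus direct verification); queries containing N are
    skipped with a warning and yield no hits.
    """
    if ts is not None and ts is not idx.ts:
        raise ConfigurationError("target space does not match the seed index")
    if not (0 <= k <= _MAX_SUPPORTED_K):
        raise ConfigurationError(
            f"k={k} outside supported mismatch range [0, {_MAX_SUPPORTED_K}]"
        )
    ts = idx.ts
    qcodes = _query_codes(q)
    if qcodes is None:
        warnings.warn(f"query containing N skipped: {q!r}", stacklevel=2)
        return []

    orientations = [(SENSE, q, qcodes)]
    if both_query_orientations:
        rc = reverse_complement(q)
        orientations.append((REVCOMP, rc, seq_to_codes(rc)))

    hits: list[MatchHit] = []
    for label, qs, qc in orientations:
        starts = _candidate_starts(qs, idx, k)
        starts, mism = _verify(starts, qc, idx, k)
        rec, off = idx.locate(starts)
        for r, o, m in zip(rec, off, mism):
            hits.append(
                MatchHit(ts.records[int(r)].seq_id, int(o), int(m), label)
            )
    hits.sort(key=MatchHit.key)
    return hits


def search_naive(
    q: str,
    ts: TargetSpace,
    k: int = DEFAULT_MAX_MISMATCHES,
    both_query_orientations: bool = True,
) -> list[MatchHit]:
    """Brute-force Hamming scan over every window of every record.

    Independent oracle for :func:`search`; identical contract and output
    ordering.
    """
    qcodes = _query_codes(q)
    if qcodes is None:
        warnings.warn(f"query containing N skipped: {q!r}", stacklevel=2)
        return []
    L = len(q)
    orientations = [(SENSE, qcodes)]
    if both_query_orientations:
        orientations.append((REVCOMP, seq_to_codes(reverse_complement(q))))

    hits: list[MatchHit] = []
    for i, rec in enumerate(ts.records):
        codes = ts.codes(i)
        if len(codes) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        for label, qc in orientations:
            mism = (windows != qc).sum(axis=1)
            for off in np.flatnonzero(mism <= k):
                hits.append(MatchHit(rec.seq_id, int(off), int(mism[off]), label))
    hits.sort(key=MatchHit.key)
    return hits
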