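"""Cot-group formation, statistics, clean regions, dsRNA design and the
randomized-genome expectation."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotscan import (
    CotGroup,
    ValidationError,
    clean_regions,
    cot_stats,
    design_dsrna_pairs,
    expected_random_matches,
    form_cot_groups,
    hamming_ball_size,
)
from conftest import make_hit

L = 21


class TestFormCotGroups:
    def test_two_starts_one_group(self):
        hits = [make_hit(start=10, tgt="geneX"), make_hit(start=500, tgt="geneX")]
        (g,) = form_cot_groups(hits)
        assert g.members == (10, 500) and g.size == 2

    def test_singleton_discarded(self):
        assert form_cot_groups([make_hit(start=10, tgt="geneX")]) == []

    def test_duplicate_transcript_hits_collapse(self):
        hits = [
            make_hit(start=10, tgt="geneX", seq_id="geneX|RA"),
            make_hit(start=10, tgt="geneX", seq_id="geneX|RB"),
            make_hit(start=44, tgt="geneX", seq_id="geneX|RA", orientation="revcomp"),
        ]
        (g,) = form_cot_groups(hits)
        assert g.members == (10, 44)

    def test_random_tables_match_pandas_groupby_oracle(self):
        rng = np.random.default_rng(99)
        hits = [
            make_hit(
                src=f"s{rng.integers(3)}",
                start=int(rng.integers(50)),
                tgt=f"t{rng.integers(6)}",
                offset=int(rng.integers(100)),
            )
            for _ in range(300)
        ]
        df = pd.DataFrame(
            {"src": [h.source_gene for h in hits],
             "tgt": [h.target_gene for h in hits],
             "start": [h.sirna_start for h in hits]}
        )
        expected = {
            (src, tgt): tuple(sorted(set(grp["start"])))
            for (src, tgt), grp in df.groupby(["src", "tgt"])
            if grp["start"].nunique() >= 2
        }
        got = {
            (g.source_gene, g.offtarget_gene): g.members
            for g in form_cot_groups(hits)
        }
        assert got == expected

    def test_group_invariants(self):
        with pytest.raises(ValidationError):
            CotGroup("s", "t", (5,))
        with pytest.raises(ValidationError):
            CotGroup("s", "t", (9, 5))


class TestCotStats:
    def test_coverage_formula(self):
        g = CotGroup("s", "t", (0, 100))
        assert cot_stats([g], "s", 2100, L).coverage_percent == pytest.approx(2.0)

    def test_empty(self):
        s = cot_stats([], "s", 1000, L)
        assert (s.n_cot_groups, s.max_group_size, s.coverage_percent) == (0, 0, 0.0)

    def test_sizes_two_and_three(self):
        gs = [CotGroup("s", "t1", (0, 30)), CotGroup("s", "t2", (0, 30, 60))]
        st_ = cot_stats(gs, "s", 210, L)
        assert st_.coverage_percent == pytest.approx(50.0)
        assert st_.max_group_size == 3

    def test_gene_shorter_than_sirna_rejected(self):
        with pytest.raises(ValidationError):
            cot_stats([], "s", 10, L)


def _contains_pair(iv, groups):
    s, e = iv
    for g in groups:
        inside = [m for m in g.members if s <= m and m + L <= e]
        if len(inside) >= 2:
            return True
    return False


class TestCleanRegions:
    def test_no_groups_whole_gene(self):
        assert clean_regions([], 1000, L) == [(0, 1000)]

    def test_single_pair_splits(self):
        groups = [CotGroup("s", "t", (100, 400))]
        regions = clean_regions(groups, 1000, L)
        assert regions == [(0, 420), (101, 1000)]
        for iv in regions:
            assert not _contains_pair(iv, groups)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_regions_clean_and_maximal(self, seed):
        rng = np.random.default_rng(seed)
        glen = int(rng.integers(200, 1200))
        groups = []
        for t in range(rng.integers(1, 5)):
            members = sorted(
                set(int(x) for x in rng.integers(0, glen - L, size=rng.integers(2, 6)))
            )
            if len(members) >= 2:
                groups.append(CotGroup("s", f"t{t}", tuple(members)))
        regions = clean_regions(groups, glen, L)
        for s, e in regions:
            assert 0 <= s < e <= glen
            assert not _contains_pair((s, e), groups)
            # maximality: extending one nt in either direction must be blocked
            if s > 0:
                assert _contains_pair((s - 1, e), groups)
            if e < glen:
                assert _contains_pair((s, e + 1), groups)

    def test_utr_mask_subtracted(self):
        regions = clean_regions([], 1000, L, utr_mask=[(0, 40), (960, 1000)])
        assert regions == [(40, 960)]


def _region_geneset(region, groups):
    s, e = region
    out = set()
    for g in groups:
        if any(s <= m and m + L <= e for m in g.members):
            out.add(g.offtarget_gene)
    return out


class TestDesign:
    def test_unconstrained_gene_gets_pairs(self):
        res = design_dsrna_pairs("g", [], gene_length=1000, min_len=300, max_len=800)
        assert res.feasible and res.pairs
        for p in res.pairs:
            r1, r2 = p.region1, p.region2
            assert r1[1] <= r2[0]
            for s, e in (r1, r2):
                assert 300 <= e - s <= 800
            assert p.shared_offtargets == ()

    def test_globally_shared_offtarget_is_infeasible(self):
        glen = 1000
        members = tuple(range(0, glen - L, 7))  # geneX hit from everywhere
        groups = [CotGroup("g", "geneX", members)]
        res = design_dsrna_pairs("g", groups, gene_length=glen, min_len=300, max_len=800)
        assert not res.feasible and res.pairs == []
        assert "geneX" in res.blocking_genes

    def test_emitted_pairs_have_disjoint_group_genesets(self):
        rng = np.random.default_rng(12)
        glen = 1600
        groups = []
        for t in range(6):
            members = tuple(
                sorted(set(int(x) for x in rng.integers(0, glen - L, size=3)))
            )
            if len(members) >= 2:
                groups.append(CotGroup("g", f"t{t}", members))
        res = design_dsrna_pairs("g", groups, gene_length=glen, min_len=300, max_len=800)
        for p in res.pairs:
            assert not (_region_geneset(p.region1, groups) & _region_geneset(p.region2, groups))

    def test_ranking_prefers_longer_combined_regions(self):
        res = design_dsrna_pairs("g", [], gene_length=2000, min_len=300, max_len=800)
        lengths = [p.combined_length for p in res.pairs]
        assert lengths == sorted(lengths, reverse=True)

    def test_avoid_utr_keeps_regions_out_of_utrs(self):
        utrs = [(0, 120), (1880, 2000)]
        res = design_dsrna_pairs(
            "g", [], gene_length=2000, min_len=300, max_len=800,
            avoid_utr=True, utr_intervals=utrs,
        )
        assert res.feasible
        for p in res.pairs:
            for s, e in (p.region1, p.region2):
                for us, ue in utrs:
                    assert e <= us or s >= ue

    def test_too_short_gene_infeasible(self):
        res = design_dsrna_pairs("g", [], gene_length=500, min_len=300, max_len=800)
        assert not res.feasible


class TestExpectedRandomMatches:
    def test_closed_form_unit_case(self):
        assert expected_random_matches(21, 0, 4**21, both_strands=False) == pytest.approx(1.0)

    def test_ball_terms_match_exhaustive_enumeration_L8(self):
        # enumerate all 4^8 words, count by distance from a fixed word
        word_codes = np.arange(4**8, dtype=np.int64)
        ref = word_codes[12345]
        x = word_codes ^ ref
        dist = np.zeros(len(word_codes), dtype=np.int64)
        for p in range(8):
            dist += (x >> (2 * p)) & 3 != 0
        for k in range(4):
            exact = int((dist == k).sum())
            assert exact == comb(8, k) * 3**k
            assert hamming_ball_size(8, k) == int((dist <= k).sum())

    def test_both_strands_doubles(self):
        one = expected_random_matches(21, 3, 10**6, both_strands=False)
        assert expected_random_matches(21, 3, 10**6, both_strands=True) == pytest.approx(2 * one)
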