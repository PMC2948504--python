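"""siRNA enumeration, activity scoring and off-target mapping semantics."""

import numpy as np
import pytest

from cotscan import (
    ConfigurationError,
    FixtureSpec,
    PlantSpec,
    Record,
    TargetSpace,
    build_index,
    build_target_space,
    enumerate_sirnas,
    filter_intron_hits,
    form_cot_groups,
    generate,
    map_offtargets,
    score_sirna,
)
from conftest import make_hit, random_dna


class TestEnumerate:
    def test_boundary_single_candidate(self):
        cands = enumerate_sirnas("A" * 21, "g", 21)
        assert len(cands) == 1 and cands[0].start == 0

    def test_window_count(self):
        rng = np.random.default_rng(0)
        cands = enumerate_sirnas(random_dna(rng, 100), "g", 21)
        assert len(cands) == 80
        assert [c.start for c in cands] == list(range(80))

    def test_n_windows_skipped(self):
        rng = np.random.default_rng(0)
        cdna = random_dna(rng, 100)
        cdna = cdna[:10] + "N" + cdna[11:]
        starts = [c.start for c in enumerate_sirnas(cdna, "g", 21)]
        # every window covering position 10 (starts 0..10) is gone
        assert starts == list(range(11, 80))

    def test_short_cdna_warns_empty(self):
        with pytest.warns(UserWarning):
            assert enumerate_sirnas("ACGT", "g", 21) == []

    def test_candidate_sequence_matches_cdna(self):
        rng = np.random.default_rng(3)
        cdna = random_dna(rng, 60)
        for c in enumerate_sirnas(cdna, "g", 21):
            assert c.sequence == cdna[c.start : c.start + 21]


class TestScoring:
    def test_scheme_none_passes_everything(self):
        assert score_sirna("G" * 21, "none") == (0.0, True)

    def test_all_gc_fails_default(self):
        score, passed = score_sirna("G" * 21, "default-v1")
        assert not passed

    def test_unknown_scheme_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            score_sirna("A" * 21, "does-not-exist")

    def test_default_scheme_against_independent_reimplementation(self):
        def oracle(seq):  # independent sequential rule evaluation
            points = 0
            gc = sum(1 for b in seq if b in "GC") / len(seq)
            if 0.30 <= gc <= 0.60:
                points += 1
            runs, cur = [], 1
            for a, b in zip(seq, seq[1:]):
                cur = cur + 1 if a == b else 1
                runs.append(cur)
            if max(runs, default=1) < 5:
                points += 1
            if seq[18] in "AT":
                points += 1
            return points >= 2

        rng = np.random.default_rng(42)
        seqs = [random_dna(rng, 21) for _ in range(1000)]
        ours = [score_sirna(s, "default-v1")[1] for s in seqs]
        assert ours == [oracle(s) for s in seqs]


def _premrna_fixture(region="intron", mm=(0, 0), starts=(60, 200)):
    return generate(
        FixtureSpec(
            seed=17,
            n_genes=5,
            planted_repeats=(
                PlantSpec(
                    source_gene=0,
                    source_starts=starts,
                    target_gene=3,
                    target_region=region,
                    mismatches_each=mm,
                ),
            ),
        )
    )


class TestMapOfftargets:
    def test_source_gene_only_space_yields_nothing(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 500)
        ts = TargetSpace("premrna", [Record("gA", "gA", seq, None)])
        idx = build_index(ts, 9)
        cands = enumerate_sirnas(seq, "gA", 21, scheme="none")
        assert map_offtargets(cands, idx, ts, 3) == []

    def test_intron_plant_visible_only_in_premrna_mode(self):
        fx = _premrna_fixture("intron")
        src = fx.sequences["gene000"]
        cands = enumerate_sirnas(src.cdna, "gene000", 21, scheme="none")

        ts_pre = build_target_space(fx.sequences.values(), "premrna")
        hits_pre = map_offtargets(cands, build_index(ts_pre, 9), ts_pre, 3)
        assert hits_pre and all(h.region == "intron" for h in hits_pre)
        assert {h.target_gene for h in hits_pre} == {"gene003"}

        ts_mat = build_target_space(fx.sequences.values(), "mature")
        hits_mat = map_offtargets(cands, build_index(ts_mat, 9), ts_mat, 3)
        assert hits_mat == []

    def test_engine_equivalence_on_fixture(self):
        fx = _premrna_fixture("exon", mm=(1, 2))
        src = fx.sequences["gene000"]
        cands = enumerate_sirnas(src.cdna, "gene000", 21, scheme="none")
        ts = build_target_space(fx.sequences.values(), "premrna")
        idx = build_index(ts, 9)
        seeded = map_offtargets(cands, idx, ts, 3, engine="seeded")
        naive = map_offtargets(cands, None, ts, 3, engine="naive")
        assert seeded == naive and seeded

    def test_on_target_exclusion_universal(self):
        fx = _premrna_fixture("exon")
        ts = build_target_space(fx.sequences.values(), "premrna")
        idx = build_index(ts, 9)
        for gid, gs in fx.sequences.items():
            cands = enumerate_sirnas(gs.cdna, gid, 21, scheme="none")
            for h in map_offtargets(cands, idx, ts, 3):
                assert h.target_gene != gid

    def test_mode_mismatch_is_configuration_error(self):
        fx = _premrna_fixture("exon")
        ts = build_target_space(fx.sequences.values(), "premrna")
        idx = build_index(ts, 9)
        with pytest.raises(ConfigurationError):
            map_offtargets([], idx, ts, 3, mode="mature")

    def test_mature_hits_subset_of_exonic_premrna_hits(self):
        fx = _premrna_fixture("exon", mm=(0, 1))
        src = fx.sequences["gene000"]
        cands = enumerate_sirnas(src.cdna, "gene000", 21, scheme="none")
        ts_pre = build_target_space(fx.sequences.values(), "premrna")
        ts_mat = build_target_space(fx.sequences.values(), "mature")
        pre = map_offtargets(cands, build_index(ts_pre, 9), ts_pre, 3)
        mat = map_offtargets(cands, build_index(ts_mat, 9), ts_mat, 3)
        pre_pairs = {(h.sirna_start, h.target_gene) for h in filter_intron_hits(pre)}
        mat_pairs = {(h.sirna_start, h.target_gene) for h in mat}
        assert mat_pairs <= pre_pairs


class TestFilterIntronHits:
    def test_region_rules(self):
        exon_hit = make_hit(region="exon")
        intron_hit = make_hit(start=5, region="intron")
        assert filter_intron_hits([exon_hit, intron_hit]) == [exon_hit]

    def test_straddling_hit_annotated_intron(self):
        # exon for the first 10 positions only: a 21-nt hit at offset 0 straddles
        mask = np.zeros(100, dtype=bool)
        mask[:10] = True
        seq = "ACGT" * 25
        ts = TargetSpace("premrna", [Record("gB", "gB", seq, mask)])
        from cotscan.sirna import _hit_region
        from cotscan.search import MatchHit

        assert _hit_region(ts, MatchHit("gB", 0, 0, "sense"), 21) == "intron"
        mask2 = np.ones(100, dtype=bool)
        ts2 = TargetSpace("premrna", [Record("gB", "gB", seq, mask2)])
        assert _hit_region(ts2, MatchHit("gB", 0, 0, "sense"), 21) == "exon"

    def test_intron_filter_never_increases_group_counts(self):
        fx = generate(
            FixtureSpec(
                seed=9,
                n_genes=6,
                planted_repeats=(
                    PlantSpec(0, (50, 250), 2, "exon", (0, 1)),
                    PlantSpec(0, (120, 300), 3, "intron", (0, 0)),
                ),
            )
        )
        src = fx.sequences["gene000"]
        cands = enumerate_sirnas(src.cdna, "gene000", 21, scheme="none")
        ts = build_target_space(fx.sequences.values(), "premrna")
        hits = map_offtargets(cands, build_index(ts, 9), ts, 3)
        before = len(form_cot_groups(hits))
        after = len(form_cot_groups(filter_intron_hits(hits)))
        assert after <= before
        assert before == 2 and after == 1  # planted: one exonic + one intronic group
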