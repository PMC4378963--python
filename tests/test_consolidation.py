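"""Filtering, clan competition and overlap collapsing of homology hits."""
import numpy as np
import pytest

from avinc.consolidate import (
    UnknownFamilyError,
    collapse_overlaps,
    compete_clans,
    consolidate_genome,
    covered_bases,
    filter_hits,
)
from avinc.model import FilterConfig

from conftest import make_hit


def brute_force_compete(hits, family_meta):
    """Independent oracle: rank all hits globally, greedily accept unless the
    candidate overlaps an already accepted same-clan hit on the same scaffold."""
    def clan(h):
        meta = family_meta.get(h.family_id)
        return meta.clan_id if meta and meta.clan_id else ("self", h.family_id)

    ranked = sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.family_id,
                                         h.start, h.end))
    accepted = []
    for h in ranked:
        clash = any(
            a.scaffold_id == h.scaffold_id
            and clan(a) == clan(h)
            and h.start < a.end
            and a.start < h.end
            for a in accepted
        )
        if not clash:
            accepted.append(h)
    return accepted


def hit_key(h):
    return (h.scaffold_id, h.family_id, h.start, h.end, h.strand, h.evalue)


class TestFilterHits:
    def test_evalue_above_cutoff_removed(self, family_meta):
        h = make_hit(evalue=1e-3, bit=60.0)  # above GA, E too large
        assert filter_hits([h], family_meta) == []

    def test_score_below_ga_removed(self, family_meta):
        h = make_hit(evalue=1e-6, bit=37.0)  # GA for RF00001 is 38.0
        assert filter_hits([h], family_meta) == []

    def test_boundary_values_retained(self, family_meta):
        h = make_hit(evalue=5e-4, bit=38.0)
        assert filter_hits([h], family_meta) == [h]

    def test_empty_input(self, family_meta):
        assert filter_hits([], family_meta) == []

    def test_unknown_family_raises_with_ids(self, family_meta):
        with pytest.raises(UnknownFamilyError, match="RFXXX"):
            filter_hits([make_hit(family="RFXXX")], family_meta)

    def test_unknown_family_tolerated_without_ga(self, family_meta):
        h = make_hit(family="RFXXX", evalue=1e-6)
        cfg = FilterConfig(apply_ga=False)
        assert filter_hits([h], family_meta, cfg) == [h]

    def test_monotone_in_evalue_max(self, family_meta):
        rng = np.random.default_rng(11)
        hits = [
            make_hit(start=i * 10, end=i * 10 + 5, bit=60.0,
                     evalue=float(10 ** rng.uniform(-8, -2)))
            for i in range(50)
        ]
        survivors = {}
        for emax in (1e-6, 1e-5, 1e-4, 5e-4, 1e-3):
            kept = filter_hits(hits, family_meta, FilterConfig(evalue_max=emax))
            survivors[emax] = {hit_key(h) for h in kept}
        cutoffs = sorted(survivors)
        for lo, hi in zip(cutoffs, cutoffs[1:]):
            assert survivors[lo] <= survivors[hi]


class TestCompeteClans:
    def test_best_evalue_wins_overlap(self, family_meta):
        a = make_hit(family="RF00001", start=100, end=200, evalue=1e-6)
        b = make_hit(family="RF00002", start=150, end=250, evalue=1e-5)
        assert compete_clans([a, b], family_meta) == [a]

    def test_abutting_half_open_intervals_both_survive(self, family_meta):
        a = make_hit(family="RF00001", start=100, end=200, evalue=1e-6)
        b = make_hit(family="RF00002", start=200, end=300, evalue=1e-5)
        assert set(map(hit_key, compete_clans([a, b], family_meta))) == {
            hit_key(a), hit_key(b)}

    def test_overlap_chain_keeps_ends(self, family_meta):
        # A-B overlap, B-C overlap, A-C disjoint; E-values 1e-8, 1e-6, 1e-7
        a = make_hit(family="RF00001", start=0, end=100, evalue=1e-8)
        b = make_hit(family="RF00002", start=50, end=150, evalue=1e-6)
        c = make_hit(family="RF00001", start=120, end=220, evalue=1e-7)
        got = compete_clans([a, b, c], family_meta)
        assert set(map(hit_key, got)) == {hit_key(a), hit_key(c)}

    def test_different_clans_never_compete(self, family_meta):
        a = make_hit(family="RF00001", start=100, end=200, evalue=1e-6)
        b = make_hit(family="RF00103", start=100, end=200, evalue=1e-5)
        assert len(compete_clans([a, b], family_meta)) == 2

    def test_strand_agnostic_competition(self, family_meta):
        a = make_hit(family="RF00001", start=100, end=200, strand="+", evalue=1e-6)
        b = make_hit(family="RF00002", start=100, end=200, strand="-", evalue=1e-5)
        assert compete_clans([a, b], family_meta) == [a]

    def test_trnascan_zero_evalue_beats_rfam_trna(self, family_meta):
        scan = make_hit(family="tRNA", start=100, end=172, evalue=0.0, bit=60.0)
        rfam = make_hit(family="RF00005", start=90, end=165, evalue=1e-9, bit=70.0)
        assert compete_clans([scan, rfam], family_meta) == [scan]

    def test_no_surviving_same_clan_overlaps(self, family_meta):
        rng = np.random.default_rng(5)
        hits = _random_instance(rng, 30, family_meta)
        survivors = compete_clans(hits, family_meta)
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                same_clan = (
                    family_meta[a.family_id].clan_id is not None
                    and family_meta[a.family_id].clan_id == family_meta[b.family_id].clan_id
                ) or a.family_id == b.family_id
                if same_clan and a.scaffold_id == b.scaffold_id:
                    assert not (a.start < b.end and b.start < a.end)

    def test_covered_bases_never_increase(self, family_meta):
        rng = np.random.default_rng(6)
        for _ in range(20):
            hits = _random_instance(rng, 20, family_meta)
            before = covered_bases((h.scaffold_id, h.start, h.end) for h in hits)
            after_hits = compete_clans(hits, family_meta)
            after = covered_bases((h.scaffold_id, h.start, h.end) for h in after_hits)
            assert after <= before

    def test_matches_bruteforce_on_random_instances(self, family_meta):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hits = _random_instance(rng, int(rng.integers(1, 31)), family_meta)
            got = {hit_key(h) for h in compete_clans(hits, family_meta)}
            want = {hit_key(h) for h in brute_force_compete(hits, family_meta)}
            assert got == want


def _random_instance(rng, n, family_meta):
    fams = list(family_meta)
    hits = []
    for _ in range(n):
        start = int(rng.integers(0, 500))
        length = int(rng.integers(1, 120))
        hits.append(
            make_hit(
                scaffold=f"s{int(rng.integers(1, 3))}",
                family=fams[int(rng.integers(0, len(fams)))],
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                bit=float(rng.integers(20, 100)),
                # discrete E-values force ties through the full tie chain
                evalue=float(10.0 ** -int(rng.integers(4, 9))),
            )
        )
    return hits


class TestCollapseOverlaps:
    def test_same_family_union_merge(self, family_meta):
        a = make_hit(start=100, end=200, evalue=1e-6, bit=50.0)
        b = make_hit(start=150, end=250, evalue=1e-5, bit=60.0)
        (ann,) = collapse_overlaps([a, b], family_meta)
        assert (ann.start, ann.end, ann.n_merged) == (100, 250, 2)
        assert ann.best_evalue == 1e-6
        assert ann.best_bit_score == 60.0
        assert ann.rna_class == "rRNA"

    def test_opposite_strands_stay_separate(self, family_meta):
        a = make_hit(start=100, end=200, strand="+")
        b = make_hit(start=100, end=200, strand="-")
        assert len(collapse_overlaps([a, b], family_meta)) == 2

    def test_distinct_families_never_merge(self, family_meta):
        a = make_hit(family="RF00001", start=100, end=200)
        b = make_hit(family="RF00002", start=150, end=250, bit=55.0)
        assert len(collapse_overlaps([a, b], family_meta)) == 2

    def test_abutting_not_merged(self, family_meta):
        a = make_hit(start=100, end=200)
        b = make_hit(start=200, end=300)
        assert len(collapse_overlaps([a, b], family_meta)) == 2

    def test_idempotent(self, family_meta):
        rng = np.random.default_rng(7)
        hits = _random_instance(rng, 25, family_meta)
        once = collapse_overlaps(hits, family_meta)
        again = collapse_overlaps(
            [make_hit(scaffold=a.scaffold_id, family=a.family_id, start=a.start,
                      end=a.end, strand=a.strand, bit=a.best_bit_score,
                      evalue=a.best_evalue)
             for a in once],
            family_meta,
        )
        assert [(a.scaffold_id, a.start, a.end, a.family_id, a.strand)
                for a in again] == [
            (a.scaffold_id, a.start, a.end, a.family_id, a.strand) for a in once]

    def test_covered_bases_preserved(self, family_meta):
        rng = np.random.default_rng(8)
        hits = _random_instance(rng, 25, family_meta)
        before = covered_bases((h.scaffold_id, h.start, h.end) for h in hits)
        anns = collapse_overlaps(hits, family_meta)
        after = covered_bases((a.scaffold_id, a.start, a.end) for a in anns)
        assert after == before

    def test_pseudogene_trna_class(self, family_meta):
        h = make_hit(family="tRNA", start=10, end=82, pseudogene=True, evalue=0.0)
        (ann,) = collapse_overlaps([h], family_meta)
        assert ann.rna_class == "Transfer RNA pseudogene"


class TestConsolidateGenome:
    def test_empty_inputs(self, family_meta):
        assert consolidate_genome([], [], family_meta) == []

    def test_rfam_trna_competed_against_trnascan(self, family_meta):
        scan = make_hit(family="tRNA", start=100, end=172, evalue=0.0, bit=60.0)
        rfam = make_hit(family="RF00005", start=95, end=170, evalue=1e-9, bit=70.0)
        anns = consolidate_genome([rfam], [scan], family_meta)
        assert len(anns) == 1
        assert anns[0].family_id == "tRNA"

    def test_planted_loci_survive_decoys(self, family_meta):
        planted = [
            make_hit(family="RF00103", start=1000 * i, end=1000 * i + 80,
                     evalue=1e-8, bit=60.0)
            for i in range(10)
        ]
        decoys = [
            make_hit(family="RF00103", start=1000 * i + 500, end=1000 * i + 580,
                     evalue=1e-3, bit=60.0)
            for i in range(5)
        ]
        anns = consolidate_genome(planted + decoys, [], family_meta)
        assert len(anns) == 10
        assert {a.start for a in anns} == {1000 * i for i in range(10)}
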