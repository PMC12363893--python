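"""Event merging, two-sided pairing, classification, clustering, degradome math."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parekit import substrates as sub
from parekit.compare import ComPARESite
from parekit.coverage import EndCountTrack
from parekit.substrates import (
    AnnotationFeature,
    AnnotationIndex,
    classify_event,
    cluster_to_substrates,
    compare_site_lists,
    decapping_reads_at_tss,
    degradome_fraction,
    merge_proximal,
    netseq_crosscheck,
    pair_two_sided,
)


def site(pos, wt=10.0, strand="+", contig="chrI"):
    return ComPARESite(contig, strand, pos, [wt, wt], [0.0, 0.0], [9.0, 9.0], True)


def simple_annotation():
    return AnnotationIndex([
        AnnotationFeature("GENE1", "chrI", "+", "gene", 100, 700, tss=100),
        AnnotationFeature("GENE1_5utr", "chrI", "+", "five_prime_UTR", 100, 150),
        AnnotationFeature("GENE1_cds1", "chrI", "+", "CDS", 150, 300),
        AnnotationFeature("GENE1_cds2", "chrI", "+", "CDS", 400, 650),
        AnnotationFeature("GENE1_3utr", "chrI", "+", "three_prime_UTR", 650, 700),
        AnnotationFeature("GENE1_intron", "chrI", "+", "intron", 300, 400),
        AnnotationFeature("SNR1", "chrI", "+", "ncRNA", 340, 360, tss=340),
        AnnotationFeature("GENE2", "chrI", "-", "gene", 900, 1200, tss=1199),
    ])


class TestMergeProximal:
    def test_adjacent_sites_merge_with_high_cpm_anchor(self):
        ev = merge_proximal([site(100, wt=2), site(101, wt=9)])
        assert len(ev) == 1
        assert ev[0].anchor_pos == 101
        assert ev[0].n_sites == 2

    def test_gap_above_window_splits(self):
        ev = merge_proximal([site(100), site(106)], max_gap=5)
        assert [e.anchor_pos for e in ev] == [100, 106]
        ev2 = merge_proximal([site(100), site(105)], max_gap=5)
        assert len(ev2) == 1

    def test_empty_and_unsorted(self):
        assert merge_proximal([]) == []
        with pytest.raises(ValueError, match="sorted"):
            merge_proximal([site(10), site(5)])

    def test_strand_boundary_not_merged(self):
        ev = merge_proximal(sorted([site(100, strand="+"), site(101, strand="-")],
                                   key=lambda s: s.key()))
        assert len(ev) == 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 500), max_size=30))
    def test_idempotent_and_partition(self, positions):
        sites = [site(p) for p in sorted(positions)]
        events = merge_proximal(sites)
        # partition: every site in exactly one event
        assert sorted(s.pos for e in events for s in e.member_sites) == sorted(positions)
        # idempotence: merging the event anchors again never splits further
        anchors = sorted(e.anchor_pos for e in events)
        again = merge_proximal([site(a) for a in anchors])
        assert len(again) <= len(events)
        # single-linkage oracle: events break exactly at gaps > 5
        runs = 0
        prev = None
        for p in sorted(positions):
            if prev is None or p - prev > 5:
                runs += 1
            prev = p
        assert len(events) == runs


class TestPairTwoSided:
    def test_canonical_34nt_pair(self):
        ev = merge_proximal([site(100), site(134)])
        pairs, unpaired = pair_two_sided(ev)
        assert len(pairs) == 1 and not unpaired
        assert pairs[0].spacing == 34
        assert pairs[0].upstream_event.anchor_pos == 100

    def test_out_of_tolerance_not_paired(self):
        ev = merge_proximal([site(100), site(150)])
        pairs, unpaired = pair_two_sided(ev)
        assert pairs == [] and len(unpaired) == 2

    def test_single_event_left_unpaired(self):
        ev = merge_proximal([site(100)])
        pairs, unpaired = pair_two_sided(ev)
        assert pairs == [] and len(unpaired) == 1

    def test_minus_strand_transcript_orientation(self):
        ev = merge_proximal([site(100, strand="-"), site(134, strand="-")])
        pairs, _ = pair_two_sided(ev)
        # on the minus strand the transcript-upstream event is genome-rightmost
        assert pairs[0].upstream_event.anchor_pos == 134

    def test_nearest_spacing_wins(self):
        # two downstream candidates within tolerance: the one closest to 34 wins
        ev = merge_proximal([site(100), site(130), site(136)])
        assert len(ev) == 3
        pairs, unpaired = pair_two_sided(ev)
        assert len(pairs) == 1
        assert pairs[0].downstream_event.anchor_pos == 136
        assert [e.anchor_pos for e in unpaired] == [130]


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (200, "+", "CDS"),
            (120, "+", "five_prime_UTR"),
            (660, "+", "three_prime_UTR"),
            (320, "+", "intron"),
            (350, "+", "ncRNA"),  # intron-hosted ncRNA outranks the intron
            (1000, "+", "antisense"),
            (800, "+", "intergenic"),
        ],
    )
    def test_priority_rule(self, pos, strand, expected):
        ev = merge_proximal([site(pos, strand=strand)])[0]
        assert classify_event(ev, simple_annotation()) == expected


class TestClusterToSubstrates:
    def test_paired_events_in_one_cds_form_one_substrate(self):
        ann = simple_annotation()
        ev = merge_proximal([site(200), site(201), site(235)])
        pairs, _ = pair_two_sided(ev)
        subs = cluster_to_substrates(ev, pairs, ann)
        assert len(subs) == 1
        s = subs[0]
        assert s.feature_id == "GENE1" and s.category == "CDS"
        assert s.n_sites == 3 and len(s.pairs) == 1

    def test_adjacent_genes_stay_separate(self):
        ann = simple_annotation()
        ev = merge_proximal(sorted(
            [site(200), site(1000, strand="-")], key=lambda s: s.key()))
        subs = cluster_to_substrates(ev, [], ann)
        assert {s.feature_id for s in subs} == {"GENE1", "GENE2"}

    def test_intergenic_orphans_cluster_by_window(self):
        ann = simple_annotation()
        ev = merge_proximal([site(2000), site(2050), site(2900)])
        subs = cluster_to_substrates(ev, [], ann, orphan_window=200)
        assert len(subs) == 2
        assert all(s.category == "intergenic" for s in subs)

    def test_partition_invariant_on_simulated_data(self, default_fixture):
        _, fx, sites = default_fixture
        sites = sorted(sites, key=lambda s: s.key())
        ev = merge_proximal(sites)
        pairs, _ = pair_two_sided(ev)
        subs = cluster_to_substrates(ev, pairs, fx.annotation)
        assert sum(s.n_sites for s in subs) == len(sites)
        # category counts sum to substrate count
        from collections import Counter

        counts = Counter(s.category for s in subs)
        assert sum(counts.values()) == len(subs)

    def test_fully_paired_perfect_hairpins_have_34nt_spacing(self, default_fixture):
        # bulge-free simulation: every recovered two-sided event pair spans 34 nt
        _, fx, sites = default_fixture
        ev = merge_proximal(sorted(sites, key=lambda s: s.key()))
        pairs, unpaired = pair_two_sided(ev)
        assert pairs and all(p.spacing == 34 for p in pairs)


class TestCompareSiteLists:
    def test_identical_lists(self):
        a = [("chrI", "+", 100), ("chrI", "+", 200)]
        cmp = compare_site_lists(a, list(a))
        assert cmp.jaccard == 1.0 and not cmp.a_only and not cmp.b_only

    def test_tolerance_match(self):
        cmp = compare_site_lists([("chrI", "+", 100)], [("chrI", "+", 101)], tolerance=1)
        assert len(cmp.matched) == 1

    def test_jaccard_one_third(self):
        cmp = compare_site_lists(
            [("chrI", "+", 100), ("chrI", "+", 200)],
            [("chrI", "+", 100), ("chrI", "+", 300)],
        )
        assert cmp.jaccard == pytest.approx(1 / 3)

    def test_strand_and_contig_must_match(self):
        cmp = compare_site_lists([("chrI", "+", 100)], [("chrI", "-", 100)])
        assert not cmp.matched

    def test_one_to_one_nearest_first(self):
        cmp = compare_site_lists(
            [("chrI", "+", 100), ("chrI", "+", 101)], [("chrI", "+", 100)]
        )
        assert cmp.matched == [(("chrI", "+", 100), ("chrI", "+", 100))]
        assert cmp.a_only == [("chrI", "+", 101)]


class TestDegradomeFraction:
    @pytest.mark.parametrize("c,d,expected", [(90, 10, 0.9), (0, 10, 0.0), (10, 0, 1.0)])
    def test_arithmetic(self, c, d, expected):
        assert degradome_fraction(c, d) == expected

    def test_both_zero_is_undefined_not_zero(self):
        assert math.isnan(degradome_fraction(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            degradome_fraction(-1, 5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e5), st.floats(0.01, 1e5), st.floats(0.01, 1e3))
    def test_scale_invariance(self, c, d, k):
        assert degradome_fraction(c * k, d * k) == pytest.approx(degradome_fraction(c, d))


class TestDecappingAtTss:
    def gene(self):
        return AnnotationFeature("G", "chrI", "+", "gene", 100, 500, tss=100)

    def test_peak_at_tss(self):
        t = EndCountTrack("chrI", "+", {100: 7.0}, scale="cpm")
        assert decapping_reads_at_tss(t, self.gene()) == 7.0

    def test_window_edge_exclusive_beyond_25(self):
        t = EndCountTrack("chrI", "+", {126: 3.0}, scale="cpm")
        assert decapping_reads_at_tss(t, self.gene(), window=25) == 0.0
        t2 = EndCountTrack("chrI", "+", {125: 3.0}, scale="cpm")
        assert decapping_reads_at_tss(t2, self.gene(), window=25) == 3.0

    def test_interval_sum(self):
        t = EndCountTrack("chrI", "+", {100: 2.0, 110: 5.0, 400: 9.0}, scale="cpm")
        assert decapping_reads_at_tss(t, self.gene()) == 7.0


class TestNetseqCrosscheck:
    def test_plus_strand_offset(self):
        ns = EndCountTrack("chrI", "+", {499: 5.0}, end_type="three_prime")
        m = netseq_crosscheck([("chrI", "+", 500)], ns, min_netseq=1.0)
        assert len(m) == 1 and m[0].netseq_pos == 499

    def test_same_position_is_not_a_match(self):
        ns = EndCountTrack("chrI", "+", {500: 5.0}, end_type="three_prime")
        assert netseq_crosscheck([("chrI", "+", 500)], ns) == []

    def test_minus_strand_mirror(self):
        ns = EndCountTrack("chrI", "-", {501: 5.0}, end_type="three_prime")
        m = netseq_crosscheck([("chrI", "-", 500)], ns)
        assert len(m) == 1 and m[0].netseq_pos == 501

    def test_wrong_end_type_rejected(self):
        five = EndCountTrack("chrI", "+", {499: 5.0}, end_type="five_prime")
        with pytest.raises(ValueError, match="three_prime"):
            netseq_crosscheck([("chrI", "+", 500)], five)

    def test_threshold_applied(self):
        ns = EndCountTrack("chrI", "+", {499: 0.5}, end_type="three_prime")
        assert netseq_crosscheck([("chrI", "+", 500)], ns, min_netseq=1.0) == []


class TestGff3Loading:
    def test_round_trip_through_gff3(self, tmp_path):
        from parekit.simulate import write_gff3

        feats = [
            AnnotationFeature("G1", "chrI", "+", "gene", 10, 50, tss=10),
            AnnotationFeature("G1_cds", "chrI", "+", "CDS", 15, 45),
            AnnotationFeature("N1", "chrI", "-", "ncRNA", 60, 90, tss=89),
        ]
        p = tmp_path / "a.gff3"
        write_gff3(feats, p)
        idx = AnnotationIndex.from_gff3(p)
        got = {(f.feature_id, f.kind, f.start, f.end, f.tss) for f in idx.features}
        assert ("G1", "gene", 10, 50, 10) in got
        assert ("G1_cds", "CDS", 15, 45, None) in got
        assert ("N1", "ncRNA", 60, 90, 89) in got
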