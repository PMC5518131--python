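"""scaffolding: mate sampling arithmetic and determinism, exact mapping
against a substring-search oracle, link bundling with a planted gap, the
greedy layout, coverage profiles, and the QC filter/split rules."""

import numpy as np
import pytest

from tandemscope import (
    MateLink,
    QcParams,
    ScaffoldParams,
    SequenceRecord,
    bundle_links,
    coverage_profile,
    filter_and_split_scaffolds,
    layout_scaffolds,
    layout_to_sequences,
    map_mates_exact,
    sample_synthetic_mates,
    extract_contigs,
    simulate_long_read_placements,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def small_params():
    return ScaffoldParams(
        read_len=100,
        insert_sizes=(1000,),
        coverage_per_insert=20,
        rng_seed=5,
    )


class TestSampling:
    def test_insert_exceeding_scaffold_gives_zero(self):
        params = ScaffoldParams(rng_seed=1)
        scf = SequenceRecord("s", "ACGT" * 25_000)  # 100 kb
        mates = [
            m
            for m in sample_synthetic_mates([scf], params)
            if m.insert_class == 160_000
        ]
        assert mates == []

    def test_pair_count_formula_and_sampled_coverage(self, rng):
        # ~20X from 2x100 bp pairs on 50 kb: n = 20*50000/(2*100) = 5000
        params = ScaffoldParams(
            read_len=100, insert_sizes=(1000,), coverage_per_insert=20, rng_seed=3
        )
        scf = SequenceRecord("s", random_seq(rng, 50_000))
        mates = sample_synthetic_mates([scf], params)
        assert len(mates) <= 5000  # end-overhang pairs skipped
        sampled_bases = sum(len(m.read1) + len(m.read2) for m in mates)
        assert sampled_bases / len(scf) == pytest.approx(20, rel=0.1)

    def test_determinism(self, rng):
        scf = SequenceRecord("s", random_seq(rng, 20_000))
        params = ScaffoldParams(
            read_len=100, insert_sizes=(1000,), coverage_per_insert=5, rng_seed=9
        )
        assert sample_synthetic_mates([scf], params) == sample_synthetic_mates(
            [scf], params
        )

    def test_reads_match_guide_innie(self, rng):
        scf = SequenceRecord("s", random_seq(rng, 5000))
        params = ScaffoldParams(
            read_len=100, insert_sizes=(1000,), coverage_per_insert=2, rng_seed=2
        )
        comp = str.maketrans("ACGT", "TGCA")
        for m in sample_synthetic_mates([scf], params):
            assert m.read1 == scf.sequence[m.pos1 : m.pos1 + 100]
            assert m.read2 == scf.sequence[m.pos2 : m.pos2 + 100].translate(comp)[::-1]


class TestMapping:
    def test_verbatim_read_placed_at_source(self, rng, small_params):
        contig = SequenceRecord("c0", random_seq(rng, 3000))
        mates = sample_synthetic_mates([contig], small_params)
        placements = map_mates_exact(mates, [contig])
        by_key = {(p.pair_id, p.mate): p for p in placements}
        for m in mates:
            p1 = by_key[(m.pair_id, 1)]
            assert (p1.contig_id, p1.start, p1.strand) == ("c0", m.pos1, "+")
            p2 = by_key[(m.pair_id, 2)]
            assert (p2.contig_id, p2.start, p2.strand) == ("c0", m.pos2, "-")

    def test_read_in_two_contigs_unmapped(self, rng):
        shared = random_seq(rng, 300)
        contigs = [
            SequenceRecord("c0", shared + random_seq(rng, 200)),
            SequenceRecord("c1", random_seq(rng, 200) + shared),
        ]
        from tandemscope.scaffolding import MatePair

        pair = MatePair("p", "g", 1000, 0, 0, shared[:100], shared[100:200])
        assert map_mates_exact([pair], contigs, k=31) == []

    def test_agrees_with_brute_force_substring_search(self, rng):
        comp = str.maketrans("ACGTN", "TGCAN")
        contigs = [SequenceRecord(f"c{i}", random_seq(rng, 500)) for i in range(4)]
        from tandemscope.scaffolding import MatePair

        reads = [c.sequence[s : s + 60] for c in contigs for s in (0, 200, 440)]
        reads.append(random_seq(rng, 60))  # absent read
        pairs = [
            MatePair(f"p{i}", "g", 500, 0, 0, r, r) for i, r in enumerate(reads)
        ]
        placements = map_mates_exact(pairs, contigs, k=31)
        placed = {(p.pair_id, p.mate): (p.contig_id, p.start) for p in placements}
        for i, read in enumerate(reads):
            rc = read.translate(comp)[::-1]
            occurrences = []
            for c in contigs:
                for probe, strand in ((read, "+"), (rc, "-")):
                    start = 0
                    while (pos := c.sequence.find(probe, start)) != -1:
                        occurrences.append((c.id, pos, strand))
                        start = pos + 1
            if len(occurrences) == 1:
                assert placed[(f"p{i}", 1)] == occurrences[0][:2]
            else:
                assert (f"p{i}", 1) not in placed


class TestBundling:
    def _planted_gap_setup(self, rng, gap):
        genome = random_seq(rng, 30_000)
        cut = 14_000
        contigs = [
            SequenceRecord("c0", genome[:cut]),
            SequenceRecord("c1", genome[cut + gap :]),
        ]
        guide = [SequenceRecord("g", genome)]
        params = ScaffoldParams(
            read_len=500,
            insert_sizes=(10_000,),
            coverage_per_insert=30,
            rng_seed=21,
        )
        mates = sample_synthetic_mates(guide, params)
        placements = map_mates_exact(mates, contigs)
        links = bundle_links(
            mates, placements, params, {c.id: len(c) for c in contigs}
        )
        return links

    def test_planted_gap_recovered(self, rng):
        (link,) = self._planted_gap_setup(rng, gap=5000)
        assert {link.contig_a, link.contig_b} == {"c0", "c1"}
        assert (link.end_a, link.end_b) == ("R", "L")
        assert link.gap_estimate == pytest.approx(5000, abs=1500)
        assert link.support >= 2

    def test_support_threshold_drops_singletons(self, rng, small_params):
        from tandemscope.scaffolding import MatePlacement, MatePair

        pair = MatePair("p0", "g", 1000, 0, 0, "A" * 100, "A" * 100)
        placements = [
            MatePlacement("p0", 1, "c0", 400, 500, "+"),
            MatePlacement("p0", 2, "c1", 0, 100, "-"),
        ]
        links = bundle_links(
            [pair], placements, small_params, {"c0": 500, "c1": 500}
        )
        assert links == []  # min_link_support = 2

    def test_intra_contig_pairs_only_gives_empty(self, rng, small_params):
        contig = SequenceRecord("c0", random_seq(rng, 3000))
        mates = sample_synthetic_mates([contig], small_params)
        placements = map_mates_exact(mates, [contig])
        assert (
            bundle_links(mates, placements, small_params, {"c0": 3000}) == []
        )


class TestLayout:
    def test_no_links_gives_singletons(self, rng):
        contigs = [SequenceRecord(f"c{i}", random_seq(rng, 100)) for i in range(3)]
        layouts = layout_scaffolds(contigs, [])
        assert len(layouts) == 3
        assert all(len(l.entries) == 1 for l in layouts)

    def test_three_contig_path_in_true_order(self):
        contigs = [SequenceRecord(f"c{i}", "ACGT" * 25) for i in range(3)]
        links = [
            MateLink("c0", "R", "c1", "L", 50, 10),
            MateLink("c1", "R", "c2", "L", 30, 8),
        ]
        (layout,) = layout_scaffolds(contigs, links)
        assert [(c, o) for c, o, _ in layout.entries] == [
            ("c0", "+"),
            ("c1", "+"),
            ("c2", "+"),
        ]

    def test_conflicting_links_higher_support_wins(self):
        contigs = [SequenceRecord(c, "ACGT" * 25) for c in ("a", "b", "bp")]
        links = [
            MateLink("a", "R", "b", "L", 40, 10),
            MateLink("a", "R", "bp", "L", 40, 3),
        ]
        layouts = layout_scaffolds(contigs, links)
        joined = {
            tuple(c for c, _, _ in l.entries) for l in layouts if len(l.entries) > 1
        }
        assert joined == {("a", "b")}

    def test_occupancy_no_contig_twice(self):
        contigs = [SequenceRecord(f"c{i}", "ACGT" * 25) for i in range(5)]
        links = [
            MateLink("c0", "R", "c1", "L", 40, 9),
            MateLink("c1", "R", "c2", "L", 40, 8),
            MateLink("c3", "R", "c1", "L", 40, 7),  # contends for c1 L end
            MateLink("c3", "R", "c4", "L", 40, 6),
        ]
        layouts = layout_scaffolds(contigs, links)
        seen = [c for l in layouts for c, _, _ in l.entries]
        assert sorted(seen) == sorted(set(seen))
        assert sorted(seen) == [f"c{i}" for i in range(5)]

    def test_cycle_refused(self):
        contigs = [SequenceRecord(f"c{i}", "ACGT" * 25) for i in range(2)]
        links = [
            MateLink("c0", "R", "c1", "L", 40, 9),
            MateLink("c0", "L", "c1", "R", 40, 8),  # would close a ring
        ]
        (layout,) = layout_scaffolds(contigs, links)
        assert len(layout.entries) == 2

    def test_layout_sequences_invert_via_contig_extraction(self):
        contigs = [
            SequenceRecord("c0", "ACGTACGTACGTACGTACGTACGT"),
            SequenceRecord("c1", "TTTTGGGGCCCCAAAATTTTGGGG"),
        ]
        links = [MateLink("c0", "R", "c1", "L", 5, 4)]  # gap below floor
        (scaffold,) = layout_to_sequences(layout_scaffolds(contigs, links), contigs)
        pieces = extract_contigs(scaffold, min_n_run=20)
        assert [p.sequence for p in pieces] == [c.sequence for c in contigs]


class TestCoverageQc:
    def test_single_read_profile(self):
        cov = coverage_profile([(0, 100)], 200)
        assert cov[:100].min() == 1 and cov[100:].max() == 0

    def test_conservation(self, rng):
        placements = [
            (int(s), int(s) + 50) for s in rng.integers(0, 950, size=200)
        ]
        cov = coverage_profile(placements, 1000)
        assert cov.sum() == sum(e - s for s, e in placements)

    def test_empty_all_zero(self):
        assert coverage_profile([], 50).max() == 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            coverage_profile([(50, 120)], 100)

    def test_read_filter_boundary_14_vs_15(self, rng):
        scaffold = SequenceRecord("s", random_seq(rng, 1000))
        p14 = [(0, 1000)] * 14
        p15 = [(0, 1000)] * 15
        assert filter_and_split_scaffolds([scaffold], {"s": p14}) == []
        assert len(filter_and_split_scaffolds([scaffold], {"s": p15})) == 1

    def test_uniform_2x_unchanged(self, rng):
        # coverage exactly at the threshold is kept ("less than 2X" splits)
        scaffold = SequenceRecord("s", random_seq(rng, 1000))
        placements = [(0, 1000)] * 16  # 16X uniform
        out = filter_and_split_scaffolds([scaffold], {"s": placements})
        assert out == [scaffold]

    def test_interior_dip_splits_into_two(self, rng):
        scaffold = SequenceRecord("s", random_seq(rng, 3000))
        # 3X everywhere except a 1X window over [1200, 1800)
        placements = (
            [(0, 1800)] * 2 + [(1200, 3000)] * 2 + [(0, 3000)]
        )
        # coverage: [0,1200) = 3, [1200,1800) = ... build explicitly instead
        placements = [(0, 1200)] * 3 + [(1200, 1800)] * 1 + [(1800, 3000)] * 3
        placements += [(0, 3000)] * 12  # reach the 15-read floor, adds 12X
        out = filter_and_split_scaffolds(
            [scaffold], {"s": placements}, QcParams(min_split_coverage=15)
        )
        assert len(out) == 2
        assert out[0].sequence == scaffold.sequence[:1200]
        assert out[1].sequence == scaffold.sequence[1800:]
        assert out[0].id.endswith("_0") and out[1].id.endswith("_1800")

    def test_short_pieces_dropped(self, rng):
        scaffold = SequenceRecord("s", random_seq(rng, 1000))
        placements = [(0, 100)] * 2 + [(900, 1000)] * 2 + [(0, 1000)] * 13
        # interior at 13X < 15 with min_split_coverage=15 -> only the two
        # 100 bp flanks survive the split; min_piece_len=200 drops them
        out = filter_and_split_scaffolds(
            [scaffold],
            {"s": placements},
            QcParams(min_split_coverage=15, min_piece_len=200),
        )
        assert out == []

    def test_base_conservation_after_split(self, rng):
        scaffold = SequenceRecord("s", random_seq(rng, 2000))
        placements = [(0, 800)] * 2 + [(1200, 2000)] * 2
        placements += [(0, 2000)] * 10  # 14 reads: removed by read filter
        assert filter_and_split_scaffolds([scaffold], {"s": placements}) == []
        placements += [(0, 2000)] * 5  # 19 reads
        # 15 full-length reads give 15X everywhere; the flank reads lift
        # [0,800) and [1200,2000) to 17X, so a 16X threshold splits there
        out = filter_and_split_scaffolds(
            [scaffold], {"s": placements}, QcParams(min_split_coverage=16)
        )
        cov = coverage_profile(placements, 2000)
        # output = kept-run bases minus runs shorter than min_piece_len,
        # and every piece is the verbatim substring at its recorded offset
        kept_runs = []
        start = None
        for i, ok in enumerate(cov >= 16):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                kept_runs.append((start, i))
                start = None
        if start is not None:
            kept_runs.append((start, 2000))
        expected = [(s, e) for s, e in kept_runs if e - s >= 200]
        assert [len(p) for p in out] == [e - s for s, e in expected]
        for piece, (s, e) in zip(out, expected):
            assert piece.sequence == scaffold.sequence[s:e]
            assert piece.id.endswith(f"_{s}")


class TestLongReadSim:
    def test_zero_coverage_empty(self):
        assert simulate_long_read_placements(10_000, 0, 100, seed=1) == []

    def test_counting_formula(self):
        placements = simulate_long_read_placements(1_000_000, 20, 10_000, seed=2)
        assert len(placements) == 2000

    def test_mean_coverage_within_tolerance(self):
        length, target = 1_000_000, 20
        placements = simulate_long_read_placements(length, target, 10_000, seed=3)
        cov = coverage_profile(placements, length)
        assert float(cov.mean()) == pytest.approx(target, rel=0.05)
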