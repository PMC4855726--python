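import numpy as np
import pytest

from memcorrect import dbg
from memcorrect._util import revcomp
from memcorrect.aligner import (
    CorrectedRead,
    ErrorModel,
    GraphAlignment,
    RunConfig,
    align_read,
    alignment_from_mapping,
    chain_within_node,
    correct_read,
    extend_unique,
    filter_mappings,
    link_chains,
    seed_distance_compatible,
)
from memcorrect.mem_index import MEMSeed, build_index
from memcorrect.seqio import SequenceRecord
from memcorrect.simulate import LongReadProfile, random_genome, simulate_long_reads

from oracles import best_chain_by_enumeration

MODEL = ErrorModel(0.09, 0.045, 0.015)


def seed(read_start, node_start, length, node_id=0, strand="+"):
    return MEMSeed(node_id, strand, node_start, read_start, length)


class TestErrorModel:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ErrorModel(0.5, 0.4, 0.2)
        with pytest.raises(ValueError):
            ErrorModel(-0.1, 0.0, 0.0)

    def test_gap_window_factors(self):
        m = ErrorModel(0.10, 0.05, 0.0)
        assert m.gap_shrink == pytest.approx(1 / 1.2)
        assert m.gap_stretch == pytest.approx(1 / 0.9)


class TestSeedCompatibility:
    def test_equal_gaps_always_compatible(self):
        a, b = seed(0, 0, 20), seed(120, 120, 20)  # both gaps 100
        assert seed_distance_compatible(a, b, MODEL)
        assert seed_distance_compatible(a, b, ErrorModel(0.3, 0.3, 0.3))

    def test_read_gap_far_exceeding_window_rejected(self):
        # g_n=100, i=0.10, d=0.05: upper bound 100/0.9 + 10 ~ 121 < 200
        m = ErrorModel(0.10, 0.05, 0.0)
        a, b = seed(0, 0, 20), seed(220, 120, 20)
        assert not seed_distance_compatible(a, b, m)

    def test_order_violation_rejected(self):
        a = seed(100, 0, 20)
        b = seed(50, 120, 20)  # before a on the read, after on the node
        assert not seed_distance_compatible(a, b, MODEL)


class TestChaining:
    def test_single_seed(self):
        maps = chain_within_node([seed(5, 7, 25)], MODEL)
        assert len(maps) == 1 and maps[0].seeds == [seed(5, 7, 25)]

    def test_two_compatible_seeds_one_mapping(self):
        s1, s2 = seed(0, 0, 20), seed(50, 52, 20)
        maps = chain_within_node([s1, s2], MODEL)
        assert len(maps) == 1 and maps[0].seeds == [s1, s2]

    def test_order_inconsistent_middle_seed_dropped(self):
        s1, s2, s3 = seed(0, 0, 20), seed(40, 300, 10), seed(50, 52, 20)
        maps = chain_within_node([s1, s2, s3], MODEL, min_weight=15)
        assert maps[0].seeds == [s1, s3]
        assert maps[0].weight == best_chain_by_enumeration([s1, s2, s3], MODEL)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_subset_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 12))
        seeds = [
            seed(int(rng.integers(0, 500)), int(rng.integers(0, 500)), int(rng.integers(5, 40)))
            for _ in range(n)
        ]
        maps = chain_within_node(seeds, MODEL)
        assert maps[0].weight == best_chain_by_enumeration(seeds, MODEL)


class TestFilterMappings:
    def _graph_one_node(self, length=1000):
        g = random_genome(length + 50, seed=55)
        return dbg.graph_from_sequence(g.sequence[: length + 30], k=21), g

    def test_contained_mapping_removed(self):
        graph, _ = self._graph_one_node()
        big = chain_within_node([seed(100, 100, 30), seed(160, 162, 30)], MODEL)[0]
        small = chain_within_node([seed(120, 400, 25)], MODEL)[0]
        kept = filter_mappings([big, small], graph, MODEL, l_used=20)
        assert kept == [big]

    def test_sparse_coverage_removed(self):
        # read span ~900 with only 40 seed bases: far below the expected
        # coverage by exact regions for a 15% error read
        graph, _ = self._graph_one_node(1000)
        sparse = chain_within_node([seed(0, 0, 20), seed(880, 900, 20)], MODEL)[0]
        kept = filter_mappings([sparse], graph, MODEL, l_used=20)
        assert kept == []

    def test_adequate_coverage_kept_with_zero_safety(self):
        graph, _ = self._graph_one_node(1000)
        sparse = chain_within_node([seed(0, 0, 20), seed(880, 900, 20)], MODEL)[0]
        kept = filter_mappings([sparse], graph, MODEL, l_used=20, cover_safety=0.0)
        assert kept == [sparse]


def manual_chain_graph(k=21, n_nodes=3, node_len=100, seed_val=61):
    """A hand-assembled linear chain of nodes with (k-1) overlaps.

    Bypasses the builder (whose compaction would merge a forced chain) to
    exercise path-walking primitives on multi-node paths.
    """
    step = node_len - (k - 1)
    g = random_genome(node_len + step * (n_nodes - 1) + 10, seed=seed_val).sequence
    graph = dbg.DeBruijnGraph(k=k)
    for i in range(n_nodes):
        s = g[i * step : i * step + node_len]
        graph.nodes[i] = dbg.GraphNode(i, s, 10.0)
    for i in range(n_nodes - 1):
        graph.arcs.add(((i, "+"), (i + 1, "+")))
        graph.arcs.add(((i + 1, "-"), (i, "-")))
    return graph, g[: node_len + step * (n_nodes - 1)]


class TestExtendUnique:
    def test_extends_across_linear_chain(self, genome_20kb, perfect_graph_20kb):
        # single-node graph: nothing to extend, input returned unchanged
        m = chain_within_node([seed(0, 100, 30)], MODEL)[0]
        aln = alignment_from_mapping(m)
        out = extend_unique(perfect_graph_20kb, aln, "right", 500, MODEL)
        assert out.path == aln.path

    def test_extends_to_full_path_both_directions(self):
        graph, _full = manual_chain_graph(n_nodes=3)
        m = chain_within_node([seed(0, 5, 30, node_id=1)], MODEL)[0]
        aln = alignment_from_mapping(m)
        out = extend_unique(graph, aln, "right", 400, MODEL)
        out = extend_unique(graph, out, "left", 400, MODEL)
        assert out.path == [(0, "+"), (1, "+"), (2, "+")]
        assert out.anchor_left[0] == 1  # anchor index shifted by the prepend

    def test_overlong_branch_pruned(self):
        # branch point with one short and one long target; small remaining
        # read gap admits only the short branch
        k = 21
        g = random_genome(4000, seed=67).sequence
        stem = g[:100]
        short_branch = stem[-(k - 1) :] + g[100:160]
        long_branch = stem[-(k - 1) :] + g[1000:3000]
        reads = [
            SequenceRecord("s1", stem + short_branch[k - 1 :][:30]),
            SequenceRecord("s2", stem + long_branch[k - 1 :][:30]),
            SequenceRecord("b1", short_branch),
            SequenceRecord("b2", long_branch),
        ]
        graph = dbg.build_graph(reads, k)
        stem_hits = [
            (nid, "+" if stem[10:60] in n.sequence else "-")
            for nid, n in graph.nodes.items()
            if stem[10:60] in n.sequence or stem[10:60] in revcomp(n.sequence)
        ]
        nid, ori = stem_hits[0]
        node_len = len(graph.nodes[nid])
        m = chain_within_node(
            [seed(0, node_len - 40 if ori == "+" else 10, 30, node_id=nid, strand=ori)],
            MODEL,
        )[0]
        aln = alignment_from_mapping(m)
        out = extend_unique(graph, aln, "right", 100, MODEL)
        assert len(out.path) == 2  # took exactly the short branch
        tgt = out.path[-1][0]
        assert len(graph.nodes[tgt]) < 200

    def test_ambiguous_branch_stops(self):
        # two short branch targets survive any length bound: extension halts
        graph, _ = manual_chain_graph(n_nodes=2)
        extra = random_genome(100, seed=91).sequence
        graph.nodes[2] = dbg.GraphNode(2, extra, 10.0)
        graph.arcs.add(((0, "+"), (2, "+")))
        graph.arcs.add(((2, "-"), (0, "-")))
        m = chain_within_node([seed(0, 5, 30, node_id=0)], MODEL)[0]
        out = extend_unique(graph, alignment_from_mapping(m), "right", 500, MODEL)
        assert out.path == [(0, "+")]


class TestLinkChains:
    def test_adjacent_mappings_on_one_node_join(self, genome_20kb, perfect_graph_20kb):
        node = perfect_graph_20kb.nodes[0]
        m1 = chain_within_node([seed(0, 1000, 40)], MODEL)[0]
        m2 = chain_within_node([seed(140, 1140, 40)], MODEL)[0]
        a1, a2 = alignment_from_mapping(m1), alignment_from_mapping(m2)
        joined = link_chains(perfect_graph_20kb, a1, a2, MODEL)
        assert joined is not None
        assert joined.read_start == 0 and joined.read_end == 180

    def test_incompatible_gap_deferred(self, perfect_graph_20kb):
        # read gap 1000 vs spelled gap 100: no window can absorb that
        m1 = chain_within_node([seed(0, 1000, 40)], MODEL)[0]
        m2 = chain_within_node([seed(1040, 1140, 40)], MODEL)[0]
        a1, a2 = alignment_from_mapping(m1), alignment_from_mapping(m2)
        assert link_chains(perfect_graph_20kb, a1, a2, MODEL) is None

    def test_gap_window_bounds(self):
        m = ErrorModel(0.10, 0.0, 0.0)
        # n=1200 read-side gap, i=0.10: minimum acceptable spelled gap is
        # 1200/1.2 = 1000 (minus slack 60); 800 is rejected, 1050 accepted
        g = random_genome(5000, seed=71).sequence
        graph = dbg.graph_from_sequence(g, 31)
        for spelled_gap, expect in ((800, False), (1050, True)):
            m1 = chain_within_node([seed(0, 100, 40)], m)[0]
            m2 = chain_within_node(
                [seed(40 + 1200, 140 + spelled_gap, 40)], m
            )[0]
            joined = link_chains(
                graph, alignment_from_mapping(m1), alignment_from_mapping(m2), m
            )
            assert (joined is not None) == expect, spelled_gap


class TestShortestPathOracle:
    def test_matches_exhaustive_path_enumeration(self):
        """Uniform-cost gap bridging returns the minimum spelled length over
        all simple paths, checked by DFS enumeration on a 6-node graph."""
        from memcorrect.aligner import _shortest_path

        k = 21
        rng = np.random.default_rng(113)
        graph = dbg.DeBruijnGraph(k=k)
        lengths = [60, 40, 120, 35, 80, 50]
        for i, ln in enumerate(lengths):
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, ln))
            graph.nodes[i] = dbg.GraphNode(i, seq, 10.0)
        arcs = [(0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 5), (1, 4)]
        for a, b in arcs:
            graph.arcs.add((((a, "+")), ((b, "+"))))
            graph.arcs.add((((b, "-")), ((a, "-"))))

        def spelled(nid):
            return len(graph.nodes[nid]) - (k - 1)

        def enumerate_paths(cur, goal, seen):
            if cur == goal:
                yield []
                return
            for (t, ori) in graph.out_arcs((cur, "+")):
                if ori != "+" or t in seen:
                    continue
                for rest in enumerate_paths(t, goal, seen | {t}):
                    yield [t] + rest

        interiors = [p[:-1] for p in enumerate_paths(0, 5, {0}) if p and p[-1] == 5]
        best = min(sum(spelled(n) for n in interior) for interior in interiors)
        got = _shortest_path(graph, (0, "+"), (5, "+"), cap=1000)
        assert got is not None
        assert sum(spelled(n) for n, _ in got) == best


class TestAlignAndCorrect:
    def _config(self, **kw):
        return RunConfig(dbg_k=31, **kw)

    def test_exact_substring_fully_aligned(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        read = genome_20kb.sequence[3000:4000]
        alns = align_read(read, perfect_graph_20kb, idx, self._config())
        assert len(alns) == 1
        assert alns[0].read_start == 0 and alns[0].read_end == 1000

    def test_chimeric_read_yields_two_alignments(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        chimera = genome_20kb.sequence[1000:2500] + genome_20kb.sequence[12000:13500]
        alns = align_read(chimera, perfect_graph_20kb, idx, self._config())
        assert len(alns) == 2
        pieces = correct_read(chimera, alns, perfect_graph_20kb, self._config(), "chi")
        assert len(pieces) == 2
        starts_ends = sorted((p.read_start, p.read_end) for p in pieces)
        assert starts_ends[0][1] <= starts_ends[1][0]  # never overlap

    def test_no_seeds_empty_alignment_and_output(self, perfect_graph_20kb, rng):
        idx = build_index(perfect_graph_20kb)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        alns = align_read(junk, perfect_graph_20kb, idx, self._config())
        assert alns == []
        assert correct_read(junk, alns, perfect_graph_20kb, self._config()) == []

    def test_noisy_reads_recovered_exactly(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        profile = LongReadProfile(mean_length=4000, length_sd=400, rng_seed=83)
        reads, _ = simulate_long_reads(genome_20kb, profile, 10)
        config = self._config()
        genome = genome_20kb.sequence
        n_exact = n_pieces = 0
        for r in reads:
            alns = align_read(r.sequence, perfect_graph_20kb, idx, config)
            for p in correct_read(r.sequence, alns, perfect_graph_20kb, config, r.id):
                n_pieces += 1
                if p.sequence in genome or revcomp(p.sequence) in genome:
                    n_exact += 1
        assert n_pieces > 0 and n_exact == n_pieces

    def test_short_mode_output_length_window(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        profile = LongReadProfile(mean_length=3000, length_sd=300, rng_seed=89)
        reads, _ = simulate_long_reads(genome_20kb, profile, 30)
        config = self._config()
        lo, hi = 1 / (1 + 2 * 0.09), 1 / (1 - 2 * 0.045)
        for r in reads:
            alns = align_read(r.sequence, perfect_graph_20kb, idx, config)
            pieces = correct_read(r.sequence, alns, perfect_graph_20kb, config, r.id)
            main = max(pieces, key=lambda p: len(p.sequence))
            ratio = len(main.sequence) / len(r.sequence)
            assert lo * 0.9 <= ratio <= hi * 1.1

    def test_long_mode_outputs_whole_unitig(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        read = genome_20kb.sequence[5000:6000]
        config = self._config(output_mode="long")
        alns = align_read(read, perfect_graph_20kb, idx, config)
        pieces = correct_read(read, alns, perfect_graph_20kb, config, "r")
        assert len(pieces) == 1
        assert len(pieces[0].sequence) == len(perfect_graph_20kb.nodes[0])

    def test_coverage_gap_splits_output(self, genome_20kb):
        # delete a band of k-mers mid-genome: reads spanning it come out in two pieces
        genome = genome_20kb.sequence
        gap_free = [
            SequenceRecord("left", genome[:10_000]),
            SequenceRecord("right", genome[10_300:]),
        ]
        graph = dbg.build_graph(gap_free, 31)
        idx = build_index(graph)
        config = self._config()
        read = genome[8000:12_500]
        alns = align_read(read, graph, idx, config)
        pieces = correct_read(read, alns, graph, config, "spanning")
        assert len(pieces) == 2
        ivals = sorted((p.read_start, p.read_end) for p in pieces)
        assert ivals[0][1] <= ivals[1][0]

    def test_corrected_reads_rethread(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        profile = LongReadProfile(mean_length=2000, length_sd=200, rng_seed=97)
        reads, _ = simulate_long_reads(genome_20kb, profile, 5)
        config = self._config()
        for r in reads:
            alns = align_read(r.sequence, perfect_graph_20kb, idx, config)
            for p in correct_read(r.sequence, alns, perfect_graph_20kb, config, r.id):
                assert dbg.thread_sequence(perfect_graph_20kb, p.sequence) is not None

    def test_determinism(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        profile = LongReadProfile(mean_length=2500, length_sd=300, rng_seed=101)
        reads, _ = simulate_long_reads(genome_20kb, profile, 5)
        config = self._config()

        def run():
            out = []
            for r in reads:
                alns = align_read(r.sequence, perfect_graph_20kb, idx, config)
                out.extend(
                    (p.id, p.sequence)
                    for p in correct_read(r.sequence, alns, perfect_graph_20kb, config, r.id)
                )
            return out

        assert run() == run()

    def test_piece_naming_convention(self, genome_20kb, perfect_graph_20kb):
        idx = build_index(perfect_graph_20kb)
        read = genome_20kb.sequence[3000:3800]
        config = self._config()
        alns = align_read(read, perfect_graph_20kb, idx, config)
        pieces = correct_read(read, alns, perfect_graph_20kb, config, "myread")
        assert pieces[0].id == "myread/0"
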