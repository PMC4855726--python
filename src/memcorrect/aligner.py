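"""Pseudo-alignment of long noisy reads to the de Bruijn graph, and correction.

The pipeline per read, repeated for up to ``max_passes`` passes over the
still-unaligned regions:

1. seed: maximal exact matches between the region and any oriented node
   (adaptive minimum length);
2. chain: per (node, strand), a maximum-weight chain of pairwise-compatible
   seeds (compatible = the read gap between two seeds falls in the interval
   the node gap predicts under the estimated insertion/deletion rates);
3. filter: drop read-contained local mappings and mappings whose seed
   coverage is implausibly low given the error rate (closed-form expected
   coverage by exact regions);
4. extend and link: walk unique arcs outward, prune over-long branch targets
   by the remaining read gap, and bridge gaps between neighbouring local
   alignments by bounded shortest path (or shortest cycle) whose spelled
   length fits the read gap window [(1+2i)^-1 n, (1-2d)^-1 n].

The best-covering alignment then dictates the corrected sequence: the path
spelling, clipped (short mode) to the estimated read extent beyond the
extremal seeds, or extended maximally along linear paths (long mode).
Discarded read ends that contain alignments of their own are corrected
recursively, so one input read may yield several non-overlapping output
pieces — which is also how coverage gaps and chimeric reads are handled.

No per-base alignment is ever computed; every corrected sequence is by
construction the spelling of a connected path in the graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

from . import theory
from .dbg import DeBruijnGraph, path_sequence
from .mem_index import MEMSeed, SparseSuffixIndex, adaptive_find

_FLIP = {"+": "-", "-": "+"}
Oriented = tuple[int, str]


@dataclass(frozen=True)
class ErrorModel:
    """Estimated per-base insertion, deletion and substitution rates."""

    insertion: float = 0.09
    deletion: float = 0.045
    substitution: float = 0.015

    def __post_init__(self) -> None:
        if min(self.insertion, self.deletion, self.substitution) < 0:
            raise ValueError("error rates must be non-negative")
        if self.insertion + self.deletion + self.substitution >= 1:
            raise ValueError("total error rate must be < 1")

    @property
    def total(self) -> float:
        return self.insertion + self.deletion + self.substitution

    @property
    def gap_shrink(self) -> float:
        """Lower spelled-gap factor: insertions shrink the graph-side gap."""
        return 1.0 / (1.0 + 2.0 * self.insertion)

    @property
    def gap_stretch(self) -> float:
        """Upper spelled-gap factor: deletions stretch the graph-side gap."""
        return 1.0 / (1.0 - 2.0 * self.deletion)


@dataclass
class RunConfig:
    """All correction tunables (graph k, seed length l, passes p, ...)."""

    dbg_k: int = 75
    min_mem: int = 20
    max_passes: int = 5
    output_mode: str = "short"
    sparseness: int = 1
    error_model: ErrorModel = field(default_factory=ErrorModel)
    min_abundance: int = 2
    coverage_ratio: float = 0.5
    adaptive_lo: int = 2
    adaptive_hi: float = 20.0
    adaptive_delta: int = 3
    cover_safety: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_mem < 2:
            raise ValueError("min_mem must be >= 2")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if self.output_mode not in ("short", "long"):
            raise ValueError("output_mode must be 'short' or 'long'")


@dataclass
class LocalMapping:
    """A chained, inexact mapping of one read region onto one oriented node."""

    node_id: int
    strand: str
    read_start: int
    read_end: int
    node_start: int
    node_end: int
    seeds: list[MEMSeed]
    node_cover_fraction: float = 0.0

    @property
    def weight(self) -> int:
        return sum(s.length for s in self.seeds)


@dataclass
class GraphAlignment:
    """A path through the graph with anchored read coordinates.

    Anchors mark where the extremal seeds sit on the path:
    ``(path_index, node_offset, read_position)``.
    """

    path: list[Oriented]
    read_start: int
    read_end: int
    anchor_left: tuple[int, int, int]
    anchor_right: tuple[int, int, int]
    mappings: list[LocalMapping] = field(default_factory=list)

    @property
    def score(self) -> int:
        """Covered read bases (sum of mapped region lengths)."""
        return sum(m.read_end - m.read_start for m in self.mappings)


@dataclass
class CorrectedRead:
    source_id: str
    piece_index: int
    sequence: str
    read_start: int
    read_end: int
    mode: str

    @property
    def id(self) -> str:
        return f"{self.source_id}/{self.piece_index}"


# ---------------------------------------------------------------------------
# seed chaining within a node


def _gap_eps(gap: int) -> float:
    return max(10.0, 0.05 * gap)


def seed_distance_compatible(a: MEMSeed, b: MEMSeed, model: ErrorModel) -> bool:
    """Can seed b follow seed a in one local mapping?

    Requires consistent ordering (b after a on both read and node) and the
    read gap to lie in the interval the node gap predicts from the estimated
    indel rates, with additive slack.
    """
    if b.read_start <= a.read_start or b.node_start <= a.node_start:
        return False
    g_r = b.read_start - a.read_end
    g_n = b.node_start - a.node_end
    g = max(g_n, 0)
    eps = _gap_eps(g)
    lo = g * model.gap_shrink - eps
    hi = g * model.gap_stretch + eps
    return lo <= g_r <= hi


def chain_within_node(
    seeds: list[MEMSeed], model: ErrorModel, min_weight: int = 0, max_chains: int = 20
) -> list[LocalMapping]:
    """Maximum-weight chains of compatible seeds on one (node, strand).

    Longest-increasing-chain dynamic programming, weight = total seed length.
    After extracting the best chain, chaining repeats on the leftover seeds,
    so a node crossed twice by the read yields two mappings. Chains lighter
    than ``min_weight`` are dropped.
    """
    if not seeds:
        return []
    node_id, strand = seeds[0].node_id, seeds[0].strand
    remaining = sorted(seeds, key=lambda s: (s.read_start, s.node_start))
    mappings: list[LocalMapping] = []
    while remaining and len(mappings) < max_chains:
        n = len(remaining)
        best = [s.length for s in remaining]
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                if seed_distance_compatible(remaining[i], remaining[j], model):
                    cand = best[i] + remaining[j].length
                    if cand > best[j]:
                        best[j] = cand
                        prev[j] = i
        j = max(range(n), key=lambda idx: best[idx])
        weight = best[j]
        chain = []
        while j >= 0:
            chain.append(remaining[j])
            j = prev[j]
        chain.reverse()
        if weight < min_weight:
            break
        mappings.append(
            LocalMapping(
                node_id=node_id,
                strand=strand,
                read_start=chain[0].read_start,
                read_end=chain[-1].read_end,
                node_start=chain[0].node_start,
                node_end=chain[-1].node_end,
                seeds=chain,
            )
        )
        used = set(id(s) for s in chain)
        remaining = [s for s in remaining if id(s) not in used]
    return mappings


def _effective_node_extent(mapping: LocalMapping, node_len: int, model: ErrorModel) -> int:
    """Node bases this mapping could plausibly cover: the read span projected
    onto the node (insertions shrink it), capped by the node length."""
    read_span = mapping.read_end - mapping.read_start
    return max(1, min(node_len, round(read_span * model.gap_shrink)))


def filter_mappings(
    mappings: list[LocalMapping],
    graph: DeBruijnGraph,
    model: ErrorModel,
    l_used: int,
    cover_safety: float = 0.5,
) -> list[LocalMapping]:
    """Drop implausible local mappings.

    (a) mappings whose read interval is contained in another mapping's read
    interval (not super-maximal); ties on identical intervals keep the
    heavier one. (b) mappings whose seed coverage falls below ``cover_safety``
    times the expected coverage by exact regions of size >= l_used at the
    estimated total error rate; coverage is measured against the node extent
    the mapping could reach (never more than the node length).
    """
    if not mappings:
        return []
    threshold = cover_safety * theory.expected_coverage(max(model.total, 1e-9), l_used)
    kept: list[LocalMapping] = []
    order = sorted(
        mappings, key=lambda m: (-(m.read_end - m.read_start), -m.weight)
    )
    for m in order:
        contained = any(
            k.read_start <= m.read_start and m.read_end <= k.read_end for k in kept
        )
        if contained:
            continue
        extent = _effective_node_extent(m, len(graph.nodes[m.node_id]), model)
        m.node_cover_fraction = m.weight / extent
        if m.node_cover_fraction < threshold:
            continue
        kept.append(m)
    kept.sort(key=lambda m: (m.read_start, m.node_id))
    return kept


# ---------------------------------------------------------------------------
# path geometry helpers


def _cum_offsets(graph: DeBruijnGraph, path: list[Oriented]) -> list[int]:
    """Spelled start coordinate of each node on the path."""
    cum = [0]
    for nid, _ in path[:-1]:
        cum.append(cum[-1] + len(graph.nodes[nid]) - (graph.k - 1))
    return cum


def _spelled_pos(graph: DeBruijnGraph, path: list[Oriented], idx: int, off: int) -> int:
    return _cum_offsets(graph, path)[idx] + off


def alignment_from_mapping(m: LocalMapping) -> GraphAlignment:
    return GraphAlignment(
        path=[(m.node_id, m.strand)],
        read_start=m.read_start,
        read_end=m.read_end,
        anchor_left=(0, m.node_start, m.read_start),
        anchor_right=(0, m.node_end, m.read_end),
        mappings=[m],
    )


# ---------------------------------------------------------------------------
# unique extension and gap bridging


def extend_unique(
    graph: DeBruijnGraph,
    alignment: GraphAlignment,
    direction: str,
    read_gap: int,
    model: ErrorModel,
    max_nodes: int = 200,
) -> GraphAlignment:
    """Extend an alignment's path outward along forced or length-pruned arcs.

    A unique arc is always taken. At a branch, candidate targets whose
    spelled contribution exceeds the remaining read-gap bound
    (1+2i) * read_gap are pruned; extension continues only if exactly one
    candidate survives. Stops otherwise (the input is returned unchanged in
    the degenerate cases).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    path = list(alignment.path)
    k = graph.k
    bound = (1.0 + 2.0 * model.insertion) * read_gap + k
    added_left = 0
    for _ in range(max_nodes):
        if bound <= 0:
            break
        if direction == "right":
            outs = graph.out_arcs(path[-1])
        else:
            # arcs entering the path head = reverse of arcs out of the flipped head
            outs = [
                (nid, _FLIP[ori]) for (nid, ori) in graph.out_arcs(
                    (path[0][0], _FLIP[path[0][1]])
                )
            ]
        if not outs:
            break
        if len(outs) > 1:
            outs = [t for t in outs if len(graph.nodes[t[0]]) - (k - 1) <= bound]
            if len(outs) != 1:
                break
        tgt = outs[0]
        if tgt in path:  # refuse to loop during blind extension
            break
        if direction == "right":
            path.append(tgt)
        else:
            path.insert(0, tgt)
            added_left += 1
        bound -= len(graph.nodes[tgt[0]]) - (k - 1)
    if added_left or len(path) != len(alignment.path):
        al = alignment.anchor_left
        ar = alignment.anchor_right
        return replace(
            alignment,
            path=path,
            anchor_left=(al[0] + added_left, al[1], al[2]),
            anchor_right=(ar[0] + added_left, ar[1], ar[2]),
        )
    return alignment


def _shortest_path(
    graph: DeBruijnGraph, start: Oriented, goal: Oriented, cap: float
) -> list[Oriented] | None:
    """Uniform-cost search on spelled length from `start`'s end to `goal`'s
    start; returns the interior node list (possibly empty), or None.

    Cost of entering a node is its spelled contribution len - (k-1). The
    search gives the shortest spelled gap; ``cap`` bounds expansion.
    """
    k = graph.k
    # direct arc: empty interior
    if goal in graph.out_arcs(start):
        return []
    pq: list[tuple[int, int, Oriented, tuple]] = []
    counter = 0
    for t in graph.out_arcs(start):
        cost = len(graph.nodes[t[0]]) - (k - 1)
        if cost <= cap:
            heapq.heappush(pq, (cost, counter, t, (t,)))
            counter += 1
    seen: dict[Oriented, int] = {}
    while pq:
        cost, _, cur, interior = heapq.heappop(pq)
        if cur in seen and seen[cur] <= cost:
            continue
        seen[cur] = cost
        if goal in graph.out_arcs(cur):
            return list(interior)
        for t in graph.out_arcs(cur):
            nc = cost + len(graph.nodes[t[0]]) - (k - 1)
            if nc <= cap and (t not in seen or seen[t] > nc):
                heapq.heappush(pq, (nc, counter, t, interior + (t,)))
                counter += 1
    return None


def _shortest_cycle(graph: DeBruijnGraph, at: Oriented, cap: float) -> list[Oriented] | None:
    """Shortest cycle through `at` (interior nodes, excluding `at` itself)."""
    return _shortest_path(graph, at, at, cap)


def _path_overlap(left: list[Oriented], right: list[Oriented]) -> int:
    """Largest o such that left[-o:] == right[:o] (0 if disjoint)."""
    for o in range(min(len(left), len(right)), 0, -1):
        if left[-o:] == right[:o]:
            return o
    return 0


def link_chains(
    graph: DeBruijnGraph,
    left: GraphAlignment,
    right: GraphAlignment,
    model: ErrorModel,
) -> GraphAlignment | None:
    """Join two read-ordered alignments into one path, or defer (None).

    The spelled length between the facing anchors must fit the read-gap
    window [(1+2i)^-1 n - eps, (1-2d)^-1 n + eps]. Overlapping paths are
    joined directly; a too-short overlap joint tries the shortest cycle at
    the common point; disjoint paths try a bounded shortest path.
    """
    n = right.anchor_left[2] - left.anchor_right[2]
    if n < 0:
        return None
    eps = _gap_eps(n)
    lo = model.gap_shrink * n - eps
    hi = model.gap_stretch * n + eps

    overlap = _path_overlap(left.path, right.path)
    if overlap:
        merged = left.path + right.path[overlap:]
        shift = len(left.path) - overlap
        return _try_merge(graph, left, right, merged, shift, lo, hi, model)
    interior = _shortest_path(graph, left.path[-1], right.path[0], cap=hi + graph.k)
    if interior is None:
        return None
    merged = left.path + interior + right.path
    shift = len(left.path) + len(interior)
    return _try_merge(graph, left, right, merged, shift, lo, hi, model)


def _try_merge(
    graph: DeBruijnGraph,
    left: GraphAlignment,
    right: GraphAlignment,
    merged: list[Oriented],
    right_shift: int,
    lo: float,
    hi: float,
    model: ErrorModel,
) -> GraphAlignment | None:
    cum = _cum_offsets(graph, merged)
    p_l = cum[left.anchor_right[0]] + left.anchor_right[1]
    p_r = cum[right_shift + right.anchor_left[0]] + right.anchor_left[1]
    gap = p_r - p_l
    if gap < lo:
        # spelled path too short for the read gap: pad with the shortest cycle
        junction = merged[min(right_shift, len(merged) - 1)]
        cycle = _shortest_cycle(graph, junction, cap=hi)
        if cycle:
            cyc_len = sum(len(graph.nodes[nid]) - (graph.k - 1) for nid, _ in cycle)
            add = []
            while gap < lo and len(add) < 10 * len(cycle):
                add.extend(cycle)
                gap += cyc_len
            merged = (
                merged[: right_shift] + add + merged[right_shift:]
            )
            right_shift += len(add)
            cum = _cum_offsets(graph, merged)
            p_r = cum[right_shift + right.anchor_left[0]] + right.anchor_left[1]
            gap = p_r - cum[left.anchor_right[0]] - left.anchor_right[1]
    if not (lo <= gap <= hi):
        return None
    return GraphAlignment(
        path=merged,
        read_start=left.read_start,
        read_end=right.read_end,
        anchor_left=left.anchor_left,
        anchor_right=(
            right_shift + right.anchor_right[0],
            right.anchor_right[1],
            right.anchor_right[2],
        ),
        mappings=left.mappings + right.mappings,
    )


# ---------------------------------------------------------------------------
# multi-pass orchestration


def _unaligned_regions(
    accepted: list[GraphAlignment], read_len: int, min_size: int
) -> list[tuple[int, int]]:
    regions = []
    pos = 0
    for a in sorted(accepted, key=lambda x: x.read_start):
        if a.read_start - pos >= min_size:
            regions.append((pos, a.read_start))
        pos = max(pos, a.read_end)
    if read_len - pos >= min_size:
        regions.append((pos, read_len))
    return regions


def align_read(
    read: str,
    graph: DeBruijnGraph,
    index: SparseSuffixIndex,
    config: RunConfig,
) -> list[GraphAlignment]:
    """Align one read: up to ``max_passes`` passes of seed / chain / filter /
    extend / link over the still-unaligned regions.

    Returns read-disjoint alignments sorted by read coordinate — several for
    chimeric reads or coverage gaps, empty if the read never seeds.
    """
    model = config.error_model
    accepted: list[GraphAlignment] = []
    for pass_no in range(config.max_passes):
        final_pass = pass_no == config.max_passes - 1
        new: list[GraphAlignment] = []
        for (start, end) in _unaligned_regions(accepted, len(read), config.min_mem):
            sub = read[start:end]
            seeds, l_used = adaptive_find(
                index,
                sub,
                config.min_mem,
                lo_count=config.adaptive_lo,
                hi_count=config.adaptive_hi,
                delta=config.adaptive_delta,
            )
            if not seeds:
                continue
            if start:
                seeds = [replace(s, read_start=s.read_start + start) for s in seeds]
            groups: dict[tuple[int, str], list[MEMSeed]] = {}
            for s in seeds:
                groups.setdefault((s.node_id, s.strand), []).append(s)
            mappings: list[LocalMapping] = []
            # largest seeds first: nodes ordered by their longest seed
            # noise floor: a chain must carry at least the configured seed
            # length in matched bases, even after an adaptive-l retry
            min_weight = max(l_used, config.min_mem)
            for key in sorted(
                groups, key=lambda g: -max(s.length for s in groups[g])
            ):
                mappings.extend(
                    chain_within_node(groups[key], model, min_weight=min_weight)
                )
            mappings = filter_mappings(
                mappings, graph, model, l_used, config.cover_safety
            )
            new.extend(_select_mappings(mappings, accepted, graph, final_pass))
        if not new and accepted:
            merged_any = _link_pass(accepted, graph, model)
            if not merged_any:
                break
            continue
        if not new and not accepted:
            break
        accepted.extend(new)
        accepted.sort(key=lambda a: a.read_start)
        _link_pass(accepted, graph, model)
    accepted.sort(key=lambda a: a.read_start)
    return accepted


def _select_mappings(
    mappings: list[LocalMapping],
    accepted: list[GraphAlignment],
    graph: DeBruijnGraph,
    final_pass: bool,
) -> list[GraphAlignment]:
    """Greedy non-overlapping acceptance with ambiguity deferral.

    Competing mappings for the same read interval are resolved by weight; a
    close race (within 20%) is deferred to a later pass unless one candidate
    touches the neighbourhood of an already-accepted alignment's path, which
    wins ('global context'). On the final pass the heavier mapping wins
    outright.
    """
    chosen: list[GraphAlignment] = []
    taken: list[tuple[int, int]] = [(a.read_start, a.read_end) for a in accepted]
    order = sorted(mappings, key=lambda m: -m.weight)
    neighbour_nodes = {nid for a in accepted for nid, _ in a.path}
    for i, m in enumerate(order):
        if any(not (m.read_end <= s or m.read_start >= e) for s, e in taken):
            continue
        rivals = [
            r
            for r in order[i + 1 :]
            if not (r.read_end <= m.read_start or r.read_start >= m.read_end)
            and r.node_id != m.node_id
            and r.weight >= 0.8 * m.weight
        ]
        if rivals and not final_pass:
            connected = m.node_id in neighbour_nodes or any(
                t[0] == m.node_id
                for a in accepted
                for end in (a.path[0], a.path[-1])
                for t in graph.out_arcs(end)
            )
            if not connected:
                continue  # ambiguous; let a later pass decide with more context
        taken.append((m.read_start, m.read_end))
        chosen.append(alignment_from_mapping(m))
    return chosen


def _link_pass(
    accepted: list[GraphAlignment], graph: DeBruijnGraph, model: ErrorModel
) -> bool:
    """Try to merge read-adjacent alignments in place; True if any merged."""
    merged_any = False
    accepted.sort(key=lambda a: a.read_start)
    i = 0
    while i < len(accepted) - 1:
        left, right = accepted[i], accepted[i + 1]
        gap = right.read_start - left.read_end
        if gap < 0:
            i += 1
            continue
        lx = extend_unique(graph, left, "right", gap, model)
        rx = extend_unique(graph, right, "left", gap, model)
        joined = link_chains(graph, lx, rx, model)
        if joined is not None:
            accepted[i : i + 2] = [joined]
            merged_any = True
        else:
            i += 1
    return merged_any


# ---------------------------------------------------------------------------
# correction


def _best_alignment(alignments: list[GraphAlignment]) -> GraphAlignment:
    """Best covers the read: score, then fewer path nodes, then node-id path."""
    return min(
        alignments,
        key=lambda a: (-a.score, len(a.path), [nid for nid, _ in a.path]),
    )


def correct_read(
    read: str,
    alignments: list[GraphAlignment],
    graph: DeBruijnGraph,
    config: RunConfig,
    source_id: str = "read",
) -> list[CorrectedRead]:
    """Turn alignments into corrected output pieces (possibly none).

    The best-covering alignment is corrected; discarded read ends containing
    further alignments are corrected recursively; unalignable ends are
    dropped. Pieces are indexed in read order and never overlap on the read.
    """
    pieces = _correct_rec(read, list(alignments), graph, config, 0, len(read))
    pieces.sort(key=lambda p: p.read_start)
    return [
        CorrectedRead(source_id, idx, p.sequence, p.read_start, p.read_end, p.mode)
        for idx, p in enumerate(pieces)
    ]


def _correct_rec(
    read: str,
    alignments: list[GraphAlignment],
    graph: DeBruijnGraph,
    config: RunConfig,
    lo: int,
    hi: int,
) -> list[CorrectedRead]:
    if not alignments:
        return []
    best = _best_alignment(alignments)
    left_side = [a for a in alignments if a.read_end <= best.read_start]
    right_side = [a for a in alignments if a.read_start >= best.read_end]
    # the best piece only claims read overhang on sides without neighbours
    piece_lo = best.read_start if left_side else lo
    piece_hi = best.read_end if right_side else hi
    piece = _spell_piece(read, best, graph, config, piece_lo, piece_hi)
    out = [piece] if piece is not None else []
    out.extend(_correct_rec(read, left_side, graph, config, lo, best.read_start))
    out.extend(_correct_rec(read, right_side, graph, config, best.read_end, hi))
    return out


def _spell_piece(
    read: str,
    best: GraphAlignment,
    graph: DeBruijnGraph,
    config: RunConfig,
    lo: int,
    hi: int,
) -> CorrectedRead | None:
    model = config.error_model
    left_over = best.anchor_left[2] - lo
    right_over = hi - best.anchor_right[2]
    if config.output_mode == "short":
        # grow the path just enough to spell the estimated read extent
        aligned = extend_unique(graph, best, "left", left_over, model)
        aligned = extend_unique(graph, aligned, "right", right_over, model)
    else:
        aligned = _extend_linear(graph, best)
    spelled = path_sequence(graph, aligned.path)
    cum = _cum_offsets(graph, aligned.path)
    p_l = cum[aligned.anchor_left[0]] + aligned.anchor_left[1]
    p_r = cum[aligned.anchor_right[0]] + aligned.anchor_right[1]
    if config.output_mode == "long":
        seq = spelled
    else:
        clip_factor = (model.gap_shrink + model.gap_stretch) / 2.0
        start = max(0, p_l - int(round(clip_factor * left_over)))
        end = min(len(spelled), p_r + int(round(clip_factor * right_over)))
        seq = spelled[start:end]
    if not seq:
        return None
    return CorrectedRead("", 0, seq, lo, hi, config.output_mode)


def _extend_linear(
    graph: DeBruijnGraph, alignment: GraphAlignment, max_nodes: int = 1000
) -> GraphAlignment:
    """Long output mode: follow strictly unique arcs outward as far as the
    linear path continues (never re-entering the path)."""
    path = list(alignment.path)
    added_left = 0
    for direction in ("right", "left"):
        for _ in range(max_nodes):
            if direction == "right":
                outs = graph.out_arcs(path[-1])
            else:
                outs = [
                    (nid, _FLIP[ori])
                    for (nid, ori) in graph.out_arcs((path[0][0], _FLIP[path[0][1]]))
                ]
            if len(outs) != 1 or outs[0] in path:
                break
            if direction == "right":
                path.append(outs[0])
            else:
                path.insert(0, outs[0])
                added_left += 1
    al, ar = alignment.anchor_left, alignment.anchor_right
    return replace(
        alignment,
        path=path,
        anchor_left=(al[0] + added_left, al[1], al[2]),
        anchor_right=(ar[0] + added_left, ar[1], ar[2]),
    )
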