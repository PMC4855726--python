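"""Unitig-compacted bidirected de Bruijn graph built from accurate short reads.

Nodes are unitigs (maximal non-branching paths of k-mers) stored once, in
canonical orientation (lexicographic min of the sequence and its reverse
complement); reverse complements are represented by node orientation, never by
duplicate nodes. Arcs are oriented (node, '+'/'-') pairs with a (k-1)-base
overlap and always come in reverse-complement twin pairs.

Graph cleaning removes the two artifact classes that isolated substitution
errors in short reads produce — dead-end tips (errors near read ends) and
bubbles (internal errors) — using topology plus a coverage-ratio test. An
absolute k-mer abundance floor at build time suppresses chimeric links; beyond
that floor no chimera-specific rule is applied, so rare spurious paths can
survive cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._util import BASES, canonical, revcomp
from .seqio import SequenceRecord

Oriented = tuple[int, str]  # (node_id, '+'/'-')
_FLIP = {"+": "-", "-": "+"}


@dataclass
class GraphNode:
    node_id: int
    sequence: str
    avg_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)

    def oriented(self, orientation: str) -> str:
        return self.sequence if orientation == "+" else revcomp(self.sequence)


@dataclass
class DeBruijnGraph:
    k: int
    nodes: dict[int, GraphNode] = field(default_factory=dict)
    arcs: set[tuple[Oriented, Oriented]] = field(default_factory=set)
    # observed (k+1)-mer transitions (canonical); arcs exist only where a read
    # actually spelled the junction, not merely where two k-mers overlap
    links: set[str] = field(default_factory=set)

    def out_arcs(self, end: Oriented) -> list[Oriented]:
        return sorted(t for (f, t) in self.arcs if f == end)

    def in_arcs(self, end: Oriented) -> list[Oriented]:
        # rc twin pairing: arcs into (v,o) mirror arcs out of (v,flip(o))
        return sorted(f for (f, t) in self.arcs if t == end)

    def total_bases(self) -> int:
        return sum(len(n) for n in self.nodes.values())

    def kmer_multiset(self) -> dict[str, int]:
        """Multiset of canonical k-mers spelled by the nodes."""
        out: dict[str, int] = {}
        for node in self.nodes.values():
            seq = node.sequence
            for i in range(len(seq) - self.k + 1):
                km = canonical(seq[i : i + self.k])
                out[km] = out.get(km, 0) + 1
        return out


def _count_kmers(
    reads: Iterable[SequenceRecord], k: int
) -> tuple[dict[str, int], set[str]]:
    counts: dict[str, int] = {}
    links: set[str] = set()
    any_long_enough = False
    for rec in reads:
        # short reads containing N are split at N: an ambiguous base is not a k-mer base
        for chunk in rec.sequence.split("N"):
            if len(chunk) < k:
                continue
            any_long_enough = True
            for i in range(len(chunk) - k + 1):
                km = canonical(chunk[i : i + k])
                counts[km] = counts.get(km, 0) + 1
            for i in range(len(chunk) - k):
                links.add(canonical(chunk[i : i + k + 1]))
    if not any_long_enough:
        raise ValueError("k exceeds read length: no read contains a full k-mer")
    return counts, links


def _extensions(
    kmer: str, table: dict[str, int], links: set[str], forward: bool
) -> list[str]:
    """Oriented k-mer successors (forward) or predecessors (backward): the
    target k-mer must be present and the junction (k+1)-mer observed."""
    out = []
    for b in BASES:
        if forward:
            cand, junction = kmer[1:] + b, kmer + b
        else:
            cand, junction = b + kmer[:-1], b + kmer
        if canonical(cand) in table and canonical(junction) in links:
            out.append(cand)
    return out


def build_graph(
    reads: Iterable[SequenceRecord], k: int, min_abundance: int = 1
) -> DeBruijnGraph:
    """Build the unitig-compacted de Bruijn graph of a read set.

    Canonical k-mers are counted with multiplicity; those below
    ``min_abundance`` are dropped (the chimeric-link floor — leave at 1 to
    conserve every observed k-mer). Unitigs are maximally compacted and node
    ids are assigned by sorting canonical unitig sequences, so the result is
    deterministic for a fixed input.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts, links = _count_kmers(reads, k)
    if min_abundance > 1:
        counts = {km: c for km, c in counts.items() if c >= min_abundance}
        if not counts:
            raise ValueError("abundance floor removed every k-mer")
    return _graph_from_kmer_counts(counts, links, k)


def graph_from_sequence(genome: str, k: int) -> DeBruijnGraph:
    """A 'perfect' graph spelled directly from a reference sequence."""
    return build_graph([SequenceRecord("ref", genome)], k, min_abundance=1)


def _graph_from_kmer_counts(
    counts: dict[str, int], links: set[str], k: int
) -> DeBruijnGraph:
    visited: set[str] = set()
    unitigs: list[tuple[str, float]] = []  # (sequence as walked, avg coverage)

    for start in counts:  # insertion order; ids re-sorted below
        if start in visited:
            continue
        visited.add(start)
        chain = [start]
        oriented_seen = {start}

        def admit(cand: str) -> bool:
            # a fresh k-mer, or a hairpin fold-back onto this chain's own
            # reverse complement (each orientation is spelled at most once)
            if cand in oriented_seen:
                return False
            if canonical(cand) in visited:
                return revcomp(cand) in oriented_seen
            return True

        # forward extension
        cur = start
        while True:
            nxt = _extensions(cur, counts, links, forward=True)
            if len(nxt) != 1:
                break
            nxt = nxt[0]
            if len(_extensions(nxt, counts, links, forward=False)) != 1:
                break
            if not admit(nxt):
                break  # circular or re-entrant
            visited.add(canonical(nxt))
            oriented_seen.add(nxt)
            chain.append(nxt)
            cur = nxt
        # backward extension
        cur = start
        while True:
            prv = _extensions(cur, counts, links, forward=False)
            if len(prv) != 1:
                break
            prv = prv[0]
            if len(_extensions(prv, counts, links, forward=True)) != 1:
                break
            if not admit(prv):
                break
            visited.add(canonical(prv))
            oriented_seen.add(prv)
            chain.insert(0, prv)
            cur = prv
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        cov = sum(counts[canonical(km)] for km in chain) / len(chain)
        unitigs.append((canonical(seq), cov))

    unitigs.sort(key=lambda t: t[0])
    nodes = {
        i: GraphNode(i, seq, cov) for i, (seq, cov) in enumerate(unitigs)
    }
    graph = DeBruijnGraph(k=k, nodes=nodes, links=links)
    _rebuild_arcs(graph, counts)
    return graph


def _rebuild_arcs(graph: DeBruijnGraph, table: Optional[dict[str, int]] = None) -> None:
    """Recompute arcs: node ends overlapping by k-1 whose junction (k+1)-mer
    was observed in the input reads."""
    k = graph.k
    if table is None:
        table = graph.kmer_multiset()
    starts: dict[str, list[Oriented]] = {}
    for nid, node in graph.nodes.items():
        starts.setdefault(node.sequence[:k], []).append((nid, "+"))
        starts.setdefault(revcomp(node.sequence)[:k], []).append((nid, "-"))
    def norm(end: Oriented) -> Oriented:
        # a palindromic node's two orientations are indistinguishable
        n = graph.nodes[end[0]]
        return (end[0], "+") if n.sequence == revcomp(n.sequence) else end

    arcs: set[tuple[Oriented, Oriented]] = set()
    for nid, node in graph.nodes.items():
        for ori in "+-":
            seq = node.oriented(ori)
            last = seq[-k:]
            for b in BASES:
                nxt = last[1:] + b
                if canonical(nxt) not in table:
                    continue
                if canonical(last + b) not in graph.links:
                    continue
                for tgt in starts.get(nxt, []):
                    arcs.add((norm((nid, ori)), norm(tgt)))
                    arcs.add(
                        (norm((tgt[0], _FLIP[tgt[1]])), norm((nid, _FLIP[ori])))
                    )
    graph.arcs = arcs


def compact(graph: DeBruijnGraph) -> DeBruijnGraph:
    """Restore unitig-maximality by merging forced node chains in place."""
    k = graph.k
    changed = True
    while changed:
        changed = False
        outdeg: dict[Oriented, list[Oriented]] = {}
        for f, t in graph.arcs:
            outdeg.setdefault(f, []).append(t)
        for (u, ou), targets in list(outdeg.items()):
            if len(targets) != 1:
                continue
            (v, ov) = targets[0]
            if v == u:
                continue  # self-loop: never merged
            # indeg of (v,ov) == outdeg of (v, flipped)
            if len(outdeg.get((v, _FLIP[ov]), [])) != 1:
                continue
            nu, nv = graph.nodes[u], graph.nodes[v]
            merged = nu.oriented(ou) + nv.oriented(ov)[k - 1 :]
            wu, wv = len(nu) - k + 1, len(nv) - k + 1
            cov = (nu.avg_coverage * wu + nv.avg_coverage * wv) / (wu + wv)
            del graph.nodes[u]
            del graph.nodes[v]
            nid = max(graph.nodes, default=-1) + 1
            cmerged = canonical(merged)
            graph.nodes[nid] = GraphNode(nid, cmerged, cov)
            new_ori = "+" if cmerged == merged else "-"
            # endpoint remapping is role-dependent: the merged arc's two ends
            # become interior; the outer ends survive on the new node
            remap_src = {
                (v, ov): (nid, new_ori),
                (u, _FLIP[ou]): (nid, _FLIP[new_ori]),
                (u, ou): None,
                (v, _FLIP[ov]): None,
            }
            remap_tgt = {
                (u, ou): (nid, new_ori),
                (v, _FLIP[ov]): (nid, _FLIP[new_ori]),
                (v, ov): None,
                (u, _FLIP[ou]): None,
            }
            new_arcs = set()
            for f, t in graph.arcs:
                if (f == (u, ou) and t == (v, ov)) or (
                    f == (v, _FLIP[ov]) and t == (u, _FLIP[ou])
                ):
                    continue  # the merged arc and its twin
                f2 = remap_src.get(f, f)
                t2 = remap_tgt.get(t, t)
                if f2 is None or t2 is None:
                    continue
                new_arcs.add((f2, t2))
            graph.arcs = new_arcs
            changed = True
            break
    _renumber(graph)
    return graph


def _renumber(graph: DeBruijnGraph) -> None:
    order = sorted(graph.nodes, key=lambda nid: graph.nodes[nid].sequence)
    mapping = {old: new for new, old in enumerate(order)}
    graph.nodes = {
        mapping[old]: GraphNode(mapping[old], n.sequence, n.avg_coverage)
        for old, n in graph.nodes.items()
    }
    graph.arcs = {
        ((mapping[f], fo), (mapping[t], to)) for (f, fo), (t, to) in graph.arcs
    }
    graph._locator_cache = None  # type: ignore[attr-defined]


def remove_tips(
    graph: DeBruijnGraph, max_tip_length: Optional[int] = None, coverage_ratio: float = 0.5
) -> tuple[DeBruijnGraph, int]:
    """Delete short, low-coverage dead-end nodes and recompact.

    A tip is a node with arcs on exactly one side, sequence length at most
    ``max_tip_length`` (default 2k) and coverage at most ``coverage_ratio``
    times the best coverage among the nodes it attaches to.
    """
    if max_tip_length is None:
        max_tip_length = 2 * graph.k
    doomed = []
    for nid, node in graph.nodes.items():
        fwd = graph.out_arcs((nid, "+"))
        bwd = graph.out_arcs((nid, "-"))
        if bool(fwd) == bool(bwd):
            continue  # isolated or through-node, not a dead end
        if len(node) > max_tip_length:
            continue
        neighbors = fwd or bwd
        through_cov = max(graph.nodes[t[0]].avg_coverage for t in neighbors)
        if node.avg_coverage <= coverage_ratio * through_cov:
            doomed.append(nid)
    for nid in doomed:
        del graph.nodes[nid]
    graph.arcs = {
        (f, t) for f, t in graph.arcs if f[0] in graph.nodes and t[0] in graph.nodes
    }
    compact(graph)
    return graph, len(doomed)


def pop_bubbles(
    graph: DeBruijnGraph, max_bubble_length: Optional[int] = None, coverage_ratio: float = 0.5
) -> tuple[DeBruijnGraph, int]:
    """Remove the low-coverage branch of simple bubbles and recompact.

    Handles the compacted form of an isolated internal error: two parallel
    single-node branches sharing both endpoints. The weaker branch is deleted
    when its coverage is at most ``coverage_ratio`` times the stronger one;
    equal coverages (for ratio < 1) are left alone. Nested bubbles resolve over
    repeated cleaning rounds.
    """
    if max_bubble_length is None:
        max_bubble_length = 2 * graph.k
    doomed: set[int] = set()
    ends: dict[Oriented, list[Oriented]] = {}
    for f, t in graph.arcs:
        ends.setdefault(f, []).append(t)
    for (u, ou), targets in ends.items():
        if len(targets) < 2:
            continue
        # group single-node branches by the endpoint they reconverge to
        by_exit: dict[Oriented, list[Oriented]] = {}
        for (x, ox) in targets:
            if x in doomed or x == u:
                continue
            outs = [t for t in ends.get((x, ox), []) if t[0] != x]
            ins = ends.get((x, _FLIP[ox]), [])
            if len(outs) == 1 and len(ins) == 1 and len(graph.nodes[x]) <= max_bubble_length:
                by_exit.setdefault(outs[0], []).append((x, ox))
        for _exit, branches in by_exit.items():
            if len(branches) < 2:
                continue
            branches.sort(key=lambda b: (graph.nodes[b[0]].avg_coverage, b[0]))
            strongest = graph.nodes[branches[-1][0]].avg_coverage
            for (x, _ox) in branches[:-1]:
                if graph.nodes[x].avg_coverage <= coverage_ratio * strongest:
                    doomed.add(x)
    for nid in doomed:
        del graph.nodes[nid]
    graph.arcs = {
        (f, t) for f, t in graph.arcs if f[0] in graph.nodes and t[0] in graph.nodes
    }
    compact(graph)
    return graph, len(doomed)


def clean_graph(
    graph: DeBruijnGraph,
    max_tip_length: Optional[int] = None,
    max_bubble_length: Optional[int] = None,
    coverage_ratio: float = 0.5,
    max_rounds: int = 10,
) -> DeBruijnGraph:
    """Alternate tip clipping and bubble popping until a fixpoint (<= max_rounds)."""
    for _ in range(max_rounds):
        _, n_tips = remove_tips(graph, max_tip_length, coverage_ratio)
        _, n_bub = pop_bubbles(graph, max_bubble_length, coverage_ratio)
        if n_tips == 0 and n_bub == 0:
            break
    return graph


def path_sequence(graph: DeBruijnGraph, path: list[Oriented]) -> str:
    """Spell the sequence of a graph path, collapsing (k-1)-base overlaps."""
    if not path:
        return ""
    for a, b in zip(path, path[1:]):
        if (a, b) not in graph.arcs:
            raise ValueError(f"path step {a} -> {b} is not an arc")
    out = [graph.nodes[path[0][0]].oriented(path[0][1])]
    for nid, ori in path[1:]:
        out.append(graph.nodes[nid].oriented(ori)[graph.k - 1 :])
    return "".join(out)


def connectedness_report(graph: DeBruijnGraph) -> dict:
    """Component statistics used to choose k: of two similarly connected
    graphs, prefer the larger k."""
    parent = {nid: nid for nid in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (f, _), (t, _) in graph.arcs:
        rf, rt = find(f), find(t)
        if rf != rt:
            parent[rf] = rt
    comp_bases: dict[int, int] = {}
    for nid, node in graph.nodes.items():
        comp_bases[find(nid)] = comp_bases.get(find(nid), 0) + len(node)
    total = sum(comp_bases.values())
    largest = max(comp_bases.values(), default=0)
    return {
        "n_nodes": len(graph.nodes),
        "n_arcs": len(graph.arcs),
        "n_components": len(comp_bases),
        "bases_in_largest_component": largest,
        "fraction_of_total_bases": (largest / total) if total else 0.0,
    }


def recommend_k(reports: dict[int, dict], tolerance: float = 0.05) -> int:
    """Choose a graph k from per-k connectedness reports.

    Among graphs whose largest-component base fraction is within
    ``tolerance`` of the best, the largest k wins (fewer unresolved repeats
    at similar connectedness).
    """
    if not reports:
        raise ValueError("no reports given")
    best = max(r["fraction_of_total_bases"] for r in reports.values())
    return max(
        k
        for k, r in reports.items()
        if r["fraction_of_total_bases"] >= best - tolerance
    )


def thread_sequence(graph: DeBruijnGraph, seq: str) -> Optional[list[Oriented]]:
    """Walk ``seq`` exactly through the graph; the path if one exists, else None.

    Used to verify the spelling property (error-free reads re-thread) and that
    corrected reads are genuine path spellings.
    """
    k = graph.k
    if len(seq) < k:
        return None
    first = seq[:k]
    cfirst = canonical(first)
    hit = _kmer_locator(graph).get(cfirst)
    if hit is None:
        return None
    nid, off, ori = hit
    if first != cfirst:  # occurrence recorded for the canonical form; mirror it
        ori = _FLIP[ori]
        off = len(graph.nodes[nid]) - k - off
    path = [(nid, ori)]
    node_seq = graph.nodes[nid].oriented(ori)
    pos, i = off, 0  # node_seq[pos] aligns with seq[i]
    while True:
        take = min(len(node_seq) - pos, len(seq) - i)
        if node_seq[pos : pos + take] != seq[i : i + take]:
            return None
        i += take
        if i >= len(seq):
            return path
        # node exhausted: follow the arc whose target starts with the last
        # (k-1) matched bases plus seq[i]
        want = seq[i - k + 1 : i + 1]
        nxt = None
        for (tnid, tori) in graph.out_arcs(path[-1]):
            if graph.nodes[tnid].oriented(tori)[:k] == want:
                nxt = (tnid, tori)
                break
        if nxt is None:
            return None
        path.append(nxt)
        node_seq = graph.nodes[nxt[0]].oriented(nxt[1])
        pos = k  # positions [0,k) of the new node are already matched/verified
        i += 1


def _kmer_locator(graph: DeBruijnGraph) -> dict[str, tuple[int, int, str]]:
    cache = getattr(graph, "_locator_cache", None)
    if cache is not None:
        return cache
    loc: dict[str, tuple[int, int, str]] = {}
    k = graph.k
    for nid, node in graph.nodes.items():
        for ori in "+-":
            s = node.oriented(ori)
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if canonical(km) == km:
                    loc.setdefault(km, (nid, i, ori))
    graph._locator_cache = loc  # type: ignore[attr-defined]
    return loc
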