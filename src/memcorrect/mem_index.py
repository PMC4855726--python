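"""Sparse suffix-array index over graph nodes for maximal-exact-match seeds.

The sequences of every node and their reverse complements are concatenated
(with non-matching sentinel separators) into one text. A suffix array over
the suffixes sampled every ``s`` positions supports reporting all MEMs of
length >= l between a query read and any oriented node: every such MEM
contains a sampled text position at offset < s from its start, so matching
the query against sampled suffixes with threshold l-s+1 and then extending
maximally recovers each MEM exactly once. With s=1 this degenerates to the
classic full-suffix-array algorithm; raising s shrinks the index roughly by
a factor s at the cost of query time.

Query inner loops are JIT-compiled (numba) over uint8-encoded text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dbg import DeBruijnGraph
from ._util import revcomp

# encoding: sentinel 0; A,C,G,T -> 1..4; node-side N -> 5; read-side N -> 6
# (5 != 6, so an ambiguous base never participates in a match)
_NODE_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NODE_ENC[ord(_b)] = _i + 1
_NODE_ENC[ord("N")] = 5
_READ_ENC = _NODE_ENC.copy()
_READ_ENC[ord("N")] = 6


@dataclass(frozen=True)
class MEMSeed:
    """A maximal exact match between a read interval and a node interval.

    ``node_start`` is 0-based on the oriented node sequence: for '-' seeds it
    indexes into the reverse-complemented node. ``read_start`` is always on
    the forward read.
    """

    node_id: int
    strand: str
    node_start: int
    read_start: int
    length: int

    @property
    def read_end(self) -> int:
        return self.read_start + self.length

    @property
    def node_end(self) -> int:
        return self.node_start + self.length


class NodeCatalog:
    """Concatenation of all oriented node sequences with an offset table."""

    def __init__(self, graph: DeBruijnGraph):
        parts: list[np.ndarray] = []
        seg_starts: list[int] = []
        seg_nodes: list[int] = []
        seg_strands: list[int] = []
        pos = 0
        for nid in sorted(graph.nodes):
            seq = graph.nodes[nid].sequence
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                seg_starts.append(pos)
                seg_nodes.append(nid)
                seg_strands.append(0 if strand == "+" else 1)
                enc = _NODE_ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
                parts.append(enc)
                parts.append(np.zeros(1, dtype=np.uint8))  # sentinel
                pos += len(s) + 1
        self.text = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self.seg_starts = np.asarray(seg_starts, dtype=np.int64)
        self.seg_nodes = np.asarray(seg_nodes, dtype=np.int64)
        self.seg_strands = np.asarray(seg_strands, dtype=np.int8)

    def locate(self, text_pos: int) -> tuple[int, str, int]:
        """(node_id, strand, offset on the oriented node) of a text position."""
        i = int(np.searchsorted(self.seg_starts, text_pos, side="right")) - 1
        return (
            int(self.seg_nodes[i]),
            "+" if self.seg_strands[i] == 0 else "-",
            text_pos - int(self.seg_starts[i]),
        )


def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    n = t.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    rank = t.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        r2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            r2[:-k] = rank[k:]
        order = np.lexsort((r2, rank))
        rr, rr2 = rank[order], r2[order]
        diff = np.ones(n, dtype=bool)
        diff[1:] = (rr[1:] != rr[:-1]) | (rr2[1:] != rr2[:-1])
        new = np.empty(n, dtype=np.int64)
        new[order] = np.cumsum(diff) - 1
        rank = new
        if int(rank[order[-1]]) == n - 1:
            return order.astype(np.int64)
        k *= 2


@njit(cache=False)
def _cmp_suffix(text, start, query, qs, qe):  # pragma: no cover - jitted
    """Compare text suffix at `start` with query[qs:qe] as a prefix pattern.

    Returns -1 if suffix < pattern, 0 if pattern is a prefix of the suffix,
    +1 if suffix > pattern. Sentinels (0) compare as smallest and never equal.
    """
    n = text.shape[0]
    j = 0
    while qs + j < qe:
        if start + j >= n:
            return -1
        tc = text[start + j]
        qc = query[qs + j]
        if tc < qc:
            return -1
        if tc > qc:
            return 1
        if tc == 0 or tc >= 5:  # equal sentinel/N codes still never match
            return -1
        j += 1
    return 0


@njit(cache=False)
def _find_mems_nb(text, sa, s, query, l):  # pragma: no cover - jitted
    nq = query.shape[0]
    nsa = sa.shape[0]
    q_thresh = l - (s - 1)
    if q_thresh < 1:
        q_thresh = 1
    cap = 64
    out_ts = np.empty(cap, dtype=np.int64)
    out_rs = np.empty(cap, dtype=np.int64)
    out_ln = np.empty(cap, dtype=np.int64)
    m = 0
    for r in range(0, nq - q_thresh + 1):
        # binary search the SA interval whose suffixes start with query[r:r+q_thresh]
        lo, hi = 0, nsa
        while lo < hi:
            mid = (lo + hi) // 2
            if _cmp_suffix(text, sa[mid], query, r, r + q_thresh) < 0:
                lo = mid + 1
            else:
                hi = mid
        first = lo
        lo, hi = first, nsa
        while lo < hi:
            mid = (lo + hi) // 2
            if _cmp_suffix(text, sa[mid], query, r, r + q_thresh) <= 0:
                lo = mid + 1
            else:
                hi = mid
        last = lo
        for idx in range(first, last):
            t = sa[idx]
            # forward maximal extension
            j = q_thresh
            n = text.shape[0]
            while r + j < nq and t + j < n:
                tc = text[t + j]
                if tc == 0 or tc >= 5 or tc != query[r + j]:
                    break
                j += 1
            fwd = j
            # left maximal extension
            left = 0
            while r - left - 1 >= 0 and t - left - 1 >= 0:
                tc = text[t - left - 1]
                if tc == 0 or tc >= 5 or tc != query[r - left - 1]:
                    break
                left += 1
            ln = left + fwd
            if ln < l:
                continue
            if t - (t - left) >= s:
                continue  # t is not the first sampled position in this MEM
            if m == cap:
                cap *= 2
                nts = np.empty(cap, dtype=np.int64)
                nrs = np.empty(cap, dtype=np.int64)
                nln = np.empty(cap, dtype=np.int64)
                nts[:m] = out_ts[:m]
                nrs[:m] = out_rs[:m]
                nln[:m] = out_ln[:m]
                out_ts, out_rs, out_ln = nts, nrs, nln
            out_ts[m] = t - left
            out_rs[m] = r - left
            out_ln[m] = ln
            m += 1
    return out_ts[:m], out_rs[:m], out_ln[:m]


@njit(cache=False)
def _find_mems_short_nb(text, query, l):  # pragma: no cover - jitted
    """Exact MEM scan for the short-seed regime (l < sparseness).

    A MEM shorter than the sampling interval may contain no sampled suffix at
    all, so the sparse array cannot see it; instead the text is streamed
    against a sorted table of the read's packed l-mers. Left-maximality makes
    each MEM fire exactly once, at its own start.
    """
    nq = query.shape[0]
    nt = text.shape[0]
    # pack read l-mers (3 bits/base); -1 marks windows with non-ACGT codes
    nkeys = nq - l + 1
    keys = np.full(max(nkeys, 1), -1, dtype=np.int64)
    for r in range(nkeys):
        key = np.int64(0)
        ok = True
        for j in range(l):
            c = query[r + j]
            if c < 1 or c > 4:
                ok = False
                break
            key = (key << 3) | c
        if ok:
            keys[r] = key
    order = np.argsort(keys)
    skeys = keys[order]
    cap = 64
    out_ts = np.empty(cap, dtype=np.int64)
    out_rs = np.empty(cap, dtype=np.int64)
    out_ln = np.empty(cap, dtype=np.int64)
    m = 0
    for t in range(nt - l + 1):
        key = np.int64(0)
        ok = True
        for j in range(l):
            c = text[t + j]
            if c < 1 or c > 4:
                ok = False
                break
            key = (key << 3) | c
        if not ok:
            continue
        lo, hi = 0, skeys.shape[0]
        while lo < hi:
            mid = (lo + hi) // 2
            if skeys[mid] < key:
                lo = mid + 1
            else:
                hi = mid
        idx = lo
        while idx < skeys.shape[0] and skeys[idx] == key:
            r = order[idx]
            idx += 1
            if t > 0 and r > 0:
                tc = text[t - 1]
                if 1 <= tc <= 4 and tc == query[r - 1]:
                    continue  # not left-maximal: counted at the true start
            j = l
            while r + j < nq and t + j < nt:
                tc = text[t + j]
                if tc < 1 or tc > 4 or tc != query[r + j]:
                    break
                j += 1
            if m == cap:
                cap *= 2
                nts = np.empty(cap, dtype=np.int64)
                nrs = np.empty(cap, dtype=np.int64)
                nln = np.empty(cap, dtype=np.int64)
                nts[:m] = out_ts[:m]
                nrs[:m] = out_rs[:m]
                nln[:m] = out_ln[:m]
                out_ts, out_rs, out_ln = nts, nrs, nln
            out_ts[m] = t
            out_rs[m] = r
            out_ln[m] = j
            m += 1
    return out_ts[:m], out_rs[:m], out_ln[:m]


class SparseSuffixIndex:
    """MEM index over a graph's node catalog; see module docstring."""

    def __init__(self, catalog: NodeCatalog, sparseness: int = 1):
        if sparseness < 1:
            raise ValueError("sparseness must be >= 1")
        self.catalog = catalog
        self.sparseness = sparseness
        full = _suffix_array(catalog.text)
        self.sa = full[full % sparseness == 0] if sparseness > 1 else full

    @property
    def element_count(self) -> int:
        """Index size proxy: number of stored suffix-array elements."""
        return int(self.sa.size)


def build_index(graph: DeBruijnGraph, sparseness: int = 1) -> SparseSuffixIndex:
    """Index all oriented node sequences of a graph for MEM queries."""
    if not graph.nodes:
        raise ValueError("cannot index an empty graph")
    return SparseSuffixIndex(NodeCatalog(graph), sparseness)


def find_mems(index: SparseSuffixIndex, read: str, min_length: int) -> list[MEMSeed]:
    """All maximal exact matches of length >= min_length between the read and
    any oriented node, sorted by (read_start, node_id)."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    if not read:
        return []
    q = _READ_ENC[np.frombuffer(read.upper().encode(), dtype=np.uint8)]
    if min_length >= index.sparseness:
        ts, rs, ln = _find_mems_nb(
            index.catalog.text, index.sa, index.sparseness, q, min_length
        )
    else:
        # below the sampling interval the sparse array is blind; exact scan
        if min_length > 21:
            raise ValueError("sparseness too large for this seed length")
        ts, rs, ln = _find_mems_short_nb(index.catalog.text, q, min_length)
    seeds = []
    for i in range(ts.size):
        nid, strand, off = index.catalog.locate(int(ts[i]))
        seeds.append(
            MEMSeed(
                node_id=nid,
                strand=strand,
                node_start=off,
                read_start=int(rs[i]),
                length=int(ln[i]),
            )
        )
    seeds.sort(key=lambda m: (m.read_start, m.node_id, m.strand, m.node_start))
    return seeds


def adaptive_find(
    index: SparseSuffixIndex,
    read: str,
    l0: int,
    lo_count: int = 2,
    hi_count: float = 20.0,
    delta: int = 3,
    max_retries: int = 3,
) -> tuple[list[MEMSeed], int]:
    """Seed search with retry on an extreme seed yield.

    Too few seeds (< lo_count) lowers l by ``delta`` (floor 2); too many
    (> hi_count per 100 read bases) raises it. At most ``max_retries``
    retries; returns the final seed list and the l actually used.
    """
    l = max(2, l0)
    hi_abs = hi_count * len(read) / 100.0
    seeds = find_mems(index, read, l)
    for _ in range(max_retries):
        if len(seeds) < lo_count and l > 2:
            l = max(2, l - delta)
        elif len(seeds) > hi_abs:
            l = l + delta
        else:
            break
        seeds = find_mems(index, read, l)
    return seeds, l
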