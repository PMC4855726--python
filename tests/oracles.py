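"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: MEM enumeration is a
dense run-length DP over the full match matrix; run statistics come from
direct Bernoulli simulation; chain optimality from exhaustive subset search.
"""

from __future__ import annotations

import numpy as np

from memcorrect._util import revcomp
from memcorrect.aligner import seed_distance_compatible


def naive_mems(node_seqs, read: str, l: int) -> set[tuple]:
    """All maximal exact matches of length >= l between the read and every
    oriented node, as (node_id, strand, node_start, read_start, length)."""
    out: set[tuple] = set()
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    for nid, seq in node_seqs:
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            t = np.frombuffer(s.encode(), dtype=np.uint8)
            if not len(t) or not len(r):
                continue
            eq = t[:, None] == r[None, :]
            M = np.zeros((len(t), len(r)), dtype=np.int32)
            M[0, :] = eq[0, :]
            for i in range(1, len(t)):
                M[i, 1:] = np.where(eq[i, 1:], M[i - 1, :-1] + 1, 0)
                M[i, 0] = eq[i, 0]
            ends = np.zeros_like(eq)
            ends[:-1, :-1] = eq[:-1, :-1] & ~eq[1:, 1:]
            ends[-1, :] = eq[-1, :]
            ends[:, -1] |= eq[:, -1]
            for i, j in zip(*np.nonzero(ends)):
                ln = int(M[i, j])
                if ln >= l:
                    out.add((nid, strand, int(i - ln + 1), int(j - ln + 1), ln))
    return out


def run_statistics(n: int, p: float, n_reads: int, seed: int, m_list, chunk: int = 2000):
    """Monte-Carlo statistics of error-free runs in Bernoulli(p) reads.

    Returns per-m coverage fractions (with batch-based standard errors),
    frequencies of >=1 and >=2 runs of size >= m, and the mean longest run.
    """
    rng = np.random.default_rng(seed)
    m_list = list(m_list)
    cov_sums = np.zeros(len(m_list))
    ge1 = np.zeros(len(m_list))
    ge2 = np.zeros(len(m_list))
    longest_sum = 0.0
    batch_cov = [[] for _ in m_list]
    done = 0
    while done < n_reads:
        b = min(chunk, n_reads - done)
        errs = rng.random((b, n)) < p
        padded = np.ones((b, n + 2), dtype=bool)
        padded[:, 1:-1] = errs
        idx = np.flatnonzero(padded.ravel())
        gaps = np.diff(idx) - 1
        rows = idx[:-1] // (n + 2)
        keep = gaps > 0
        gaps_k, rows_k = gaps[keep], rows[keep]
        longest = np.zeros(b, dtype=int)
        np.maximum.at(longest, rows_k, gaps_k)
        longest_sum += longest.sum()
        for j, m in enumerate(m_list):
            sel = gaps_k >= m
            cov = np.bincount(rows_k[sel], weights=gaps_k[sel], minlength=b)
            cnt = np.bincount(rows_k[sel], minlength=b)
            cov_sums[j] += cov.sum()
            ge1[j] += (cnt >= 1).sum()
            ge2[j] += (cnt >= 2).sum()
            batch_cov[j].append(cov.mean() / n)
        done += b
    return {
        "coverage": cov_sums / (n_reads * n),
        "coverage_se": np.array(
            [np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0 for v in batch_cov]
        ),
        "p_ge1": ge1 / n_reads,
        "p_ge2": ge2 / n_reads,
        "mean_longest": longest_sum / n_reads,
    }


def best_chain_by_enumeration(seeds, model) -> int:
    """Max total seed length over all subsets forming a pairwise-compatible,
    ordered chain (exhaustive; use only for <= ~12 seeds)."""
    seeds = sorted(seeds, key=lambda s: (s.read_start, s.node_start))
    n = len(seeds)
    best = 0
    for mask in range(1, 1 << n):
        subset = [seeds[i] for i in range(n) if mask >> i & 1]
        ok = all(
            seed_distance_compatible(a, b, model)
            for a, b in zip(subset, subset[1:])
        )
        if ok:
            best = max(best, sum(s.length for s in subset))
    return best
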