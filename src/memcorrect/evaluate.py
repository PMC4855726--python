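"""Correction quality metrics: gain, accuracy, error-free, aligned, throughput, Nx.

Reads are placed on the reference with a unit-cost edit-distance aligner
(read-global, reference-local, both strands; edlib under the hood) and kept
when the alignment identity reaches ``min_identity`` (default 70%).
Accuracy and gain are aggregated base-weighted: totals of matched and
erroneous alignment columns, not unweighted per-read means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import edlib

from ._util import revcomp
from .seqio import SequenceRecord


@dataclass
class ReadAlignment:
    identity: float  # percent
    matches: int
    errors: int
    aligned_bases: int  # read bases placed on the reference


@dataclass
class MetricsReport:
    gain: Optional[float]
    accuracy: float
    error_free: float
    aligned: float
    throughput: float
    nx: dict[int, int]
    n_reads_in: int
    n_reads_out: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["nx"] = {str(k): v for k, v in self.nx.items()}
        return d


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment_columns) from an edlib extended cigar."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def align_to_reference(
    read: str, reference: str, min_identity: float = 0.70
) -> Optional[ReadAlignment]:
    """Best local placement of the read on either reference strand.

    identity = matches / alignment columns (as a percent); placements below
    ``min_identity`` are discarded (returns None, 'unaligned').
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if not read:
        return None
    # pick the strand by edit distance first (cheap), then trace one path
    fwd = edlib.align(read, reference, mode="HW", task="distance")
    rev = edlib.align(read, revcomp(reference), mode="HW", task="distance")
    target = reference if fwd["editDistance"] <= rev["editDistance"] else revcomp(reference)
    res = edlib.align(read, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    matches, cols = _cigar_stats(res["cigar"])
    identity = matches / cols
    if identity < min_identity:
        return None
    return ReadAlignment(
        identity=100.0 * identity,
        matches=matches,
        errors=cols - matches,
        aligned_bases=len(read),
    )


def nx(lengths: list[int], x: float) -> int:
    """Minimum read size such that all reads at least that long hold x% of
    the bases (N50 for x=50)."""
    if not lengths:
        raise ValueError("nx of an empty length list")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    target = sum(lengths) * x / 100.0
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= target:
            return ln
    return min(lengths)


def compute_metrics(
    original_reads: Iterable[SequenceRecord],
    corrected_reads: Iterable[SequenceRecord],
    reference: str,
    min_identity: float = 0.70,
    nx_points: tuple[int, ...] = (50,),
) -> MetricsReport:
    """Score a correction run against the reference.

    gain compares total alignment errors of the aligned corrected reads with
    those of the aligned originals (null when the originals align without
    any error); accuracy/error-free cover aligned corrected reads; aligned
    is the fraction of corrected bases that placed on the reference;
    throughput is corrected bases over input bases.
    """
    originals = list(original_reads)
    corrected = list(corrected_reads)

    errors_before = 0
    for rec in originals:
        aln = align_to_reference(rec.sequence, reference, min_identity)
        if aln is not None:
            errors_before += aln.errors

    errors_after = 0
    matches_after = 0
    cols_after = 0
    n_aligned = 0
    n_error_free = 0
    aligned_bases = 0
    for rec in corrected:
        aln = align_to_reference(rec.sequence, reference, min_identity)
        if aln is None:
            continue
        n_aligned += 1
        errors_after += aln.errors
        matches_after += aln.matches
        cols_after += aln.errors + aln.matches
        aligned_bases += aln.aligned_bases
        if aln.errors == 0:
            n_error_free += 1

    in_bases = sum(len(r) for r in originals)
    out_bases = sum(len(r) for r in corrected)
    gain = (
        100.0 * (errors_before - errors_after) / errors_before
        if errors_before
        else None
    )
    return MetricsReport(
        gain=gain,
        accuracy=100.0 * matches_after / cols_after if cols_after else 0.0,
        error_free=100.0 * n_error_free / n_aligned if n_aligned else 0.0,
        aligned=100.0 * aligned_bases / out_bases if out_bases else 0.0,
        throughput=100.0 * out_bases / in_bases if in_bases else 0.0,
        nx={x: nx([len(r) for r in corrected], x) for x in nx_points}
        if corrected
        else {},
        n_reads_in=len(originals),
        n_reads_out=len(corrected),
    )
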