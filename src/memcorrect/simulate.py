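"""Synthetic data: random genomes, accurate short reads, noisy long reads.

The long-read generator emulates SMRT-like data: errors are placed i.i.d.
per emitted base at a total rate of 15% by default, split 60% insertions /
30% deletions / 10% substitutions, with lognormal read lengths (mean 10 kb).
Short reads model post-correction Illumina data: uniformly placed on both
strands, substitution errors only, error-free by default.

Everything is deterministic for a fixed seed. Genomes are linear; reads are
clipped at genome ends rather than wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import BASES, revcomp
from .seqio import SequenceRecord


@dataclass
class TruthInterval:
    """Where a simulated long read came from, plus its true error counts."""

    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    n_ins: int = 0
    n_del: int = 0
    n_sub: int = 0
    n_events: int = 0  # emitted bases + deletions


@dataclass
class LongReadProfile:
    mean_length: int = 10_000
    length_sd: int = 2_000
    total_error: float = 0.15
    fraction_ins: float = 0.60
    fraction_del: float = 0.30
    fraction_sub: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        s = self.fraction_ins + self.fraction_del + self.fraction_sub
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"error fractions must sum to 1, got {s}")
        if not 0.0 <= self.total_error < 1.0:
            raise ValueError("total_error must be in [0,1)")

    @property
    def rates(self) -> tuple[float, float, float]:
        """(insertion, deletion, substitution) per-base rates."""
        return (
            self.total_error * self.fraction_ins,
            self.total_error * self.fraction_del,
            self.total_error * self.fraction_sub,
        )


def random_genome(length: int, seed: int, gc: float = 0.5) -> SequenceRecord:
    """An i.i.d. random genome with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    seq = "".join(np.array(list(BASES))[idx])
    return SequenceRecord(f"genome_len{length}_seed{seed}", seq)


def simulate_short_reads(
    genome: SequenceRecord,
    read_length: int = 100,
    coverage: float = 100.0,
    sub_rate: float = 0.0,
    seed: int = 0,
):
    """Uniformly placed single-end short reads on both strands.

    ``sub_rate`` adds i.i.d. substitutions; 0 models reads that were already
    corrected by a dedicated short-read corrector.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    seq = genome.sequence
    G = len(seq)
    if read_length > G:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * G / read_length))
    starts = rng.integers(0, G - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    for i in range(n_reads):
        s = int(starts[i])
        frag = seq[s : s + read_length]
        if strands[i]:
            frag = revcomp(frag)
        if sub_rate > 0:
            frag = _substitute(frag, sub_rate, rng)
        yield SequenceRecord(f"sr{i}", frag)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for j in hits:
        old = chars[j]
        choices = [b for b in BASES if b != old]
        chars[j] = choices[rng.integers(3)]
    return "".join(chars)


def simulate_long_reads(
    genome: SequenceRecord,
    profile: LongReadProfile | None = None,
    n_reads: int = 100,
) -> tuple[list[SequenceRecord], list[TruthInterval]]:
    """Noisy long reads plus the truth intervals they were drawn from.

    Per emitted base an error occurs with probability ``total_error`` and is
    an insertion, deletion or substitution per the profile fractions:
    insertions emit a uniform random base without consuming reference,
    deletions consume reference without emitting, substitutions emit one of
    the three other bases. Read lengths are lognormal (truncated to
    [100, genome length]); reads are clipped at the genome end.
    """
    if profile is None:
        profile = LongReadProfile()
    seq = genome.sequence
    G = len(seq)
    if profile.mean_length > G:
        raise ValueError("mean read length exceeds genome length")
    rng = np.random.default_rng(profile.rng_seed)
    i_rate, d_rate, s_rate = profile.rates

    mean, sd = float(profile.mean_length), float(max(profile.length_sd, 1))
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    lengths = np.clip(
        rng.lognormal(mu, math.sqrt(sigma2), size=n_reads), 100, G
    ).astype(int)

    reads: list[SequenceRecord] = []
    truths: list[TruthInterval] = []
    base_idx = {b: i for i, b in enumerate(BASES)}
    for r in range(n_reads):
        target = int(lengths[r])
        start = int(rng.integers(0, max(G - target, 0) + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        template = seq if strand == "+" else revcomp(seq)
        pos = start  # position on the oriented template
        out: list[str] = []
        n_ins = n_del = n_sub = n_events = 0
        # draw event randomness in bulk; worst case every event is a deletion
        us = rng.random(int(target * 2.5) + 64)
        picks = rng.integers(0, 4, size=us.shape[0])
        ei = 0
        while len(out) < target and pos < G and ei < len(us):
            u = us[ei]
            pick = int(picks[ei])
            ei += 1
            n_events += 1
            if u < i_rate:
                out.append(BASES[pick])
                n_ins += 1
            elif u < i_rate + d_rate:
                pos += 1
                n_del += 1
            elif u < i_rate + d_rate + s_rate:
                old = template[pos]
                out.append(BASES[(base_idx[old] + 1 + pick % 3) % 4])
                pos += 1
                n_sub += 1
            else:
                out.append(template[pos])
                pos += 1
        rid = f"lr{r}"
        reads.append(SequenceRecord(rid, "".join(out)))
        if strand == "+":
            ival = (start, pos)
        else:
            ival = (G - pos, G - start)
        truths.append(
            TruthInterval(rid, ival[0], ival[1], strand, n_ins, n_del, n_sub, n_events)
        )
    return reads, truths


def write_truth(truths: list[TruthInterval], path) -> None:
    with open(path, "wt") as fh:
        fh.write("read_id\tref_start\tref_end\tstrand\tn_ins\tn_del\tn_sub\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.ref_start}\t{t.ref_end}\t{t.strand}"
                f"\t{t.n_ins}\t{t.n_del}\t{t.n_sub}\n"
            )
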