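"""Small shared helpers: alphabet handling and reverse complements."""

from __future__ import annotations

_RC = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_RC)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc
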