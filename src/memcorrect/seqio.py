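"""FASTA/FASTQ/GFA readers and writers.

Plumbing only: sequences are upper-cased on ingest, coordinates elsewhere in
the package are 0-based half-open, strands are '+'/'-'. Gzip input is handled
transparently by extension.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO

PathLike = Union[str, Path]


@dataclass
class SequenceRecord:
    """One sequencing read or reference sequence.

    ``qualities`` are per-base scores (Phred, as integers) and are optional;
    when present they have the same length as ``sequence``.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: PathLike) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: PathLike) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: cannot detect FASTA/FASTQ format")
    return "fasta"  # empty file: arbitrary, parses to an empty stream


def read_sequences(path: PathLike, format: str = "auto") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (gzip-aware).

    ``format`` may be ``fasta``, ``fastq`` or ``auto`` (sniff from content).
    Malformed records raise ``ValueError`` naming the offending record.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                quals = rec.letter_annotations.get("phred_quality")
                yield SequenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    qualities=list(quals) if quals is not None else None,
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {format} record: {exc}") from exc


def write_sequences(
    records: Iterable[SequenceRecord], path: PathLike, format: str = "fasta", wrap: int = 60
) -> int:
    """Write records as FASTA with fixed line wrap. Returns the record count.

    Output is deterministic byte-for-byte for a fixed input.
    """
    if format != "fasta":
        raise ValueError(f"unsupported output format {format!r}")
    n = 0
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
            if not seq:
                fh.write("\n")
            n += 1
    return n


def export_gfa(graph, path: PathLike) -> None:
    """Serialize a de Bruijn graph as GFA1.

    S-lines carry the node sequence and average k-mer coverage (``dc`` tag,
    float); L-lines carry the (k-1)M overlap. A ``CM`` header tag records k.
    Arcs are written once per reverse-complement pair (canonical member only).
    """
    k = graph.k
    with open(path, "wt") as fh:
        fh.write(f"H\tVN:Z:1.0\tkm:i:{k}\n")
        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            fh.write(f"S\t{nid}\t{node.sequence}\tdc:f:{node.avg_coverage:.4f}\n")
        seen = set()
        for (fid, fo), (tid, to) in sorted(graph.arcs):
            key = ((fid, fo), (tid, to))
            rc_key = ((tid, "-" if to == "+" else "+"), (fid, "-" if fo == "+" else "+"))
            if rc_key in seen:
                continue
            seen.add(key)
            fh.write(f"L\t{fid}\t{fo}\t{tid}\t{to}\t{k - 1}M\n")


def import_gfa(path: PathLike):
    """Read a GFA1 file written by :func:`export_gfa` back into a graph.

    A foreign GFA whose overlaps are not uniformly (k-1)M is rejected.
    """
    from .dbg import DeBruijnGraph, GraphNode

    k = None
    nodes = {}
    links = []
    with _open_text(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "H":
                for tag in fields[1:]:
                    if tag.startswith("km:i:"):
                        k = int(tag[5:])
            elif fields[0] == "S":
                nid = int(fields[1])
                seq = fields[2]
                cov = 1.0
                for tag in fields[3:]:
                    if tag.startswith("dc:f:"):
                        cov = float(tag[5:])
                nodes[nid] = GraphNode(nid, seq, cov)
            elif fields[0] == "L":
                links.append((int(fields[1]), fields[2], int(fields[3]), fields[4], fields[5]))
    if k is None:
        if not links:
            raise ValueError(f"{path}: GFA lacks a km header tag and has no links")
        k = int(links[0][4].rstrip("M")) + 1
    from ._util import revcomp

    def norm(end):
        node = nodes[end[0]]
        return (end[0], "+") if node.sequence == revcomp(node.sequence) else end

    arcs = set()
    flip = {"+": "-", "-": "+"}
    for fid, fo, tid, to, cigar in links:
        if cigar != f"{k - 1}M":
            raise ValueError(f"{path}: overlap {cigar} != {k - 1}M; foreign GFA dialect")
        arcs.add((norm((fid, fo)), norm((tid, to))))
        arcs.add((norm((tid, flip[to])), norm((fid, flip[fo]))))
    return DeBruijnGraph(k=k, nodes=nodes, arcs=arcs)
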