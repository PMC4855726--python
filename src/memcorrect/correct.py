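"""The top-level estimator: fit a graph/index on short reads, transform long reads.

``ReadCorrector`` follows the scikit-learn estimator protocol so the whole
hybrid-correction pipeline is one object: ``fit`` ingests accurate short
reads (or a prebuilt graph), builds and cleans the de Bruijn graph and the
MEM index; ``transform`` pseudo-aligns long reads to the graph and returns
their corrected pieces.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from sklearn.base import BaseEstimator, TransformerMixin

from . import dbg
from .aligner import CorrectedRead, ErrorModel, RunConfig, align_read, correct_read
from .mem_index import build_index
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


class ReadCorrector(BaseEstimator, TransformerMixin):
    """Hybrid long-read error correction by MEM-seeded graph pseudo-alignment.

    Parameters mirror :class:`~memcorrect.aligner.RunConfig`: ``dbg_k`` is the
    graph k-mer size (decoupled from the seed length), ``min_mem`` the minimum
    MEM seed length l, ``max_passes`` the chaining pass count p, and
    ``output_mode`` 'short' (clip to the estimated read extent) or 'long'
    (extend maximally along linear paths).

    Fitted attributes: ``graph_`` (cleaned de Bruijn graph), ``index_``
    (sparse suffix-array MEM index), ``report_`` (graph connectedness stats).
    """

    def __init__(
        self,
        dbg_k: int = 75,
        min_mem: int = 20,
        max_passes: int = 5,
        output_mode: str = "short",
        sparseness: int = 1,
        insertion_rate: float = 0.09,
        deletion_rate: float = 0.045,
        substitution_rate: float = 0.015,
        min_abundance: int = 2,
        coverage_ratio: float = 0.5,
        cover_safety: float = 0.5,
        clean: bool = True,
    ):
        self.dbg_k = dbg_k
        self.min_mem = min_mem
        self.max_passes = max_passes
        self.output_mode = output_mode
        self.sparseness = sparseness
        self.insertion_rate = insertion_rate
        self.deletion_rate = deletion_rate
        self.substitution_rate = substitution_rate
        self.min_abundance = min_abundance
        self.coverage_ratio = coverage_ratio
        self.cover_safety = cover_safety
        self.clean = clean

    def _config(self) -> RunConfig:
        return RunConfig(
            dbg_k=self.dbg_k,
            min_mem=self.min_mem,
            max_passes=self.max_passes,
            output_mode=self.output_mode,
            sparseness=self.sparseness,
            error_model=ErrorModel(
                self.insertion_rate, self.deletion_rate, self.substitution_rate
            ),
            min_abundance=self.min_abundance,
            coverage_ratio=self.coverage_ratio,
            cover_safety=self.cover_safety,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None):
        """Build (and clean) the de Bruijn graph and MEM index from short reads."""
        config = self._config()
        graph = dbg.build_graph(X, self.dbg_k, min_abundance=self.min_abundance)
        if self.clean:
            dbg.clean_graph(graph, coverage_ratio=self.coverage_ratio)
        return self._finish_fit(graph, config)

    def fit_graph(self, graph: dbg.DeBruijnGraph):
        """Fit from a prebuilt graph (e.g. imported GFA or a perfect graph)."""
        if graph.k != self.dbg_k:
            self.dbg_k = graph.k
        return self._finish_fit(graph, self._config())

    def _finish_fit(self, graph: dbg.DeBruijnGraph, config: RunConfig):
        self.graph_ = graph
        self.index_ = build_index(graph, self.sparseness)
        self.report_ = dbg.connectedness_report(graph)
        logger.info(
            "fitted graph: %d nodes, %d arcs, %.1f%% bases in largest component",
            self.report_["n_nodes"],
            self.report_["n_arcs"],
            100 * self.report_["fraction_of_total_bases"],
        )
        return self

    def transform(self, X: Iterable[SequenceRecord]) -> list[CorrectedRead]:
        """Correct long reads; returns the flat list of corrected pieces."""
        if not hasattr(self, "graph_"):
            raise RuntimeError("ReadCorrector is not fitted")
        config = self._config()
        out: list[CorrectedRead] = []
        n_in = 0
        for rec in X:
            n_in += 1
            alignments = align_read(rec.sequence, self.graph_, self.index_, config)
            pieces = correct_read(
                rec.sequence, alignments, self.graph_, config, source_id=rec.id
            )
            logger.debug("read %s: %d alignments, %d pieces", rec.id, len(alignments), len(pieces))
            out.extend(pieces)
        logger.info("corrected %d reads into %d pieces", n_in, len(out))
        return out

    def transform_records(self, X: Iterable[SequenceRecord]) -> list[SequenceRecord]:
        """Like :meth:`transform` but as writable sequence records."""
        return [SequenceRecord(p.id, p.sequence) for p in self.transform(X)]


def correct_long_reads(
    short_reads: Iterable[SequenceRecord],
    long_reads: Iterable[SequenceRecord],
    **params,
) -> list[SequenceRecord]:
    """One-shot functional wrapper over :class:`ReadCorrector`."""
    return ReadCorrector(**params).fit(short_reads).transform_records(long_reads)
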