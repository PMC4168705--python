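"""Five-step assembly orchestration: input reading, graph construction,
graph cleaning, graph reduction, contig extension — plus assembly metrics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .extend import (
    ContigRecord,
    ExtensionConfig,
    assemble_loop,
    emit_contigs,
)
from .graph import MSGGraph, auto_threshold, build_graph, clean_graph, dump_graph
from .io import read_sequences, write_contigs_fasta
from .swap import ScheduleReport, SchedulerConfig, reduce_graph

logger = logging.getLogger(__name__)


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L hold at least half of all
    assembled bases; 0 for an empty list."""
    if not lengths:
        return 0
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    return ordered[-1]  # pragma: no cover


@dataclass
class AssemblyStats:
    contig_count: int = 0
    total_bases: int = 0
    max_length: int = 0
    n50: int = 0
    molecules_before_clean: int = 0
    molecules_after_clean: int = 0
    edges_before_clean: int = 0
    edges_after_clean: int = 0
    molecule_threshold: int = 0
    edge_threshold: int = 0
    extension_rounds: int = 0
    schedule: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _resolve_thresholds(
    g: MSGGraph, threshold: int | str, fraction: float
) -> tuple[int, int]:
    if threshold == "auto":
        t = auto_threshold(g, fraction)
    else:
        t = int(threshold)
    return t, t


def assemble(
    inputs: Iterable[str | Path] | None = None,
    *,
    reads: Iterable[str] | None = None,
    k: int = 31,
    threshold: int | str = "auto",
    threshold_fraction: float = 0.05,
    min_contig_len: int | None = None,
    extension: ExtensionConfig | None = None,
    scheduler: SchedulerConfig | None = None,
    no_extension: bool = False,
    output: str | Path | None = None,
    stats_path: str | Path | None = None,
    dump_prefix: str | Path | None = None,
) -> tuple[list[ContigRecord], AssemblyStats]:
    """Run the full pipeline on read files (``inputs``) or in-memory
    ``reads`` and return the contigs and their statistics.

    ``threshold='auto'`` derives the cleaning cutoff from mean molecule
    coverage (``threshold_fraction`` of it, floor 2); an explicit integer is
    used for both molecule and edge cleaning. ``no_extension`` stops after
    graph reduction. ``min_contig_len`` defaults to 2k-1.
    """
    if (inputs is None) == (reads is None):
        raise ValueError("provide exactly one of inputs= or reads=")
    if reads is None:
        read_iter: list[str] = []
        for path in inputs:  # type: ignore[union-attr]
            read_iter.extend(read_sequences(path))
    else:
        read_iter = list(reads)
    if not read_iter:
        raise ValueError("no reads supplied")

    scheduler = scheduler or SchedulerConfig()
    extension = extension or ExtensionConfig()
    if min_contig_len is None:
        min_contig_len = 2 * k - 1

    g = build_graph(read_iter, k)
    stats = AssemblyStats(
        molecules_before_clean=g.n_molecules(), edges_before_clean=g.n_edges()
    )
    if dump_prefix is not None:
        Path(f"{dump_prefix}.construct.tsv").write_text(dump_graph(g))

    mt, et = _resolve_thresholds(g, threshold, threshold_fraction)
    stats.molecule_threshold, stats.edge_threshold = mt, et
    g = clean_graph(g, mt, et)
    stats.molecules_after_clean = g.n_molecules()
    stats.edges_after_clean = g.n_edges()
    if stats.molecules_before_clean:
        pct = 100 * (1 - stats.molecules_after_clean / stats.molecules_before_clean)
        logger.info(
            "cleaning removed %.1f%% of %d k-molecules (thresholds %d/%d)",
            pct, stats.molecules_before_clean, mt, et,
        )
    if dump_prefix is not None:
        Path(f"{dump_prefix}.clean.tsv").write_text(dump_graph(g))

    if no_extension:
        _, report = reduce_graph(g, scheduler)
        rounds = 0
    else:
        g, rounds, report = assemble_loop(g, extension, scheduler)
    stats.extension_rounds = rounds
    stats.schedule = report.to_dict()
    if dump_prefix is not None:
        Path(f"{dump_prefix}.final.tsv").write_text(dump_graph(g))

    contigs = emit_contigs(g, min_contig_len)
    lengths = [c.length for c in contigs]
    stats.contig_count = len(contigs)
    stats.total_bases = sum(lengths)
    stats.max_length = max(lengths, default=0)
    stats.n50 = n50(lengths)
    logger.info(
        "assembly: %d contigs, %d bases, N50 %d, max %d",
        stats.contig_count, stats.total_bases, stats.n50, stats.max_length,
    )

    if output is not None:
        write_contigs_fasta(output, contigs)
    if stats_path is not None:
        Path(stats_path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
    return contigs, stats
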