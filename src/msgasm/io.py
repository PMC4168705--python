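"""Read ingestion (FASTA/FASTQ, optionally gzipped) and contig output."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .extend import ContigRecord

_GZIP_MAGIC = b"\x1f\x8b"


class SequenceFormatError(ValueError):
    """Malformed or unrecognizable sequence file."""


def _open_text(path: str | Path, gzipped: str = "auto"):
    path = Path(path)
    if gzipped == "auto":
        with open(path, "rb") as fh:
            gz = fh.read(2) == _GZIP_MAGIC
    else:
        gz = gzipped == "yes"
    if gz:
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def _sniff_format(handle) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceFormatError(
        f"cannot recognize sequence format (first char {first!r}); "
        "expected FASTA ('>') or FASTQ ('@')"
    )


def read_sequences(
    path: str | Path, format: str = "auto", gzipped: str = "auto"
) -> Iterator[str]:
    """Stream uppercase sequences from a FASTA or FASTQ file, preserving
    record order. FASTQ qualities are discarded; multi-line FASTA is fine.
    Malformed records raise :class:`SequenceFormatError`."""
    with _open_text(path, gzipped) as handle:
        fmt = format if format != "auto" else _sniff_format(handle)
        try:
            for record in SeqIO.parse(handle, fmt):
                yield str(record.seq).upper()
        except ValueError as exc:
            raise SequenceFormatError(f"malformed {fmt} in {path}: {exc}") from exc


def write_contigs_fasta(path: str | Path, contigs: list[ContigRecord]) -> None:
    """Contig FASTA: ``>contig_<n> length=<L> cov=<c>[ circular]``, 80-column
    wrapped."""
    with open(path, "w") as fh:
        for c in contigs:
            header = f">{c.id} length={c.length} cov={c.coverage:.2f}"
            if c.circular:
                header += " circular"
            fh.write(header + "\n")
            for j in range(0, len(c.sequence), 80):
                fh.write(c.sequence[j : j + 80] + "\n")


def read_contig_lengths(path: str | Path) -> list[int]:
    """Lengths of the records in a FASTA file (for the stats command)."""
    with _open_text(path) as handle:
        return [len(r.seq) for r in SeqIO.parse(handle, "fasta")]
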