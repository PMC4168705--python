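"""The multi-step bi-directed de Bruijn graph: vertices are k-molecules,
edges carry an orientation at each endpoint plus a spelled label.

An edge ``(from_key, to_key, d_from, d_to, label)`` asserts that reading
molecule ``from_key`` in orientation ``d_from`` and appending ``label`` ends
in molecule ``to_key`` read in orientation ``d_to``::

    suffix_k(oriented(from_key, d_from) + label) == oriented(to_key, d_to)

Every edge has an equivalent *twin* representation seen from the other
endpoint; the store keeps exactly one of the two (the lexicographically
smaller tuple) and materializes the twin on demand, so an edge can never be
double-counted or double-mutated. A palindromic junction (an edge equal to
its own twin, e.g. spelled "TCGA" with k=3) is stored once and contributes
two attachment entries to its single molecule.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable

from .kmers import (
    kmer_list,
    negate,
    oriented,
    representative,
    reverse_complement,
    validate_k,
)

# An edge is identified by everything but its coverage.
EdgeKey = tuple[str, str, str, str, str]


@dataclass(frozen=True)
class BiEdge:
    """A multi-step bi-directed edge.

    ``step`` (the number of 1-step edges merged into it) always equals
    ``len(label)``; a freshly constructed edge has step 1.
    """

    from_key: str
    to_key: str
    d_from: str
    d_to: str
    label: str
    coverage: float = 0.0

    @property
    def step(self) -> int:
        return len(self.label)

    @property
    def key(self) -> EdgeKey:
        return (self.from_key, self.to_key, self.d_from, self.d_to, self.label)

    def spelled(self) -> str:
        """Full sequence of the edge: oriented source k-mer plus label."""
        return oriented(self.from_key, self.d_from) + self.label


class ZeroEdge:
    """Absorbing sentinel for non-existing edges (result of a failed merge)."""

    _instance: "ZeroEdge | None" = None

    def __new__(cls) -> "ZeroEdge":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "ZERO_EDGE"


ZERO_EDGE = ZeroEdge()


class GraphInvariantError(ValueError):
    """An edge or graph mutation violated a structural invariant."""


def check_edge(e: BiEdge, k: int) -> BiEdge:
    """Validate the oriented-string invariant of a single edge."""
    if e.step < 1:
        raise GraphInvariantError(f"empty label on edge {e}")
    spelled = oriented(e.from_key, e.d_from) + e.label
    if spelled[-k:] != oriented(e.to_key, e.d_to):
        raise GraphInvariantError(
            f"oriented-string invariant violated for edge {e.key}"
        )
    return e


def twin(e: BiEdge) -> BiEdge:
    """The equivalent representation of ``e`` from the other endpoint.

    An involution. The twin spells the reverse complement of the edge's
    sequence: its label is the reverse complement of the first ``step``
    bases of ``oriented(from_key, d_from) + label``.
    """
    spelled = oriented(e.from_key, e.d_from) + e.label
    return BiEdge(
        from_key=e.to_key,
        to_key=e.from_key,
        d_from=negate(e.d_to),
        d_to=negate(e.d_from),
        label=reverse_complement(spelled[: e.step]),
        coverage=e.coverage,
    )


def canonical_edge(e: BiEdge) -> BiEdge:
    """The stored representation: the smaller of ``e`` and ``twin(e)``."""
    t = twin(e)
    return e if e.key <= t.key else t


@dataclass(frozen=True)
class Attachment:
    """One slot of a molecule's adjacency: which edge, attached by which end,
    leaving on which side (outgoing orientation)."""

    side: str  # orientation of traversal leaving the molecule through this edge
    edge_key: EdgeKey
    end: str  # 'from' or 'to': which end of the stored record touches here


@dataclass
class Molecule:
    key: str
    frequency: int = 0


class MSGGraph:
    """Vertex/edge store with twin-consistent adjacency.

    Edges are stored once under their canonical key; molecules index their
    incident edges through :class:`Attachment` entries (a palindromic
    self-twin edge contributes two entries to the same molecule).
    """

    def __init__(self, k: int):
        self.k = validate_k(k)
        self.molecules: dict[str, Molecule] = {}
        self.edges: dict[EdgeKey, BiEdge] = {}
        self._attach: dict[str, list[Attachment]] = {}

    # ------------------------------------------------------------------ build

    def add_molecule(self, key: str, frequency: int = 0) -> Molecule:
        mol = self.molecules.get(key)
        if mol is None:
            mol = Molecule(key, 0)
            self.molecules[key] = mol
            self._attach[key] = []
        mol.frequency += frequency
        return mol

    @staticmethod
    def _attachments_of(e: BiEdge) -> list[tuple[str, Attachment]]:
        """The (molecule, attachment) entries a stored edge contributes."""
        return [
            (e.from_key, Attachment(e.d_from, e.key, "from")),
            (e.to_key, Attachment(negate(e.d_to), e.key, "to")),
        ]

    def add_edge(self, e: BiEdge, check: bool = True) -> BiEdge:
        """Insert ``e`` (canonicalized). If an identical edge record already
        exists, their coverages are summed. Endpoints must exist."""
        if check:
            check_edge(e, self.k)
        e = canonical_edge(e)
        existing = self.edges.get(e.key)
        if existing is not None:
            self.edges[e.key] = replace(
                existing, coverage=existing.coverage + e.coverage
            )
            return self.edges[e.key]
        for key in (e.from_key, e.to_key):
            if key not in self.molecules:
                raise GraphInvariantError(f"edge endpoint {key} not in graph")
        self.edges[e.key] = e
        for mol_key, att in self._attachments_of(e):
            self._attach[mol_key].append(att)
        return e

    def remove_edge(self, key: EdgeKey) -> BiEdge:
        e = self.edges.pop(key)
        for mol_key, att in self._attachments_of(e):
            self._attach[mol_key].remove(att)
        return e

    def remove_molecule(self, key: str) -> None:
        for att in list(self._attach.get(key, ())):
            if att.edge_key in self.edges:
                self.remove_edge(att.edge_key)
        del self.molecules[key]
        del self._attach[key]

    def set_coverage(self, key: EdgeKey, coverage: float) -> None:
        self.edges[key] = replace(self.edges[key], coverage=coverage)

    # ------------------------------------------------------------------ query

    def attachments(self, key: str) -> list[Attachment]:
        if key not in self.molecules:
            raise KeyError(f"molecule {key} not in graph")
        return list(self._attach[key])

    def degree(self, key: str) -> int:
        """Number of attachment entries (a self-edge counts twice)."""
        return len(self.attachments(key))

    def side_degree(self, key: str, side: str) -> int:
        """Attachments leaving ``key`` with outgoing orientation ``side``."""
        return sum(1 for a in self.attachments(key) if a.side == side)

    def attached_edges(self, key: str) -> set[EdgeKey]:
        return {a.edge_key for a in self.attachments(key)}

    def leaving_rep(self, att: Attachment) -> BiEdge:
        """The representation of ``att``'s edge whose source is the molecule
        the attachment belongs to (traversal leaves on ``att.side``)."""
        e = self.edges[att.edge_key]
        return e if att.end == "from" else twin(e)

    def n_molecules(self) -> int:
        return len(self.molecules)

    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "MSGGraph":
        g = MSGGraph(self.k)
        g.molecules = {k: Molecule(m.key, m.frequency) for k, m in self.molecules.items()}
        g.edges = dict(self.edges)
        g._attach = {k: list(v) for k, v in self._attach.items()}
        return g

    # ------------------------------------------------------------------ audit

    def audit(self) -> None:
        """Full-graph structural check; raises GraphInvariantError on failure.

        Verifies canonical single storage, the oriented-string invariant,
        endpoint membership, attachment/edge cross-consistency, and the
        eight-edge attachment bound for 1-step adjacencies.
        """
        for key, e in self.edges.items():
            if key != e.key:
                raise GraphInvariantError(f"edge stored under wrong key {key}")
            if canonical_edge(e).key != key:
                raise GraphInvariantError(f"edge {key} not in canonical form")
            check_edge(e, self.k)
            check_edge(twin(e), self.k)
            if twin(twin(e)).key != e.key:
                raise GraphInvariantError(f"twin not involutive for {key}")
            for mol_key, att in self._attachments_of(e):
                if mol_key not in self.molecules:
                    raise GraphInvariantError(f"endpoint {mol_key} missing")
                if att not in self._attach[mol_key]:
                    raise GraphInvariantError(
                        f"attachment of {key} missing at {mol_key}"
                    )
        for mol_key, atts in self._attach.items():
            for att in atts:
                if att.edge_key not in self.edges:
                    raise GraphInvariantError(
                        f"dangling attachment at {mol_key}: {att.edge_key}"
                    )
            one_step = {a.edge_key for a in atts if len(a.edge_key[4]) == 1}
            if len(one_step) > 8:
                raise GraphInvariantError(
                    f"molecule {mol_key} has {len(one_step)} one-step edges (>8)"
                )

    # ------------------------------------------------------------- statistics

    def mean_molecule_frequency(self) -> float:
        if not self.molecules:
            return 0.0
        return sum(m.frequency for m in self.molecules.values()) / len(self.molecules)


def build_graph(reads: Iterable[str], k: int) -> MSGGraph:
    """Construct the 1-step bi-directed graph of a read set.

    A window of length k slides along each read; every window increments its
    molecule's frequency, and every consecutive window pair contributes one
    1-step edge occurrence (coverage). The construction is strand symmetric:
    the graph of the reverse-complemented read set is identical.
    """
    g = MSGGraph(k)
    for read in reads:
        windows = kmer_list(read.upper(), k)
        prev: tuple[str, str, str] | None = None  # (kmer, key, orientation)
        for w in windows:
            key, d = representative(w)
            g.add_molecule(key, frequency=1)
            if prev is not None and prev[0][1:] == w[:-1]:
                _, pkey, pd = prev
                g.add_edge(
                    BiEdge(pkey, key, pd, d, label=w[-1], coverage=1.0),
                    check=False,
                )
            prev = (w, key, d)
    return g


# ----------------------------------------------------------------- cleaning


def auto_threshold(g: MSGGraph, fraction: float = 0.05) -> int:
    """Frequency cutoff derived from mean molecule coverage.

    ``max(2, ceil(fraction * mean frequency))``; 0 for an empty graph. The
    3-10% band of the average coverage is the usual working range for
    separating erroneous k-molecules from genuine ones.
    """
    if not g.molecules:
        return 0
    return max(2, math.ceil(fraction * g.mean_molecule_frequency()))


def clean_graph(
    g: MSGGraph, molecule_threshold: int, edge_threshold: int | None = None
) -> MSGGraph:
    """Remove low-frequency molecules (with their edges), then low-coverage
    edges, then molecules left without any attachment. Strict comparison
    (< threshold is removed); idempotent at fixed thresholds.

    Returns a new graph; the input is not modified.
    """
    if edge_threshold is None:
        edge_threshold = molecule_threshold
    g = g.copy()
    for key in [k for k, m in g.molecules.items() if m.frequency < molecule_threshold]:
        g.remove_molecule(key)
    for ekey in [k for k, e in g.edges.items() if e.coverage < edge_threshold]:
        g.remove_edge(ekey)
    for key in [k for k in g.molecules if not g._attach[k]]:
        g.remove_molecule(key)
    return g


# ------------------------------------------------------------- dump / load

_DUMP_FLOAT_FMT = "{:.6g}"


def dump_graph(g: MSGGraph, handle: io.TextIOBase | None = None) -> str:
    """Serialize to the TSV dialect::

        K  <k>
        M  <representative>  <frequency>
        E  <from> <to> <d_from> <d_to> <label> <coverage>

    Lines are emitted in sorted order, so equal graphs dump identically.
    """
    lines = [f"K\t{g.k}"]
    for key in sorted(g.molecules):
        lines.append(f"M\t{key}\t{g.molecules[key].frequency}")
    for ekey in sorted(g.edges):
        e = g.edges[ekey]
        cov = _DUMP_FLOAT_FMT.format(e.coverage)
        lines.append(
            f"E\t{e.from_key}\t{e.to_key}\t{e.d_from}\t{e.d_to}\t{e.label}\t{cov}"
        )
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


def load_graph(source: str | io.TextIOBase) -> MSGGraph:
    """Parse the TSV dialect produced by :func:`dump_graph`."""
    text = source if isinstance(source, str) else source.read()
    g: MSGGraph | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        tag = parts[0]
        try:
            if tag == "K":
                g = MSGGraph(int(parts[1]))
            elif tag == "M":
                if g is None:
                    raise ValueError("M line before K header")
                g.add_molecule(parts[1], int(parts[2]))
            elif tag == "E":
                if g is None:
                    raise ValueError("E line before K header")
                _, f, t, df, dt, label, cov = parts
                g.add_edge(BiEdge(f, t, df, dt, label, float(cov)))
            else:
                raise ValueError(f"unknown record tag {tag!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed graph dump at line {lineno}: {exc}") from exc
    if g is None:
        raise ValueError("empty graph dump (missing K header)")
    return g
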