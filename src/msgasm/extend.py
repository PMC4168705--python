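"""Contig-extension heuristics and contig emission.

After reduction, the graph stalls at structures a pure unanimous-path merge
cannot pass: short dead-end spurs (tips), self-loops, parallel edges, and
cross-like junctions. Each heuristic resolves one structure class; the
reduce/extend loop alternates reduction with the heuristics until a full
pass changes nothing. Remaining edges are emitted as contigs.

Coverage is the arbiter throughout: tips and the lower-coverage member of a
parallel pair are treated as error artifacts, while junction edges are paired
through the junction only when their coverages agree to within a relative
tolerance (default 20%) — the signature of a single genomic path crossing a
repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import BiEdge, EdgeKey, MSGGraph, ZeroEdge, twin
from .kmers import MINUS, PLUS, negate, oriented, reverse_complement
from .swap import SchedulerConfig, ScheduleReport, merge, reduce_graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtensionConfig:
    """Knobs of the extension heuristics.

    tip_max_label: spur edges with label shorter than this (default: k,
        set at use time when left None) are deletable tips.
    coverage_tolerance: maximum relative coverage difference,
        |c1-c2|/max(c1,c2), for pairing edges through a junction.
    max_rounds: cap on reduce/extend passes.
    """

    tip_max_label: int | None = None
    coverage_tolerance: float = 0.20
    max_rounds: int = 16
    enable_tips: bool = True
    enable_self_loops: bool = True
    enable_multiple_edges: bool = True
    enable_cross: bool = True
    enable_virtual_cross: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_tolerance < 1.0:
            raise ValueError("coverage_tolerance must be in (0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")

    def tip_limit(self, k: int) -> int:
        return self.tip_max_label if self.tip_max_label is not None else k


def _within_tolerance(c1: float, c2: float, tol: float) -> bool:
    hi = max(c1, c2)
    if hi <= 0:
        return True
    return abs(c1 - c2) / hi < tol


def _prune_bare_molecules(g: MSGGraph) -> None:
    for key in [k for k in g.molecules if not g.attachments(k)]:
        g.remove_molecule(key)


def remove_tips(g: MSGGraph, cfg: ExtensionConfig) -> tuple[MSGGraph, int]:
    """Delete dead-end spur edges.

    A tip has exactly one endpoint of degree 1 and a label shorter than the
    tip limit. An isolated edge (both endpoints degree 1) is a finished
    contig, never a tip. Mutates in place; returns (graph, removed count).
    """
    limit = cfg.tip_limit(g.k)
    doomed: list[EdgeKey] = []
    for ekey, e in g.edges.items():
        if e.step >= limit:
            continue
        if e.from_key == e.to_key:
            continue
        d_from, d_to = g.degree(e.from_key), g.degree(e.to_key)
        if (d_from == 1) != (d_to == 1):
            doomed.append(ekey)
    for ekey in doomed:
        g.remove_edge(ekey)
    _prune_bare_molecules(g)
    return g, len(doomed)


def resolve_self_loops(g: MSGGraph) -> tuple[MSGGraph, int, int]:
    """Merge each self-loop edge with a direction-compatible neighbor edge
    (highest coverage first), or delete it when no neighbor can take it.

    The degree-2 requirement of ordinary merging is deliberately waived here:
    this is how palindromic junctions — which block reduction because the
    loop doubles the center's degree — are opened up. Returns
    (graph, merged count, removed count).
    """
    loops = [ekey for ekey, e in g.edges.items() if e.from_key == e.to_key]
    merged = removed = 0
    for ekey in loops:
        if ekey not in g.edges:
            continue
        loop = g.edges[ekey]
        center = loop.from_key
        loop_reps = {loop.key: loop, twin(loop).key: twin(loop)}.values()
        best: tuple[float, EdgeKey, BiEdge] | None = None
        for att in g.attachments(center):
            if att.edge_key == ekey:
                continue
            neighbor = g.leaving_rep(att)  # leaves center
            for lrep in loop_reps:
                # neighbor enters center, then around the loop ...
                cand = merge(twin(neighbor), lrep)
                # ... or around the loop, then out through the neighbor.
                if isinstance(cand, ZeroEdge):
                    cand = merge(lrep, neighbor)
                if isinstance(cand, ZeroEdge):
                    continue
                rank = (neighbor.coverage, att.edge_key)
                if best is None or rank > (best[0], best[1]):
                    best = (neighbor.coverage, att.edge_key, cand)
        if best is None:
            g.remove_edge(ekey)
            removed += 1
        else:
            _, neighbor_key, cand = best
            g.remove_edge(ekey)
            g.remove_edge(neighbor_key)
            g.add_edge(cand)
            merged += 1
    _prune_bare_molecules(g)
    return g, merged, removed


def _connection_key(e: BiEdge) -> tuple:
    """Label-independent identity of the connection an edge realizes."""
    fwd = (e.from_key, e.to_key, e.d_from, e.d_to)
    rev = (e.to_key, e.from_key, negate(e.d_to), negate(e.d_from))
    return min(fwd, rev)


def resolve_multiple_edges(g: MSGGraph) -> tuple[MSGGraph, int]:
    """Among parallel edges (same endpoints, same endpoint orientations),
    keep only the highest-coverage one; ties keep the lexicographically
    smaller label. Returns (graph, removed count)."""
    groups: dict[tuple, list[BiEdge]] = {}
    for e in g.edges.values():
        groups.setdefault(_connection_key(e), []).append(e)
    removed = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda e: (-e.coverage, e.label))
        for e in members[1:]:
            g.remove_edge(e.key)
            removed += 1
    _prune_bare_molecules(g)
    return g, removed


def _paired_pass(
    g: MSGGraph,
    ins: list,
    outs: list,
    tol: float,
    through: BiEdge | None = None,
) -> int:
    """Pair in-attachments with out-attachments by descending coverage and
    merge each accepted pair (optionally through a cloned middle edge)."""
    def cov(att):
        return g.edges[att.edge_key].coverage

    ins = sorted(ins, key=lambda a: (-cov(a), a.edge_key))
    outs = sorted(outs, key=lambda a: (-cov(a), a.edge_key))
    merged = 0
    for a, b in zip(ins, outs):
        if a.edge_key == b.edge_key:
            continue
        if a.edge_key not in g.edges or b.edge_key not in g.edges:
            continue
        if not _within_tolerance(cov(a), cov(b), tol):
            continue
        left = twin(g.leaving_rep(a))
        right = g.leaving_rep(b)
        path = merge(left, through) if through is not None else left
        if isinstance(path, ZeroEdge):
            continue
        cand = merge(path, right)
        if isinstance(cand, ZeroEdge):
            continue
        g.remove_edge(a.edge_key)
        g.remove_edge(b.edge_key)
        g.add_edge(cand)
        merged += 1
    return merged


def resolve_cross_vertices(
    g: MSGGraph, cfg: ExtensionConfig
) -> tuple[MSGGraph, int]:
    """Resolve X-junctions: molecules with >= 2 attachments on each side.

    Edges are sorted by descending coverage side by side and paired rank for
    rank; a pair whose coverages agree within the tolerance is merged through
    a cloned copy of the center (the degree condition is waived), consuming
    both edges. Unpaired edges stay attached. Returns (graph, merged pairs).
    """
    candidates = [
        key
        for key in g.molecules
        if g.side_degree(key, PLUS) >= 2 and g.side_degree(key, MINUS) >= 2
    ]
    merged = 0
    for key in candidates:
        if key not in g.molecules:
            continue
        atts = g.attachments(key)
        plus = [a for a in atts if a.side == PLUS]
        minus = [a for a in atts if a.side == MINUS]
        if len(plus) < 2 or len(minus) < 2:
            continue
        # Traversal enters through a plus-side edge's twin and leaves minus-side.
        merged += _paired_pass(g, plus, minus, cfg.coverage_tolerance)
    _prune_bare_molecules(g)
    return g, merged


def resolve_virtual_cross(
    g: MSGGraph, cfg: ExtensionConfig
) -> tuple[MSGGraph, int]:
    """Resolve H-junctions: an edge e0 whose endpoints each carry >= 2
    further edges on their outer sides acts as one virtual cross vertex.

    Outer edges are ranked by coverage and paired across e0 under the same
    tolerance rule; each accepted pair produces (outer_in x e0 x outer_out)
    through a cloned e0. e0 itself is removed only when every outer edge on
    both sides was consumed. Returns (graph, merged pairs).
    """
    e0_keys = [k for k, e in g.edges.items() if e.from_key != e.to_key]
    merged = 0
    for ekey in e0_keys:
        if ekey not in g.edges:
            continue
        e0 = g.edges[ekey]
        u, v = e0.from_key, e0.to_key
        # outer-in edges at u must enter u compatibly with e0 leaving it;
        # they sit on the side opposite e0's from-attachment.
        u_outer = [
            a
            for a in g.attachments(u)
            if a.edge_key != ekey and a.side == negate(e0.d_from)
        ]
        v_outer = [
            a
            for a in g.attachments(v)
            if a.edge_key != ekey and a.side == e0.d_to
        ]
        if len(u_outer) < 2 or len(v_outer) < 2:
            continue
        n_outer = len(u_outer) + len(v_outer)
        got = _paired_pass(g, u_outer, v_outer, cfg.coverage_tolerance, through=e0)
        merged += got
        if got and 2 * got == n_outer:
            # every outer edge consumed: the virtual vertex is fully resolved
            if ekey in g.edges:
                g.remove_edge(ekey)
    _prune_bare_molecules(g)
    return g, merged


def assemble_loop(
    g: MSGGraph,
    cfg: ExtensionConfig | None = None,
    scheduler_cfg: SchedulerConfig | None = None,
) -> tuple[MSGGraph, int, ScheduleReport]:
    """Alternate the extension heuristics with graph reduction until a full
    pass changes nothing (or max_rounds is reached, with a warning).

    Pass order: self-loops, multiple edges, cross, virtual cross, reduction,
    tips. Self-loop resolution precedes reduction because a self-loop doubles
    its anchor's degree and thereby hides the unanimous continuation; tip
    removal runs after reduction so that genuine terminal arms exposed by a
    resolved junction are merged into their chain before the spur test sees
    them as short dead ends.

    Returns (graph, passes that made changes, cumulative schedule report).
    """
    cfg = cfg or ExtensionConfig()
    scheduler_cfg = scheduler_cfg or SchedulerConfig()
    total = ScheduleReport()
    rounds = 0
    while True:
        changed = 0
        if cfg.enable_self_loops:
            _, m, r = resolve_self_loops(g)
            changed += m + r
        if cfg.enable_multiple_edges:
            _, n = resolve_multiple_edges(g)
            changed += n
        if cfg.enable_cross:
            _, n = resolve_cross_vertices(g, cfg)
            changed += n
        if cfg.enable_virtual_cross:
            _, n = resolve_virtual_cross(g, cfg)
            changed += n
        _, report = reduce_graph(g, scheduler_cfg)
        changed += report.operations_applied
        total.rounds += report.rounds
        total.operations_applied += report.operations_applied
        total.per_round_counts.extend(report.per_round_counts)
        if cfg.enable_tips:
            _, n = remove_tips(g, cfg)
            changed += n
        if changed == 0:
            break
        rounds += 1
        if rounds >= cfg.max_rounds:
            logger.warning(
                "assembly loop stopped at max_rounds=%d before fixpoint",
                cfg.max_rounds,
            )
            reduce_graph(g, scheduler_cfg)
            break
    return g, rounds, total


@dataclass(frozen=True)
class ContigRecord:
    """An emitted contig. ``sequence`` is canonical (the lexicographically
    larger of the spelled string and its reverse complement); ``circular``
    flags a self-edge closing on itself with matching orientation (a
    collapsed circular chain)."""

    id: str
    sequence: str
    length: int
    coverage: float
    circular: bool = False


def emit_contigs(g: MSGGraph, min_length: int | None = None) -> list[ContigRecord]:
    """One contig per remaining edge: the oriented source k-mer plus the
    label, canonicalized; records shorter than ``min_length`` are dropped.
    Deterministic ordering by (length descending, sequence)."""
    if min_length is None:
        min_length = g.k
    rows: list[tuple[str, float, bool]] = []
    for e in g.edges.values():
        seq = oriented(e.from_key, e.d_from) + e.label
        seq = max(seq, reverse_complement(seq))
        if len(seq) < min_length:
            continue
        circular = (
            e.from_key == e.to_key
            and e.d_from == e.d_to
            and len(g.attachments(e.from_key)) == 2
        )
        rows.append((seq, e.coverage, circular))
    rows.sort(key=lambda r: (-len(r[0]), r[0]))
    return [
        ContigRecord(f"contig_{i + 1}", seq, len(seq), cov, circ)
        for i, (seq, cov, circ) in enumerate(rows)
    ]
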