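"""Edge merging (the semigroup operation), the mergeable-pair operation set,
and a round-synchronous scheduler in the small-world lock-compute-unlock
style, emulated in one process.

Two consecutive bi-directed edges meeting at a degree-2 molecule with
matching traversal orientation merge into one multi-step edge whose label is
the concatenation of the two labels. The operation is associative, so the
final set of fully extended edges (the contigs) is independent of merge
order — which is what allows merges to be applied concurrently. Per round,
a maximal set of pairwise non-conflicting merges is applied (two merges
conflict iff their *small worlds* — the records they touch — intersect);
a pure path of E edges therefore collapses in ceil(log2 E) rounds.

The distributed lock protocol is emulated as independent-set selection over
one graph snapshot per round: a selected operation corresponds to a
successful lock of its whole small world, a skipped one to a lock failure
retried next round. ``partitions`` emulates the hash distribution of the
operation set across processes; it affects bookkeeping only, never results.
"""

from __future__ import annotations

import heapq
import math
import random
import zlib
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

from .graph import ZERO_EDGE, BiEdge, EdgeKey, MSGGraph, ZeroEdge, twin
from .kmers import MINUS


def merge(e1: BiEdge | ZeroEdge, e2: BiEdge | ZeroEdge) -> BiEdge | ZeroEdge:
    """The edge-merging operation (a total function; failure is the zero edge).

    Succeeds when ``e1`` ends where ``e2`` starts with the same traversal
    orientation; the result concatenates labels, sums steps, and carries the
    label-length-weighted mean coverage. Degree conditions at the shared
    molecule are the caller's concern, not checked here.
    """
    if isinstance(e1, ZeroEdge) or isinstance(e2, ZeroEdge):
        return ZERO_EDGE
    if e1.to_key != e2.from_key or e1.d_to != e2.d_from:
        return ZERO_EDGE
    x, y = e1.step, e2.step
    return BiEdge(
        from_key=e1.from_key,
        to_key=e2.to_key,
        d_from=e1.d_from,
        d_to=e2.d_to,
        label=e1.label + e2.label,
        coverage=(e1.coverage * x + e2.coverage * y) / (x + y),
    )


@dataclass(frozen=True)
class MergePair:
    """One element of the operation set: two distinct edges meeting at a
    degree-2 center, oriented so ``left`` enters the center and ``right``
    leaves it (``left.d_to == right.d_from``)."""

    left: BiEdge
    right: BiEdge
    center: str
    left_key: EdgeKey
    right_key: EdgeKey

    @property
    def sort_key(self) -> tuple:
        return (self.center, min(self.left_key, self.right_key))

    def small_world(self) -> frozenset:
        """Records this operation touches: both edges, the center molecule,
        and the far endpoints' attachment slots (identified by the consumed
        edge, so slot conflicts coincide with edge conflicts)."""
        return frozenset(
            [("E", self.left_key), ("E", self.right_key), ("C", self.center)]
        )


def enumerate_sigma(g: MSGGraph) -> list[MergePair]:
    """All mergeable pairs of the current graph: one per degree-2 molecule
    whose two attachments are distinct edges leaving on opposite sides."""
    pairs: list[MergePair] = []
    for key in g.molecules:
        atts = g.attachments(key)
        if len(atts) != 2:
            continue
        a, b = atts
        if a.edge_key == b.edge_key:  # self-loop or palindromic junction
            continue
        if a.side == b.side:  # both edges leave the same strand: no through-path
            continue
        if a.side == MINUS:
            a, b = b, a
        # a leaves on '+', b on '-': enter through a's twin, leave through b.
        left = twin(g.leaving_rep(a))
        right = g.leaving_rep(b)
        assert left.d_to == right.d_from
        pairs.append(MergePair(left, right, key, a.edge_key, b.edge_key))
    return pairs


@dataclass(frozen=True)
class SchedulerConfig:
    """Round scheduler settings: ``deterministic`` orders operations by
    canonical center key; ``randomized`` draws a random priority order from
    ``seed`` (emulating backoff winners). ``partitions`` is the logical
    process count of the emulated hash distribution."""

    mode: str = "deterministic"
    seed: int = 0
    partitions: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("deterministic", "randomized"):
            raise ValueError(f"unknown scheduler mode {self.mode!r}")
        if self.partitions < 1:
            raise ValueError("partitions must be >= 1")


@dataclass
class ScheduleReport:
    rounds: int = 0
    operations_applied: int = 0
    per_round_counts: list[int] = field(default_factory=list)
    per_partition_counts: dict[int, int] = field(default_factory=dict)
    circular_chains: int = 0

    def record_round(self, ops: int) -> None:
        self.rounds += 1
        self.operations_applied += ops
        self.per_round_counts.append(ops)

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "operations_applied": self.operations_applied,
            "per_round_counts": list(self.per_round_counts),
        }


def _partition_of(token: Hashable, partitions: int) -> int:
    return zlib.crc32(repr(token).encode()) % partitions


def _select_ops(
    ops: Sequence,
    small_world: Callable[[object], frozenset],
    sort_key: Callable[[object], tuple],
    cfg: SchedulerConfig,
    seed: int,
) -> list:
    """A maximal set of operations with pairwise-disjoint small worlds.

    Deterministic mode selects by fewest-remaining-conflicts first (ties by
    canonical sort key): on chain-shaped conflict graphs this always takes a
    chain end next, which alternates selections and achieves the maximum
    independent set — the source of the per-round halving on pure paths.
    Randomized mode emulates backoff winners with a seeded priority order.
    Both are maximal: every rejected operation conflicts with a selected one.
    """
    ordered = sorted(ops, key=sort_key)
    worlds = [small_world(op) for op in ordered]
    if cfg.mode == "randomized":
        random.Random(seed).shuffle(ordered)
        worlds = [small_world(op) for op in ordered]
        locked: set = set()
        selected = []
        for op, world in zip(ordered, worlds):
            if world & locked:
                continue
            locked |= world
            selected.append(op)
        return selected
    # deterministic: min-conflict-degree greedy
    token_to_ops: dict = {}
    for i, world in enumerate(worlds):
        for tok in world:
            token_to_ops.setdefault(tok, []).append(i)
    neighbors: list[set[int]] = [set() for _ in ordered]
    for members in token_to_ops.values():
        for i in members:
            neighbors[i].update(j for j in members if j != i)
    alive = set(range(len(ordered)))
    selected = []
    heap = [(len(neighbors[i]), i) for i in alive]
    heapq.heapify(heap)
    degree = {i: len(neighbors[i]) for i in alive}
    while heap:
        d, i = heapq.heappop(heap)
        if i not in alive or d != degree[i]:
            continue
        selected.append(ordered[i])
        doomed = {i} | (neighbors[i] & alive)
        alive -= doomed
        for j in doomed:
            for nb in neighbors[j]:
                if nb in alive:
                    degree[nb] -= 1
                    heapq.heappush(heap, (degree[nb], nb))
    selected.sort(key=sort_key)
    return selected


def select_independent(
    pairs: Iterable[MergePair], cfg: SchedulerConfig
) -> list[MergePair]:
    """Maximal conflict-free subset of merge pairs (see :func:`_select_ops`)."""
    return _select_ops(
        list(pairs), MergePair.small_world, lambda p: p.sort_key, cfg, cfg.seed
    )


def apply_merge(g: MSGGraph, pair: MergePair) -> BiEdge:
    """Replace the pair's two edges with their merge and retire the center."""
    merged = merge(pair.left, pair.right)
    assert not isinstance(merged, ZeroEdge)
    g.remove_edge(pair.left_key)
    g.remove_edge(pair.right_key)
    if not g.attachments(pair.center):
        g.remove_molecule(pair.center)
    return g.add_edge(merged)


def reduction_round(g: MSGGraph, cfg: SchedulerConfig) -> int:
    """One synchronous round: enumerate, select a maximal independent set,
    apply all selected merges. Returns the number of merges applied."""
    selected = select_independent(enumerate_sigma(g), cfg)
    for pair in sorted(selected, key=lambda p: p.sort_key):
        apply_merge(g, pair)
    return len(selected)


def max_rounds_cap(n_edges: int) -> int:
    """Safety cap: the theoretical ceil(log2 E) bound with generous slack."""
    return 4 * math.ceil(math.log2(n_edges + 2))


class ScheduleOverrunError(RuntimeError):
    """The activity did not reach a fixpoint within the round cap."""


def reduce_graph(
    g: MSGGraph, cfg: SchedulerConfig | None = None
) -> tuple[MSGGraph, ScheduleReport]:
    """Merge until no mergeable pair remains (all paths fully extended).

    Mutates ``g`` in place and returns it with a :class:`ScheduleReport`.
    The final edge multiset is independent of scheduler mode, seed and
    partition count (associativity of the merge).
    """
    cfg = cfg or SchedulerConfig()
    activity = Activity(
        enumerate_ops=enumerate_sigma,
        small_world=MergePair.small_world,
        apply=apply_merge,
        sort_key=lambda p: p.sort_key,
    )
    report = run_swap(g, activity, cfg)
    return g, report


@dataclass
class Activity:
    """A SWAP computational activity: how to enumerate the operation set over
    the current state, extract an operation's small world, and evaluate it.
    The evaluator must be associative over its element domain (caller's
    responsibility) for the result to be schedule-independent."""

    enumerate_ops: Callable[[object], Sequence]
    small_world: Callable[[object], frozenset]
    apply: Callable[[object, object], object]
    sort_key: Callable[[object], tuple] = lambda op: (repr(op),)


def run_swap(
    state: object,
    activity: Activity,
    cfg: SchedulerConfig | None = None,
    max_rounds: int | None = None,
) -> ScheduleReport:
    """Generic round-synchronous driver for an associative activity.

    Each round takes a snapshot of the operation set, selects a maximal
    conflict-free subset (ordered canonically or by seeded random priority),
    and applies it; stops when the operation set is empty. Guarded by a
    round cap (:class:`ScheduleOverrunError` beyond it).
    """
    cfg = cfg or SchedulerConfig()
    report = ScheduleReport()
    round_seed = cfg.seed
    while True:
        ops = list(activity.enumerate_ops(state))
        if not ops:
            break
        if max_rounds is None:
            max_rounds = max_rounds_cap(len(ops))
        if report.rounds >= max_rounds:
            raise ScheduleOverrunError(
                f"no fixpoint after {report.rounds} rounds ({len(ops)} ops left)"
            )
        selected = _select_ops(
            ops, activity.small_world, activity.sort_key, cfg, round_seed
        )
        for op in selected:
            part = _partition_of(activity.sort_key(op), cfg.partitions)
            report.per_partition_counts[part] = (
                report.per_partition_counts.get(part, 0) + 1
            )
            activity.apply(state, op)
        report.record_round(len(selected))
        round_seed = (round_seed * 1103515245 + 12345) % (2**31)
    return report


# ------------------------------------------------------- schedule cost model


def schedule_cost(path_node_counts: Sequence[int], strategy: str) -> int:
    """Cost of collapsing a set of linear paths under a scheduling strategy.

    Each entry is the number of k-molecules on one path (>= 2, i.e. >= 1
    edge). ``sequential`` counts total k-mer join operations, one per join
    across the whole workload (m - 1 per path of m nodes). ``per_path_parallel``
    counts rounds when paths advance concurrently but joins within a path are
    serial (max of m - 1). ``swap`` counts rounds of pairwise concurrent edge
    merging (max of ceil(log2(m - 1)); 0 when a path is already a single edge).
    """
    counts = list(path_node_counts)
    if not counts:
        return 0
    for m in counts:
        if m < 2:
            raise ValueError(f"a path needs at least 2 k-molecules, got {m}")
    if strategy == "sequential":
        return sum(m - 1 for m in counts)
    if strategy == "per_path_parallel":
        return max(m - 1 for m in counts)
    if strategy == "swap":
        return max(
            0 if m - 1 <= 1 else math.ceil(math.log2(m - 1)) for m in counts
        )
    raise ValueError(f"unknown strategy {strategy!r}")
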