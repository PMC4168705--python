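# Methods

## The model

`msgasm` assembles short DNA reads with a bi-directed de Bruijn graph over
*k-molecules*. A k-molecule is the unordered pair of a k-mer and its reverse
complement; it is represented by the lexicographically **larger** member
(byte order, A < C < G < T), called the positive k-mer. k is restricted to
odd values ≥ 3, which rules out self-reverse-complementary k-mers, so the
±split of every molecule is well defined. Note that many assemblers pick the
*smaller* member as canonical; the choice is arbitrary but must be made
consistently, and this package uses the larger-member convention throughout
(contig sequences are likewise reported as the larger of the two strands).

An edge `(from, to, d_from, d_to, label)` carries an orientation at each
endpoint and a spelled label, subject to the oriented-string invariant

    suffix_k(oriented(from, d_from) ∘ label) = oriented(to, d_to)

where `oriented(m, +)` is the representative and `oriented(m, −)` its
reverse complement. Every edge has an equivalent *twin* seen from the other
endpoint — `(to, from, ¬d_to, ¬d_from, label′)` with
`label′ = revcomp(prefix_step(oriented(from, d_from) ∘ label))` — and the
store keeps exactly one of the two representations (the smaller tuple),
materializing the twin on demand. This makes double-counting and
double-mutation structurally impossible and gives exact strand symmetry:
the graph built from the reverse-complemented read set is identical,
byte for byte, in the TSV dump.

A 1-step edge joins two consecutive windows of a read; its label is the
last base of the second window as traversed. Molecule frequency counts
window occurrences; edge coverage counts adjacent-pair occurrences. A
molecule can carry at most four distinct 1-step edges per strand — one per
extension base — hence at most eight distinct edges. One wrinkle: when a
(k+1)-mer is its own reverse complement (e.g. `TCGA` at k=3), the resulting
edge is its own twin and attaches twice to its single molecule on the same
side. Degree counts attachment *entries* (such an edge contributes 2), while
the eight-bound applies to distinct *edges*; a fully saturated molecule with
a palindromic extension therefore has 9 entries but exactly 8 edges, and the
audit checks the latter.

## Edge merging and scheduling

Two edges meeting at a molecule of degree 2, entering and leaving on
opposite strands, merge into one multi-step edge: labels concatenate, steps
add, and coverage becomes the label-length-weighted mean of the inputs
(exactly associative in exact arithmetic; compared with a float tolerance in
tests). Merging is a total function whose failure value is an absorbing
zero edge. Because the operation is associative, the final set of
fully extended edges — the contigs — does not depend on merge order, which
is what licenses concurrent application.

The scheduler is round-synchronous. Each round enumerates all mergeable
pairs of the current graph, selects a maximal subset whose *small worlds*
(the two consumed edges plus the center molecule; far-endpoint attachment
slots are identified by the consumed edge) are pairwise disjoint, and
applies the whole selection. A distributed lock-compute-unlock protocol is
emulated by this selection: selected = lock succeeded, rejected = retry next
round. `partitions` emulates hashing the operation set across processes and
affects only per-partition bookkeeping, never results (tested).

Deterministic selection is min-conflict-degree greedy with canonical-key tie
breaks. On a chain of E edges the conflict graph is a path, and taking a
lowest-conflict operation first always takes a chain end, which alternates
selections, achieves the maximum independent set (⌊E/2⌋ merges), and yields
the ⌈log₂ E⌉ round bound that the cost model predicts; plain priority-order
greedy does not guarantee this, which is why it is not used. Randomized mode
draws a seeded priority order per round (a stand-in for backoff winners) and
must — and does — produce the same final contigs.

A safety cap of `4·⌈log₂(ops+2)⌉` rounds guards non-terminating activities.
Circular chains (every molecule degree 2) reduce to a single self-edge whose
endpoint orientations match; no mergeable pair remains because a pair
requires two distinct edges, so cycles terminate naturally and the final
edge is flagged circular.

The schedule-cost model compares three strategies on a workload of linear
paths with mᵢ molecules each: sequential joins (`Σ(mᵢ−1)` operations),
per-path parallelism (`max(mᵢ−1)` rounds), and pairwise-concurrent merging
(`max ⌈log₂(mᵢ−1)⌉` rounds, 0 for a single edge).

## Cleaning

Sequencing errors produce k-mers of characteristically low multiplicity.
Cleaning removes molecules with frequency below a threshold together with
their edges, then edges below a coverage threshold, then stranded molecules.
Comparisons are strict (`< threshold` removed) and the pass is idempotent.
The automatic threshold is `max(2, ⌈fraction · mean molecule frequency⌉)`
with fraction defaulting to 0.05, inside the 3–10 % band of average coverage
that works for typical depth; the floor of 2 keeps the rule meaningful at
low depth. Both thresholds default to the same value.

## Contig extension

Reduction stalls at four structure classes, each with a heuristic:

- **Self-loops** (including self-twin palindromic junctions) merge with
  their highest-coverage direction-compatible neighbor, waiving the degree
  condition, or are deleted when no neighbor fits.
- **Tips** — edges with exactly one degree-1 endpoint and label shorter than
  `tip_max_label` (default k) — are deleted; an isolated edge is a finished
  contig, never a tip. Tip length is the label length (step count), the
  conservative reading for merged spurs.
- **Parallel edges** (same endpoints and endpoint orientations) keep only
  the highest coverage; ties keep the smaller canonical label.
- **Cross vertices** (≥ 2 attachments per side) sort each side by coverage
  and pair rank for rank; a pair with relative coverage difference
  `|c₁−c₂|/max(c₁,c₂)` below the tolerance (default 0.20) merges through a
  cloned center. **Virtual crosses** treat an edge e0 with ≥ 2 outer edges
  at each endpoint the same way, pairing across e0 and removing e0 only when
  every outer edge was consumed. Greedy rank pairing is used because
  coverage sorting alone does not define a pairing; each edge is used once.

The assembly loop repeats
`[self-loops → parallel edges → cross → virtual cross → reduce → tips]`
until a full pass changes nothing (counted rounds exclude the final no-op
pass) or `max_rounds` (default 16) is hit, in which case a final reduction
still runs. The ordering is deliberate: a self-loop doubles its anchor's
degree and hides the unanimous continuation, so loops are opened before
anything else; tip removal runs *after* reduction so that genuine terminal
arms exposed by a resolved junction are merged into their long chain before
the spur test sees them — otherwise a real 2-step terminal arm hanging off a
palindromic junction (exactly the situation in the 9 bp worked example) is
destroyed as a "tip" and the reference cannot be recovered.

Contigs are one record per remaining edge: the oriented source k-mer plus
the label, canonicalized to the larger strand, filtered by a minimum length
(CLI default 2k−1, the shortest length that proves two overlapping k-mers),
and ordered by length then sequence. The full spelled sequence is emitted
rather than the bare label: the label alone drops the leading k bases of
the path, and only the spelled form satisfies "reads map back to contigs".

## Synthetic data

The simulator provides i.i.d. random genomes; *repeat-free* genomes whose
canonical (k−1)-mers are all distinct (built by seeded randomized extension
with backtracking), so the graph is a single unanimous path and error-free
reads must assemble to exactly one contig; deterministic tilings; uniform
position sampling at a target depth with strand flipping; and i.i.d.
substitution errors that never reproduce the original base. Substitutions
are the only error model because graph cleaning targets low-frequency
k-mers, which substitutions produce; indels would add nothing the assembler
distinguishes. The generators do not model coverage waviness, quality-value
correlation, or real repeat structure, so passing round-trip tests
demonstrates correctness of the graph machinery, not performance on real
libraries.

## Problem sizes and numerics

Tests run at desk scale chosen to finish in seconds while still crossing
the interesting regimes: round-trip recovery uses a 10 kb repeat-free genome
at k=31 with tiled 100 bp reads; schedule-invariance sweeps 20 random
300 bp-genome graphs across scheduler modes, seeds, and partition counts;
the halving bound covers path lengths 2–256; associativity checks 10³
consecutive triples. Coverage values are IEEE doubles; equality assertions
on coverage use relative tolerances, while keys, labels, orientations and
sequences are compared exactly. Graph dumps print coverage with 6
significant digits, which is lossless for the integer-valued coverages
produced by construction and stable for weighted means at test scale.

## Known limitations

- Single-process only; partitions are logical. No claim about wall-clock
  scalability is made or tested.
- Cross/virtual-cross pairing can chimerize genuine repeats when coverages
  coincide within tolerance; this is the accepted cost of longer contigs.
- Coverage thresholds assume roughly uniform depth; heavily biased
  libraries need explicit thresholds.
- No bubble popping, scaffolding, or paired-end constraints.
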