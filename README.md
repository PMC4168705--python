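# msgasm

A genome assembler for short reads built on a **multi-step bi-directed de
Bruijn graph**, with an associative edge-merging operation scheduled in
conflict-free rounds and coverage-guided contig extension. It is written for
people who want an assembler whose every stage — graph construction,
cleaning, reduction, extension — is a small, separately testable library
function, and whose parallel merge schedule can be reasoned about (and
asserted on) mathematically.

## The model in brief

Vertices are *k-molecules*: unordered pairs {α, revcomp(α)} of odd-length
k-mers, represented by the lexicographically larger member α⁺. An edge

    e = (α̂, β̂, d_α, d_β, c),   suffix_k(oriented(α̂, d_α) ∘ c) = oriented(β̂, d_β)

carries an orientation at each endpoint and a label c; each edge has an
equivalent twin representation from the other endpoint, stored once. Two
edges meeting at a degree-2 molecule with matching traversal orientation
merge:

    e_αβ ⊗ e_βγ = e_αγ,   c_αγ = c_αβ ∘ c_βγ

⊗ is associative (with an absorbing zero edge for incompatible operands), so
the fully merged edge set — the contigs — is independent of merge order.
That freedom is exploited by a round-synchronous scheduler: per round, a
maximal set of non-conflicting merges (disjoint *small worlds*: the two
edges plus the shared molecule) is applied at once, so a unanimous path of
E edges collapses in ⌈log₂ E⌉ rounds instead of E−1 sequential joins.
Low-frequency k-molecules and edges are cleaned as likely errors, and
junction heuristics (tips, self-loops, parallel edges, cross and virtual
cross vertices paired by coverage within a 20 % relative tolerance) extend
contigs past structures pure merging cannot cross. See `docs/methods.md`
for the full account.

## Worked example

Simulate a 10 kb repeat-free genome, tile error-free 100 bp reads across it,
and assemble at k = 31:

```sh
msgasm simulate --genome-length 10000 -k 31 --repeat-free \
    --read-length 100 --tile-step 50 --seed 7 -o reads.fa
# wrote 199 reads of length 100 to reads.fa

msgasm assemble -i reads.fa -k 31 --threshold 0 -o contigs.fa --stats stats.json
# 1 contigs, 10000 bases, N50 10000, max 10000
```

The single contig is the genome (up to strand; sequences are reported on
the lexicographically larger strand). `stats.json` records the stages:

```json
{
  "contig_count": 1,
  "total_bases": 10000,
  "n50": 10000,
  "molecules_before_clean": 9970,
  "edges_before_clean": 9969,
  "extension_rounds": 1,
  "schedule": {"rounds": 14, "operations_applied": 9968,
               "per_round_counts": [4984, 2492, 1246, "..."]}
}
```

9 969 one-step edges form one unanimous path; merging finishes in 14 rounds
(⌈log₂ 9969⌉ = 14), halving the mergeable edges each round — the schedule
the cost model predicts. With `--threshold auto` (the default) the cleaning
cutoff is derived from mean k-molecule coverage; `--scheduler randomized
--seed N` and `--partitions P` change only the schedule bookkeeping, never
the contigs.

A fully worked micro-example from the library instead of the CLI:

```python
>>> from msgasm import assemble
>>> contigs, stats = assemble(reads=["TAGTCG", "AGTCGA", "TCGAGG"],
...                           k=3, threshold=0, min_contig_len=3)
>>> contigs[0].sequence
'TAGTCGAGG'
```

Three 6 bp reads over a 9 bp reference reassemble it exactly, crossing a
palindromic junction (the self-twin edge spelled `TCGA`) on the way.

## Command reference

- `msgasm assemble -i reads.fa [-i more.fq.gz ...] -k 31 --threshold auto -o contigs.fa`
  — the five-step pipeline (read, construct, clean, reduce, extend); FASTA
  or FASTQ input, optionally gzipped; `--dump-graph PREFIX` writes the graph
  TSV after construction, cleaning and the final state; `--no-extension`
  stops after reduction.
- `msgasm simulate` — synthetic genomes (random or repeat-free) and reads
  (tiled or sampled, optional substitution errors).
- `msgasm stats contigs.fa` — contig count, total bases, max length, N50.
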