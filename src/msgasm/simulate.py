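"""Synthetic genomes and reads for exercising the assembler.

The generators emulate the statistical structure the assembler assumes:
uniform coverage, reads from both strands, and independent substitution
errors (the error type that produces the low-frequency k-mers graph
cleaning targets). Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .kmers import reverse_complement, validate_k

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Read-sampling settings. ``coverage`` is the expected sequencing depth;
    ``error_rate`` the per-base substitution probability; ``both_strands``
    flips each read to the reverse strand with probability 1/2."""

    genome_length: int = 10_000
    k: int = 31
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        validate_k(self.k)
        if self.read_length < self.k:
            raise ValueError("read_length must be >= k")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def random_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. random DNA string."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = random.Random(seed)
    return "".join(rng.choice(BASES) for _ in range(length))


class RepeatFreeError(RuntimeError):
    """Could not generate a repeat-free genome at the requested length/k."""


def repeat_free_genome(length: int, k: int, seed: int, max_restarts: int = 20) -> str:
    """A genome whose canonical (k-1)-mers are all distinct (reverse
    complement collisions count), so its de Bruijn graph is a single
    unanimous path and error-free reads assemble back to one contig.

    Built by seeded randomized extension with backtracking; raises
    :class:`RepeatFreeError` when the length is infeasible for this k.
    """
    validate_k(k)
    w = k - 1
    if length < w:
        raise ValueError(f"length must be >= k-1 = {w}")
    if length - w + 1 > 4 ** w / 2:
        raise RepeatFreeError(
            f"length {length} cannot host distinct canonical {w}-mers"
        )
    rng = random.Random(seed)
    for _ in range(max_restarts):
        seq: list[str] = [rng.choice(BASES) for _ in range(w)]
        first = "".join(seq)
        seen = {max(first, reverse_complement(first))}
        stuck = 0
        while len(seq) < length:
            tail = "".join(seq[-(w - 1):]) if w > 1 else ""
            options = rng.sample(BASES, 4)
            for base in options:
                cand = tail + base
                canon = max(cand, reverse_complement(cand))
                if canon not in seen:
                    seen.add(canon)
                    seq.append(base)
                    break
            else:
                # dead end: back off a few bases and retry
                back = min(len(seq) - w, w)
                if back <= 0:
                    break
                for _ in range(back):
                    last = "".join(seq[-w:])
                    seen.discard(max(last, reverse_complement(last)))
                    seq.pop()
                stuck += 1
                if stuck > 100:
                    break
        if len(seq) == length:
            return "".join(seq)
    raise RepeatFreeError(
        f"failed to build a repeat-free genome of length {length} at k={k}"
    )


def tile_reads(genome: str, read_length: int, step: int) -> list[str]:
    """Windows at offsets 0, step, 2*step, ... plus a final window flush with
    the genome end (so every base is covered)."""
    if read_length > len(genome):
        raise ValueError("read_length must be <= genome length")
    if step < 1:
        raise ValueError("step must be >= 1")
    last = len(genome) - read_length
    offsets = list(range(0, last + 1, step))
    if offsets[-1] != last:
        offsets.append(last)
    return [genome[o : o + read_length] for o in offsets]


def sample_reads(genome: str, cfg: SimConfig) -> list[str]:
    """ceil(coverage * |genome| / read_length) reads at seeded uniform
    positions, each flipped to the reverse strand with probability 1/2 when
    ``both_strands``. Substitution errors are applied separately by
    :func:`inject_errors`."""
    rng = random.Random(cfg.seed)
    n_reads = math.ceil(cfg.coverage * len(genome) / cfg.read_length)
    last = len(genome) - cfg.read_length
    if last < 0:
        raise ValueError("genome shorter than read_length")
    reads = []
    for _ in range(n_reads):
        pos = rng.randint(0, last)
        read = genome[pos : pos + cfg.read_length]
        if cfg.both_strands and rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append(read)
    if cfg.error_rate > 0:
        reads = inject_errors(reads, cfg.error_rate, cfg.seed + 1)
    return reads


def inject_errors(reads: list[str], rate: float, seed: int) -> list[str]:
    """Apply i.i.d. substitutions: each base independently replaced, with
    probability ``rate``, by a uniformly random *different* base."""
    rng = random.Random(seed)
    out = []
    for read in reads:
        chars = list(read)
        for i, base in enumerate(chars):
            if rng.random() < rate:
                chars[i] = rng.choice([b for b in BASES if b != base])
        out.append("".join(chars))
    return out


def write_fasta(path, sequences: list[str], prefix: str = "read") -> None:
    """Plain FASTA, 80-column wrapped."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}_{i + 1}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")


def write_fastq(path, sequences: list[str], prefix: str = "read") -> None:
    """FASTQ with constant quality 'I' (qualities are ignored downstream)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f"@{prefix}_{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
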