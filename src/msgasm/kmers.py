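"""Sequence primitives: reverse complement, canonical k-mers, k-molecule spectra.

A *k-molecule* is the unordered pair {kmer, reverse_complement(kmer)}; it is the
vertex of the assembly graph. Its representative is the lexicographically
*larger* member of the pair under plain byte order (A < C < G < T), called the
positive k-mer; the smaller one is the negative k-mer. k is required to be odd,
which guarantees no k-mer equals its own reverse complement, so the +/- split
is always well defined.
"""

from __future__ import annotations

from typing import Iterator

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PLUS = "+"
MINUS = "-"


class AmbiguousBaseError(ValueError):
    """A graph-side string contained a character outside {A,C,G,T}."""


class InvalidKError(ValueError):
    """k failed validation (must be odd and >= 3)."""


def validate_k(k: int) -> int:
    if k < 3 or k % 2 == 0:
        raise InvalidKError(
            f"k must be an odd integer >= 3 (palindromic k-mers are only "
            f"excluded for odd k); got {k}"
        )
    return k


def negate(orientation: str) -> str:
    """Flip an orientation sign: + <-> -."""
    if orientation == PLUS:
        return MINUS
    if orientation == MINUS:
        return PLUS
    raise ValueError(f"invalid orientation {orientation!r}")


def reverse_complement(s: str) -> str:
    """Reverse ``s`` and complement every base (A<->T, C<->G).

    Raises :class:`AmbiguousBaseError` for any character outside {A,C,G,T}.
    """
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AmbiguousBaseError(f"non-ACGT characters {bad} in {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


def representative(kmer: str) -> tuple[str, str]:
    """Canonicalize a k-mer to its k-molecule key.

    Returns ``(key, orientation)`` where ``key`` is the lexicographically
    larger of ``kmer`` and its reverse complement (the positive k-mer) and
    ``orientation`` is ``'+'`` iff ``kmer`` equals the key.
    """
    validate_k(len(kmer))
    rc = reverse_complement(kmer)
    if kmer > rc:
        return kmer, PLUS
    if kmer < rc:
        return rc, MINUS
    raise InvalidKError(f"palindromic k-mer {kmer!r} (is k even?)")


def oriented(key: str, orientation: str) -> str:
    """The k-mer obtained by reading molecule ``key`` in ``orientation``."""
    if orientation == PLUS:
        return key
    if orientation == MINUS:
        return reverse_complement(key)
    raise ValueError(f"invalid orientation {orientation!r}")


def _clean_segments(s: str) -> Iterator[str]:
    """Split a read at non-ACGT characters into pure-ACGT segments."""
    start = None
    for i, base in enumerate(s):
        if base in DNA_ALPHABET:
            if start is None:
                start = i
        else:
            if start is not None:
                yield s[start:i]
                start = None
    if start is not None:
        yield s[start:]


def kmer_list(s: str, k: int) -> list[str]:
    """All length-k windows of ``s`` in order.

    Windows containing a non-ACGT character are skipped (the read is
    effectively split at ambiguous bases). A read shorter than k yields an
    empty list.
    """
    validate_k(k)
    out: list[str] = []
    for seg in _clean_segments(s):
        out.extend(seg[i : i + k] for i in range(len(seg) - k + 1))
    return out


def spectrum(s: str, k: int) -> set[str]:
    """The k-molecule set of ``s``: canonical keys of every k-window.

    Strand-symmetric: ``spectrum(s, k) == spectrum(reverse_complement(s), k)``.
    """
    return {representative(w)[0] for w in kmer_list(s, k)}
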