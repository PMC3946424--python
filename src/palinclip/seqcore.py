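"""Core sequence primitives for terminal-palindrome artifact analysis.

Reads from degraded (historic/ancient) DNA libraries can carry an
*interrupted palindrome*: the last ``L`` bases of a read are the perfect
reverse complement of its first ``L`` bases, with unrelated sequence in
between.  The 5'-proximal copy is genomic; the 3'-terminal section is an
artificial fill-in produced during library preparation, so the artifact is
removed by clipping the 3' end only.

This module provides the alphabet-level primitives: reverse complement,
terminal-palindrome detection and clipping, GC content, melting temperature,
a dinucleotide-repeat metric and a sequence-identity duplicate fraction.
Only the five-letter alphabet {A, C, G, T, N} is accepted; ``N`` is never
considered complementary to anything, so low-quality bases cannot inflate
artifact calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "NucleotideRead",
    "PalindromeCall",
    "reverse_complement",
    "terminal_palindrome_length",
    "clip_palindrome",
    "gc_content",
    "melting_temperature",
    "dinucleotide_repeat_span",
    "duplicate_fraction",
]

_ALPHABET = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
# Watson-Crick partner of each base; N pairs with nothing.
_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _check_dna(seq: str) -> None:
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"sequence contains non-DNA characters: {bad!r}")


@dataclass
class NucleotideRead:
    """A single sequencing read.

    Parameters
    ----------
    id : str
        Read identifier.
    sequence : str
        DNA string over ``{A, C, G, T, N}``; lower case is upper-cased on
        ingestion.
    qualities : list of int, optional
        Phred quality scores, one per base.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        _check_dna(self.sequence)
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PalindromeCall:
    """Detector result for one read.

    ``palindrome_length`` is the maximal ``L`` such that the 3'-terminal
    ``L`` bases are the reverse complement of the 5'-initial ``L`` bases
    (capped at half the read length so the two sections stay disjoint).
    ``residual`` flags reads whose re-detected length after a single-pass
    clip is still at or above the clip threshold.
    """

    read_id: str
    read_length: int
    palindrome_length: int
    clipped: bool
    clip_length: int
    residual: bool = False


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``.

    Raises ``ValueError`` on characters outside ``{A, C, G, T, N}``.
    """
    _check_dna(seq)
    return seq.translate(_RC_TABLE)[::-1]


def terminal_palindrome_length(seq: str) -> int:
    """Length of the terminal interrupted palindrome of ``seq``.

    Returns the largest ``L <= len(seq) // 2`` such that the last ``L``
    bases equal the reverse complement of the first ``L`` bases.  By the
    nested-match property this equals the number of consecutive end pairs
    ``(seq[t], seq[n-1-t])`` that are Watson-Crick complementary, counting
    from ``t = 0``.  ``N`` never counts as complementary.
    """
    n = len(seq)
    half = n // 2
    pair = _PAIR
    t = 0
    while t < half and pair.get(seq[t]) == seq[n - 1 - t]:
        t += 1
    return t


def clip_palindrome(
    read: NucleotideRead, min_clip: int = 4
) -> tuple[NucleotideRead, PalindromeCall]:
    """Single-pass 3'-end clip of the terminal palindrome.

    If the detected palindrome length ``L`` is at least ``min_clip``, the
    last ``L`` bases (and their qualities) are removed; the 5' end is never
    touched.  Otherwise the read is returned unchanged.  The returned
    :class:`PalindromeCall` records the decision; its ``residual`` flag is
    set when the clipped read still carries a palindrome of at least
    ``min_clip`` bases (clipping is deliberately not iterated).
    """
    if min_clip < 1:
        raise ValueError("min_clip must be >= 1")
    n = len(read.sequence)
    L = terminal_palindrome_length(read.sequence)
    if L >= min_clip:
        new_seq = read.sequence[: n - L]
        new_qual = read.qualities[: n - L] if read.qualities is not None else None
        out = NucleotideRead(read.id, new_seq, new_qual)
        residual = terminal_palindrome_length(new_seq) >= min_clip
        call = PalindromeCall(read.id, n, L, True, L, residual)
        return out, call
    return read, PalindromeCall(read.id, n, L, False, 0, False)


def gc_content(seq: str) -> float:
    """Fraction of G/C bases; ``N`` counts in the denominator."""
    if len(seq) == 0:
        raise ValueError("gc_content of an empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Salt-unadjusted melting temperature (degrees C).

    For sequences longer than 13 bases this is the length/GC formula

        Tm = 64.9 + 41 * (nGC - 16.4) / n

    with ``nGC`` the number of G or C bases and ``n`` the length.  For 13
    bases or fewer the Wallace rule ``2*(A+T) + 4*(G+C)`` is used instead
    and a warning is emitted, since the long-sequence formula is not meant
    for oligos that short.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("melting temperature of an empty sequence is undefined")
    ngc = seq.count("G") + seq.count("C")
    if n > 13:
        return 64.9 + 41.0 * (ngc - 16.4) / n
    warnings.warn(
        f"sequence of length {n} <= 13: using the Wallace rule",
        stacklevel=2,
    )
    return wallace_tm(seq)


def wallace_tm(seq: str) -> float:
    """Wallace-rule Tm for short duplexes: ``2*(A+T) + 4*(G+C)``."""
    ngc = seq.count("G") + seq.count("C")
    nat = seq.count("A") + seq.count("T")
    return 2.0 * nat + 4.0 * ngc


def dinucleotide_repeat_span(seq: str) -> int:
    """Length (bases) of the longest tandem run of a two-base motif.

    Only motifs whose two bases differ count (homopolymers are excluded),
    and only complete copies contribute, so a run needs at least two copies
    (four bases) to score; anything shorter reports 0.
    """
    n = len(seq)
    best = 0
    i = 0
    while i < n - 3:
        a, b = seq[i], seq[i + 1]
        if a == b or "N" in (a, b):
            i += 1
            continue
        j = i + 2
        while j < n and seq[j] == seq[i + (j - i) % 2]:
            j += 1
        span = 2 * ((j - i) // 2)
        if span >= 4 and span > best:
            best = span
        # restart after the first period of the run; overlapping runs with a
        # different phase cannot be longer.
        i += max(1, (j - i) - 1)
    return best


def duplicate_fraction(reads: Iterable[NucleotideRead | str]) -> float:
    """Fraction of reads that are sequence-identical copies of another read.

    Computed as ``(total - distinct) / total`` over full-sequence identity;
    this is a reproducible surrogate for alignment-based duplicate marking
    and needs no reference genome.
    """
    seqs = [r.sequence if isinstance(r, NucleotideRead) else r for r in reads]
    if not seqs:
        raise ValueError("duplicate_fraction of an empty collection is undefined")
    return (len(seqs) - len(set(seqs))) / len(seqs)
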