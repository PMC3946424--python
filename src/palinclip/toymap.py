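"""Minimal exhaustive read mapper for synthetic genomes.

A deliberately simple, ungapped stand-in for a short-read aligner: every
placement of a read on both strands of a (small) genome is scored by
mismatch count, and a read is mapped only when the best placement is unique
at its mismatch count and its mismatch fraction does not exceed a
threshold (default 0.03, i.e. at most 3% of bases).  Uniqueness stands in
for a mapping-quality cutoff.  This is enough to measure how much terminal
artifact clipping improves alignability, and to profile substitution
classes along read positions, on simulated data — it is not meant for real
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqcore import NucleotideRead, reverse_complement

__all__ = [
    "ToyAlignment",
    "GenomeIndex",
    "map_read",
    "map_reads",
    "alignability",
    "positional_mismatch_profile",
]


@dataclass
class ToyAlignment:
    """Result of placing one read on the genome."""

    read_id: str
    mapped: bool
    pos: int = -1
    strand: str = "+"
    mismatches: int = -1
    mismatch_positions: list[int] = field(default_factory=list)


class GenomeIndex:
    """Byte-encoded genome with cached sliding windows per read length."""

    def __init__(self, sequence: str):
        self.sequence = sequence.upper()
        self.arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
        self._windows: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.sequence)

    def windows(self, length: int) -> np.ndarray:
        win = self._windows.get(length)
        if win is None:
            win = np.lib.stride_tricks.sliding_window_view(self.arr, length)
            self._windows[length] = win
        return win


def _as_index(genome) -> GenomeIndex:
    if isinstance(genome, GenomeIndex):
        return genome
    if hasattr(genome, "sequence"):  # SyntheticGenome
        return GenomeIndex(genome.sequence)
    return GenomeIndex(genome)


def map_read(
    read: NucleotideRead,
    genome: Union[str, GenomeIndex],
    max_mismatch_frac: float = 0.03,
) -> ToyAlignment:
    """Best ungapped placement of ``read`` over both genome strands.

    Placements are ranked by mismatch count; among equals the leftmost
    position wins with the forward strand preferred.  The read is
    ``mapped`` only if the best mismatch count is achieved by exactly one
    placement (either strand) and ``mismatches / len(read) <=
    max_mismatch_frac``.  Reads longer than the genome are unmapped.
    """
    idx = _as_index(genome)
    L = len(read.sequence)
    if L == 0 or L > len(idx):
        return ToyAlignment(read.id, False)
    win = idx.windows(L)
    fwd = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
    rev = np.frombuffer(
        reverse_complement(read.sequence).encode("ascii"), dtype=np.uint8
    )
    mm_f = np.count_nonzero(win != fwd, axis=1)
    mm_r = np.count_nonzero(win != rev, axis=1)
    best = int(min(mm_f.min(), mm_r.min()))
    n_best = int(np.count_nonzero(mm_f == best) + np.count_nonzero(mm_r == best))
    if (mm_f == best).any():
        pos = int(np.argmax(mm_f == best))
        strand = "+"
        window_mism = np.nonzero(win[pos] != fwd)[0]
        positions = [int(o) for o in window_mism]
    else:
        pos = int(np.argmax(mm_r == best))
        strand = "-"
        window_mism = np.nonzero(win[pos] != rev)[0]
        # window offsets -> read offsets on the minus strand
        positions = sorted(int(L - 1 - o) for o in window_mism)
    mapped = n_best == 1 and best <= max_mismatch_frac * L
    return ToyAlignment(read.id, mapped, pos, strand, best, positions)


def map_reads(
    reads: Iterable[NucleotideRead],
    genome: Union[str, GenomeIndex],
    max_mismatch_frac: float = 0.03,
) -> list[ToyAlignment]:
    idx = _as_index(genome)
    return [map_read(r, idx, max_mismatch_frac) for r in reads]


def alignability(
    reads: Sequence[NucleotideRead],
    genome: Union[str, GenomeIndex],
    max_mismatch_frac: float = 0.03,
    untrimmed_pair_count: Optional[int] = None,
) -> dict:
    """Fraction of reads that map, under both denominators.

    Returns a dict with the mapped count, the fraction of the reads given
    (collapsed-read denominator) and — when ``untrimmed_pair_count`` is
    supplied — the fraction relative to the untrimmed pair count.
    """
    if len(reads) == 0:
        raise ValueError("alignability of an empty read set is undefined")
    alns = map_reads(reads, genome, max_mismatch_frac)
    mapped = sum(a.mapped for a in alns)
    out = {
        "mapped": mapped,
        "n_reads": len(reads),
        "fraction_of_reads": mapped / len(reads),
    }
    if untrimmed_pair_count:
        out["fraction_of_untrimmed_pairs"] = mapped / untrimmed_pair_count
    return out


def positional_mismatch_profile(
    alignments: Sequence[ToyAlignment],
    reads: Union[Sequence[NucleotideRead], Mapping[str, NucleotideRead]],
    genome: Union[str, GenomeIndex],
    max_offset: int = 25,
) -> pd.DataFrame:
    """Per-position substitution rates near read ends, read versus genome.

    For 5' offsets ``1..max_offset`` and 3' offsets ``-max_offset..-1`` the
    rate of each substitution class (``C>T``, ``G>A``, ``other``) among
    aligned bases is computed, with the reference oriented to the read so
    that classes refer to read coordinates.  Only mapped alignments
    contribute.  Returns a tidy frame with columns ``end``, ``offset``,
    ``substitution``, ``count``, ``total``, ``rate``.
    """
    idx = _as_index(genome)
    if isinstance(reads, Mapping):
        by_id = reads
    else:
        by_id = {r.id: r for r in reads}

    classes = ("C>T", "G>A", "other")
    counts: dict[tuple[str, int, str], int] = {}
    totals: dict[tuple[str, int], int] = {}

    for aln in alignments:
        if not aln.mapped:
            continue
        read = by_id[aln.read_id]
        L = len(read.sequence)
        ref = idx.sequence[aln.pos : aln.pos + L]
        if aln.strand == "-":
            ref = reverse_complement(ref)
        for k in range(1, max_offset + 1):
            if k > L:
                break
            for end, ri in (("5p", k - 1), ("3p", L - k)):
                off = k if end == "5p" else -k
                totals[(end, off)] = totals.get((end, off), 0) + 1
                rb, qb = ref[ri], read.sequence[ri]
                if rb != qb:
                    if rb == "C" and qb == "T":
                        cls = "C>T"
                    elif rb == "G" and qb == "A":
                        cls = "G>A"
                    else:
                        cls = "other"
                    key = (end, off, cls)
                    counts[key] = counts.get(key, 0) + 1

    rows = []
    for (end, off), total in sorted(totals.items()):
        for cls in classes:
            c = counts.get((end, off, cls), 0)
            rows.append(
                {
                    "end": end,
                    "offset": off,
                    "substitution": cls,
                    "count": c,
                    "total": total,
                    "rate": c / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["end", "offset", "substitution", "count", "total", "rate"])
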