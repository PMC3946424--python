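"""Adapter trimming and paired-end overlap collapsing.

Short degraded fragments are usually shorter than the read length, so the
forward and reverse mates overlap and can be merged ("collapsed") into a
single full-length fragment sequence.  This module re-implements the
behaviours the artifact analysis depends on — adapter-tail removal, N
trimming, overlap search, quality-aware merging and a minimum-length
filter — as a functional equivalent of the classic collapse workflow, with
deterministic tie-breaking.  Only collapsed reads are used downstream,
mirroring the analysis this package supports.

Defaults: minimum overlap 11 bases, mismatch rate at most 0.33 within the
overlap, collapsed reads shorter than 25 bases discarded, N-ends trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seqcore import NucleotideRead, reverse_complement

__all__ = ["ReadPair", "CollapseParams", "trim_adapter", "collapse_pair"]


@dataclass
class ReadPair:
    """A forward/reverse mate pair (both non-empty)."""

    forward: NucleotideRead
    reverse: NucleotideRead

    def __post_init__(self) -> None:
        if len(self.forward) == 0 or len(self.reverse) == 0:
            raise ValueError("both mates of a pair must be non-empty")


@dataclass
class CollapseParams:
    """Collapse settings (defaults mirror the historic-DNA workflow)."""

    min_overlap: int = 11
    max_mismatch_rate: float = 0.33
    min_length: int = 25
    trim_ns: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.max_mismatch_rate < 1.0):
            raise ValueError("max_mismatch_rate must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def trim_adapter(
    read: NucleotideRead,
    adapter: str,
    max_mismatch_rate: float = 0.33,
    min_overlap: int = 3,
    trim_ns: bool = True,
) -> NucleotideRead:
    """Remove a 3' adapter tail (and optionally terminal N runs).

    The longest read suffix that aligns to a prefix of ``adapter`` with a
    per-base mismatch rate at most ``max_mismatch_rate`` is removed; ties go
    to the longer trim.  Alignments shorter than ``min_overlap`` bases are
    ignored so that chance one- or two-base suffix matches do not nibble
    reads carrying no adapter.  If nothing qualifies the read is returned
    unchanged (apart from N trimming when ``trim_ns`` is on).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    quals = read.qualities
    n = len(seq)
    arr = _encode(seq)
    ad = _encode(adapter.upper())
    cut = n
    for p in range(n):  # p = read position where the adapter starts
        ov = min(n - p, len(ad))
        if ov < min_overlap:
            break
        mm = int(np.count_nonzero(arr[p : p + ov] != ad[:ov]))
        if mm <= max_mismatch_rate * ov:
            cut = p
            break  # smallest p == longest trim
    seq = seq[:cut]
    if quals is not None:
        quals = quals[:cut]
    if trim_ns:
        start = 0
        end = len(seq)
        while start < end and seq[start] == "N":
            start += 1
        while end > start and seq[end - 1] == "N":
            end -= 1
        seq = seq[start:end]
        if quals is not None:
            quals = quals[start:end]
    return NucleotideRead(read.id, seq, quals)


def collapse_pair(
    pair: ReadPair, params: CollapseParams | None = None
) -> Optional[NucleotideRead]:
    """Merge an (adapter-trimmed) mate pair into one collapsed read.

    The reverse complement of the reverse mate is slid against the forward
    mate over every offset whose overlap is at least ``min_overlap``; the
    candidate with the fewest mismatches wins, ties going to the longer
    overlap.  The pair is collapsed only if the winning overlap's mismatch
    fraction is at most ``max_mismatch_rate``.  Within the overlap a
    disagreement takes the base with the higher quality (forward on ties);
    the merged quality at every position is the best available contributing
    score.  Returns ``None`` ("not collapsible") on rejection or when the
    merged read is shorter than ``min_length``.
    """
    if params is None:
        params = CollapseParams()
    f = pair.forward.sequence
    r = reverse_complement(pair.reverse.sequence)
    fq = pair.forward.qualities
    rq = pair.reverse.qualities[::-1] if pair.reverse.qualities is not None else None
    nf, nr = len(f), len(r)
    fa, ra = _encode(f), _encode(r)

    best: tuple[int, int, int] | None = None  # (mismatches, -overlap, offset)
    for off in range(-(nr - 1), nf):
        lo = max(0, off)
        hi = min(nf, off + nr)
        ov = hi - lo
        if ov < params.min_overlap:
            continue
        mm = int(np.count_nonzero(fa[lo:hi] != ra[lo - off : hi - off]))
        cand = (mm, -ov, off)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    mm, neg_ov, off = best
    ov = -neg_ov
    if mm > params.max_mismatch_rate * ov:
        return None

    out_seq: list[str] = []
    out_qual: list[int] = []

    def fqual(i: int) -> int:
        return fq[i] if fq is not None else 0

    def rqual(i: int) -> int:
        return rq[i] if rq is not None else 0

    # In proper paired geometry the forward read starts at the insert's 5'
    # end and the reverse read starts at its 3' end, so the insert spans
    # [0, off + nr) in forward coordinates.  Anything outside that span
    # (reverse bases left of the forward start, forward bases right of the
    # reverse end) is adapter read-through and is dropped.
    start = 0
    end = off + nr
    for pos in range(start, end):
        in_f = 0 <= pos < nf
        in_r = off <= pos < off + nr
        if in_f and in_r:
            bf, br = f[pos], r[pos - off]
            qf, qr = fqual(pos), rqual(pos - off)
            if bf == br:
                out_seq.append(bf)
            else:
                out_seq.append(bf if qf >= qr else br)
            out_qual.append(max(qf, qr))
        elif in_f:
            out_seq.append(f[pos])
            out_qual.append(fqual(pos))
        else:
            out_seq.append(r[pos - off])
            out_qual.append(rqual(pos - off))

    merged = "".join(out_seq)
    if len(merged) < params.min_length:
        return None
    quals = out_qual if (fq is not None or rq is not None) else None
    return NucleotideRead(pair.forward.id, merged, quals)
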