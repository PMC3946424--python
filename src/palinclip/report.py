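"""Library-level summaries and subsampling.

Aggregates per-read detector results into the per-library quantities the
artifact analysis reports: palindrome content (percentage of collapsed
reads whose terminal palindrome exceeds three bases), length/GC/Tm
statistics stratified by palindrome status, the palindrome-length
histogram, and duplicate fractions per stratum.  Also provides seeded
reservoir subsampling of reads or read pairs.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence, TypeVar

import numpy as np

from .seqcore import (
    NucleotideRead,
    duplicate_fraction,
    gc_content,
    melting_temperature,
    terminal_palindrome_length,
)

__all__ = [
    "LibrarySummary",
    "palindrome_content",
    "subsample",
    "subsample_pairs",
    "summarize_library",
]

T = TypeVar("T")


@dataclass
class LibrarySummary:
    """Per-library report.

    Strata are keyed ``"palindromic"`` (palindrome length above the report
    threshold minus one, i.e. L > 3 at the default) versus ``"clean"``.
    Stratified means are ``None`` when a stratum is empty.
    """

    library_id: str
    n_collapsed: int
    n_pairs_untrimmed: Optional[int]
    pct_collapsed: Optional[float]
    mean_length: float
    gc_pct: float
    palindrome_content_pct: float
    palindrome_length_histogram: dict[int, int]
    mean_length_by_status: dict[str, Optional[float]]
    mean_gc_by_status: dict[str, Optional[float]]
    mean_tm_by_status: dict[str, Optional[float]]
    duplicate_fraction_by_status: dict[str, Optional[float]]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["palindrome_length_histogram"] = {
            str(k): v for k, v in sorted(self.palindrome_length_histogram.items())
        }
        return d


def palindrome_content(
    reads: Sequence[NucleotideRead | str], min_report_len: int = 4
) -> float:
    """Percentage of reads with a terminal palindrome of at least
    ``min_report_len`` bases (default 4, i.e. "longer than three")."""
    if len(reads) == 0:
        raise ValueError("palindrome_content of an empty read set is undefined")
    hits = 0
    for r in reads:
        seq = r.sequence if isinstance(r, NucleotideRead) else r
        if terminal_palindrome_length(seq) >= min_report_len:
            hits += 1
    return 100.0 * hits / len(reads)


def subsample(items: Sequence[T], n: int, seed: int = 0) -> list[T]:
    """Uniform sample of ``n`` items without replacement (reservoir).

    If fewer than ``n`` items are available, all of them are returned.
    Reproducible under ``seed``; output preserves input order.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir_idx: list[int] = []
    for i, _ in enumerate(items):
        if i < n:
            reservoir_idx.append(i)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir_idx[j] = i
    return [items[i] for i in sorted(reservoir_idx)]


def subsample_pairs(
    pairs: Sequence[tuple[T, T]], n: int, seed: int = 0
) -> list[tuple[T, T]]:
    """Reservoir-sample read pairs jointly (mates stay together)."""
    return subsample(pairs, n, seed)


def _mean(values: list[float]) -> Optional[float]:
    return statistics.fmean(values) if values else None


def summarize_library(
    collapsed_reads: Sequence[NucleotideRead],
    untrimmed_pair_count: Optional[int] = None,
    library_id: str = "library",
    min_report_len: int = 4,
) -> LibrarySummary:
    """Compute the full per-library report from collapsed reads.

    GC, length and Tm are computed on the unclipped collapsed reads; every
    statistic is also stratified by palindrome status (L at or above
    ``min_report_len`` versus below).  The histogram counts reads per
    palindrome length L and sums to the collapsed-read count.
    """
    if len(collapsed_reads) == 0:
        raise ValueError("summarize_library needs at least one read")
    hist: dict[int, int] = {}
    strata: dict[str, list[NucleotideRead]] = {"palindromic": [], "clean": []}
    for r in collapsed_reads:
        L = terminal_palindrome_length(r.sequence)
        hist[L] = hist.get(L, 0) + 1
        strata["palindromic" if L >= min_report_len else "clean"].append(r)

    n = len(collapsed_reads)
    lengths = [len(r.sequence) for r in collapsed_reads]
    gcs = [gc_content(r.sequence) for r in collapsed_reads]

    def stratify(fn) -> dict[str, Optional[float]]:
        return {k: _mean([fn(r) for r in v]) for k, v in strata.items()}

    dup = {
        k: (duplicate_fraction(v) if v else None) for k, v in strata.items()
    }
    return LibrarySummary(
        library_id=library_id,
        n_collapsed=n,
        n_pairs_untrimmed=untrimmed_pair_count,
        pct_collapsed=(
            100.0 * n / untrimmed_pair_count if untrimmed_pair_count else None
        ),
        mean_length=statistics.fmean(lengths),
        gc_pct=100.0 * statistics.fmean(gcs),
        palindrome_content_pct=100.0 * len(strata["palindromic"]) / n,
        palindrome_length_histogram=hist,
        mean_length_by_status=stratify(lambda r: float(len(r.sequence))),
        mean_gc_by_status=stratify(lambda r: gc_content(r.sequence)),
        mean_tm_by_status=stratify(lambda r: melting_temperature(r.sequence)),
        duplicate_fraction_by_status=dup,
    )
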