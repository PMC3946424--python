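"""Study-condition measurements: detector validation and simulator readouts.

Each function here sets up one of the package's benchmark experiments —
detector-versus-oracle agreement, the analytic chance background, mechanism
recovery against simulator truth, protocol scheme contrasts, alignment gain
from clipping, the palindrome/alignment-gain linearity sweep, read-property
stratification and the collapse round-trip — runs it from scratch under a
seed, and returns the measured numbers.  The tests assert the expected
bounds on these measurements; the acceptance script reports them.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .collapse import CollapseParams, ReadPair, collapse_pair
from .hairpinsim import blunt_like, find_hairpin, form_artifact, microplex_like, truseq_like
from .pipeline import simulate_library
from .report import palindrome_content
from .seqcore import (
    NucleotideRead,
    clip_palindrome,
    duplicate_fraction,
    melting_temperature,
    reverse_complement,
    terminal_palindrome_length,
)
from .toymap import GenomeIndex, map_reads

__all__ = [
    "brute_force_palindrome_length",
    "oracle_agreement",
    "background_palindrome_rate",
    "mechanism_recovery",
    "worked_example",
    "scheme_contrast",
    "alignment_gain",
    "linearity_sweep",
    "stratification",
    "collapse_roundtrip",
]


def brute_force_palindrome_length(seq: str) -> int:
    """Independent O(n^2) oracle: try every k from n//2 downward and compare
    the 3' suffix against the reverse complement of the 5' prefix directly."""
    n = len(seq)
    for k in range(n // 2, 0, -1):
        if seq[n - k :] == reverse_complement(seq[:k]):
            return k
    return 0


def _random_reads(rng: np.random.Generator, n: int, lengths) -> list[str]:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        rng.choice(alphabet, size=int(L)).tobytes().decode("ascii") for L in lengths
    ]


def oracle_agreement(seed: int, n_reads: int = 100_000) -> dict:
    """Fraction of random reads (lengths 2-200) on which the linear-scan
    detector and the brute-force oracle agree."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(2, 201, size=n_reads)
    agree = 0
    for seq in _random_reads(rng, n_reads, lengths):
        agree += terminal_palindrome_length(seq) == brute_force_palindrome_length(seq)
    return {"agreement_pct": 100.0 * agree / n_reads, "n": n_reads}


def background_palindrome_rate(
    seed: int, n_reads: int = 1_000_000, read_len: int = 70
) -> dict:
    """Chance rate of palindromes of at least 4 bases in i.i.d. uniform
    reads; the analytic value is (1/4)^4 = 0.390625%."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    block = rng.choice(alphabet, size=(n_reads, read_len))
    hits = 0
    for row in block:
        if terminal_palindrome_length(row.tobytes().decode("ascii")) >= 4:
            hits += 1
    p0 = 0.25**4
    half_ci = 2.5758 * math.sqrt(p0 * (1 - p0) / n_reads)
    return {
        "rate_pct": 100.0 * hits / n_reads,
        "analytic_pct": 100.0 * p0,
        "ci99_low_pct": 100.0 * (p0 - half_ci),
        "ci99_high_pct": 100.0 * (p0 + half_ci),
        "n": n_reads,
    }


def mechanism_recovery(
    seed: int, n_fragments: int = 10_000, genome_length: int = 10_000
) -> dict:
    """Detector L versus truth fill+stem on an error-free forked-adapter
    simulation over a uniform-composition genome."""
    sim = simulate_library(
        protocol=truseq_like(error_rate=0.0),
        n_fragments=n_fragments,
        genome_length=genome_length,
        gc_target=0.5,
        seed=seed,
    )
    n = exact = lower = 0
    for read in sim.collapsed:
        t = sim.truth_by_id.get(read.id)
        if t is None or not t.is_artifact:
            continue
        n += 1
        L = terminal_palindrome_length(read.sequence)
        exact += L == t.artifact_len
        lower += L >= t.artifact_len
    return {
        "exact_pct": 100.0 * exact / n,
        "lower_bound_pct": 100.0 * lower / n,
        "n": n,
    }


def worked_example() -> dict:
    """The canonical small hairpin: stem at (i=2, j=10, m=4) on a 14-mer."""
    strand = "TTACGAAAAATCGT"
    i, j, m = find_hairpin(strand, min_stem=4)
    product = form_artifact(strand, i, j, m)
    return {
        "strand": strand,
        "stem": (i, j, m),
        "product": product,
        "palindrome_length": terminal_palindrome_length(product),
    }


def scheme_contrast(seed: int, n_fragments: int = 10_000) -> dict:
    """Palindrome content of default libraries under the three adapter
    schemes, plus the mean palindrome length of the artifact mode."""
    out = {}
    lengths = []
    for name, proto in (
        ("forked_AT", truseq_like()),
        ("blunt", blunt_like()),
        ("stem_loop_blunt", microplex_like()),
    ):
        sim = simulate_library(protocol=proto, n_fragments=n_fragments, seed=seed)
        out[name] = {
            "palindrome_content_pct": palindrome_content(sim.collapsed),
            "n": len(sim.collapsed),
        }
        if name == "forked_AT":
            lengths = [
                L
                for L in (terminal_palindrome_length(r.sequence) for r in sim.collapsed)
                if L >= 4
            ]
    out["forked_AT"]["mean_palindrome_length"] = float(np.mean(lengths))
    return out


def _high_fill_protocol():
    """Forked protocol variant with denaturation forced on and a 5-base
    minimum stem, yielding near-total artifact content with long fill-ins
    (the regime where clipping has the largest alignment effect)."""
    return truseq_like(error_rate=0.0, min_stem=5, denature_midpoint_offset=-500.0)


def alignment_gain(seed: int, n_fragments: int = 4_000) -> dict:
    """Mapped-read count before/after clipping for a high-artifact forked
    library, and the same change for a default blunt library."""
    sim = simulate_library(
        protocol=_high_fill_protocol(),
        n_fragments=n_fragments,
        genome_length=10_000,
        seed=seed,
    )
    truths = sim.collapsed_truths
    arts = [t for t in truths if t.is_artifact]
    gi = GenomeIndex(sim.genome.sequence)
    pre = sum(a.mapped for a in map_reads(sim.collapsed, gi))
    clipped = [clip_palindrome(r)[0] for r in sim.collapsed]
    post = sum(a.mapped for a in map_reads(clipped, gi))

    simb = simulate_library(
        protocol=blunt_like(), n_fragments=n_fragments, genome_length=10_000, seed=seed
    )
    gib = GenomeIndex(simb.genome.sequence)
    pre_b = sum(a.mapped for a in map_reads(simb.collapsed, gib))
    post_b = sum(
        a.mapped
        for a in map_reads([clip_palindrome(r)[0] for r in simb.collapsed], gib)
    )
    return {
        "artifact_content_pct": 100.0 * len(arts) / len(truths),
        "mean_fill_len": float(np.mean([t.fill_len for t in arts])),
        "mapped_before": pre,
        "mapped_after": post,
        "gain_fold": post / pre if pre else math.inf,
        "blunt_mapped_before": pre_b,
        "blunt_mapped_after": post_b,
        "blunt_change_pct": 100.0 * abs(post_b - pre_b) / pre_b if pre_b else 0.0,
        "n": len(sim.collapsed),
    }


def linearity_sweep(
    seed: int, n_libraries: int = 8, n_fragments: int = 1_200
) -> dict:
    """Across libraries spanning hairpin rates from ~0 to ~80%+, correlate
    the number of palindrome-bearing reads with the gain in mapped reads
    after clipping (squared Pearson correlation)."""
    offsets = [40.0, 10.0, 6.0, 3.0, 0.0, -3.0, -8.0, -40.0][:n_libraries]
    xs, ys, rates = [], [], []
    for k, off in enumerate(offsets):
        proto = truseq_like(error_rate=0.0, denature_midpoint_offset=off)
        sim = simulate_library(
            protocol=proto,
            n_fragments=n_fragments,
            genome_length=10_000,
            seed=seed + k,
        )
        gi = GenomeIndex(sim.genome.sequence)
        n_pal = sum(
            terminal_palindrome_length(r.sequence) >= 4 for r in sim.collapsed
        )
        pre = sum(a.mapped for a in map_reads(sim.collapsed, gi))
        post = sum(
            a.mapped
            for a in map_reads([clip_palindrome(r)[0] for r in sim.collapsed], gi)
        )
        xs.append(n_pal)
        ys.append(post - pre)
        rates.append(100.0 * n_pal / len(sim.collapsed))
    r = np.corrcoef(xs, ys)[0, 1]
    return {
        "r_squared": float(r**2),
        "palindrome_counts": xs,
        "alignment_gains": ys,
        "palindrome_rates_pct": rates,
        "n_libraries": len(offsets),
    }


def stratification(seed: int, n_fragments: int = 12_000) -> dict:
    """Mean GC, mean Tm and duplicate fraction of artifact versus clean
    reads in the default Tm-coupled forked simulation."""
    sim = simulate_library(protocol=truseq_like(), n_fragments=n_fragments, seed=seed)
    art_reads, clean_reads = [], []
    for r in sim.collapsed:
        t = sim.truth_by_id.get(r.id)
        if t is None:
            continue
        (art_reads if t.is_artifact else clean_reads).append(r)
    def gc(r):
        return (r.sequence.count("G") + r.sequence.count("C")) / len(r.sequence)
    out = {
        "n_artifact": len(art_reads),
        "n_clean": len(clean_reads),
        "mean_gc_artifact_pct": 100.0 * float(np.mean([gc(r) for r in art_reads])),
        "mean_gc_clean_pct": 100.0 * float(np.mean([gc(r) for r in clean_reads])),
        "mean_tm_artifact_c": float(
            np.mean([melting_temperature(r.sequence) for r in art_reads])
        ),
        "mean_tm_clean_c": float(
            np.mean([melting_temperature(r.sequence) for r in clean_reads])
        ),
        "duplicate_fraction_artifact": duplicate_fraction(art_reads),
        "duplicate_fraction_clean": duplicate_fraction(clean_reads),
    }
    out["duplicate_enrichment_fold"] = (
        out["duplicate_fraction_artifact"] / out["duplicate_fraction_clean"]
        if out["duplicate_fraction_clean"]
        else math.inf
    )
    return out


def collapse_roundtrip(seed: int, n_pairs: int = 10_000) -> dict:
    """Error-free perfectly-trimmed pairs from fragments of length 25-189
    must reconstruct the fragment exactly; a 190-base fragment leaves a
    10-base best overlap and must be rejected."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    exact = 0
    for _ in range(n_pairs):
        n = int(rng.integers(25, 190))
        frag = rng.choice(alphabet, size=n).tobytes().decode("ascii")
        f = frag[:100]
        r = reverse_complement(frag)[:100]
        merged = collapse_pair(
            ReadPair(NucleotideRead("p", f), NucleotideRead("p", r))
        )
        exact += merged is not None and merged.sequence == frag
    frag190 = rng.choice(alphabet, size=190).tobytes().decode("ascii")
    rejected = (
        collapse_pair(
            ReadPair(
                NucleotideRead("p", frag190[:100]),
                NucleotideRead("p", reverse_complement(frag190)[:100]),
            )
        )
        is None
    )
    return {
        "exact_pct": 100.0 * exact / n_pairs,
        "overlap10_rejected": rejected,
        "n": n_pairs,
    }
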