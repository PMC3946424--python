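"""Generative simulator of hairpin-loop palindrome artifacts.

Mechanism being modelled
------------------------
Short double-stranded fragments from degraded samples denature easily.  A
single strand can fold back on itself wherever a short reverse-complement
("stem") pairs a 3'-proximal region with a 5'-proximal one, enclosing a
loop.  3'->5' exonucleases chew back any unannealed 3' tail beyond the
stem; polymerases then fill in the recessed 3' end using the 5' part of the
same strand as template.  The product carries, at its 3' end, an artificial
reverse-complement copy of its own 5' start — an *interrupted palindrome*
of length ``i + m`` (fill-in ``i`` plus genomic stem ``m``).  Forked
adapters (A-tailed, P5/P7) ligate onto the double-stranded stem and make
the construct amplifiable; blunt-end schemes do not, so the artifact is a
property of the library protocol, not of the sample alone.

The simulator draws fragments from a synthetic genome, decides denaturation
with a logistic function of the fragment melting temperature versus the
hottest pre-ligation step, searches each single strand for a foldable stem,
forms the artifact, applies a protocol-dependent amplifiability rule and a
length/GC-biased PCR duplication step, and finally emits paired reads with
substitution errors, adapter read-through and a truth record per molecule.

All randomness flows from the single seed given to each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqcore import (
    NucleotideRead,
    melting_temperature,
    reverse_complement,
    terminal_palindrome_length,
    wallace_tm,
)

__all__ = [
    "SyntheticGenome",
    "Fragment",
    "LibraryProtocol",
    "Molecule",
    "HairpinTruth",
    "generate_genome",
    "draw_fragments",
    "apply_deamination",
    "denature_probability",
    "find_hairpin",
    "form_artifact",
    "build_library",
    "sequence_library",
    "truseq_like",
    "blunt_like",
    "microplex_like",
    "DEFAULT_ADAPTER_R1",
    "DEFAULT_ADAPTER_R2",
]

# Standard Illumina adapter read-through sequences seen at the 3' end of
# R1/R2 when the insert is shorter than the read length.
DEFAULT_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_MIN_LOOP = 3  # steric minimum number of unpaired loop bases


@dataclass
class SyntheticGenome:
    """An i.i.d. random reference sequence with a target GC fraction."""

    sequence: str
    gc_target: float
    seed: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Fragment:
    """A degraded template molecule drawn from the genome.

    ``start``/``end`` are 0-based half-open genome coordinates; ``sequence``
    is the genome slice, reverse-complemented when ``strand`` is ``'-'``.
    ``tm`` is the salt-unadjusted melting temperature of the fragment.
    """

    start: int
    end: int
    strand: str
    sequence: str
    tm: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LibraryProtocol:
    """Library-preparation protocol parameters.

    ``adapter_scheme`` is one of ``forked_AT`` (A-tailed forked adapters,
    TruSeq-like; hairpins are ligatable and amplify), ``blunt`` (blunt-end
    ligation; hairpins are dropped) or ``stem_loop_blunt`` (Microplex-like
    stem-loop adapters with blunt ligation; hairpins likewise dropped).

    Temperatures are in degrees C.  ``post_atail_hold`` of 0 means no
    inactivation hold.  Denaturation of a fragment at the hottest
    pre-ligation step is ``logistic((T - Tm - denature_midpoint_offset) *
    denature_slope)``.  A found stem only forms an artifact if its duplex
    survives at ``ligation_temp`` (Wallace-rule Tm for stems of <= 13 bp).
    ``length_bias_strength`` scales the PCR preference for short, AT-rich
    molecules; ``error_rate`` is the per-base substitution rate applied at
    sequencing.
    """

    name: str = "custom"
    adapter_scheme: str = "forked_AT"
    atail_temp: float = 37.0
    post_atail_hold: float = 70.0
    ligation_temp: float = 10.0
    denature_midpoint_offset: float = -3.0
    denature_slope: float = 0.6
    min_stem: int = 4
    max_fill: int = 20
    pcr_cycles: int = 18
    length_bias_strength: float = 3.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.adapter_scheme not in {"forked_AT", "blunt", "stem_loop_blunt"}:
            raise ValueError(f"unknown adapter scheme {self.adapter_scheme!r}")
        if self.min_stem < 1:
            raise ValueError("min_stem must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def hottest_preligation_temp(self) -> float:
        return max(self.atail_temp, self.post_atail_hold)


def truseq_like(**overrides) -> LibraryProtocol:
    """TruSeq-V2-like protocol: forked A-tailed adapters, low-temperature
    enzymatics plus a 70 C inactivation hold before ligation."""
    kw = dict(name="truseq_like", adapter_scheme="forked_AT")
    kw.update(overrides)
    return LibraryProtocol(**kw)


def blunt_like(**overrides) -> LibraryProtocol:
    """Blunt-end ligation protocol (no forked adapters); hairpin constructs
    cannot be ligated, so artifacts never amplify."""
    kw = dict(name="blunt_like", adapter_scheme="blunt")
    kw.update(overrides)
    return LibraryProtocol(**kw)


def microplex_like(**overrides) -> LibraryProtocol:
    """Microplex-like single-tube protocol: stem-loop adapters, blunt
    ligation, no enzymatic step above 55 C and no inactivation hold."""
    kw = dict(
        name="microplex_like",
        adapter_scheme="stem_loop_blunt",
        atail_temp=37.0,
        post_atail_hold=0.0,
        pcr_cycles=14,
    )
    kw.update(overrides)
    return LibraryProtocol(**kw)


@dataclass
class Molecule:
    """A library molecule ready for sequencing."""

    id: str
    sequence: str


@dataclass
class HairpinTruth:
    """Ground truth for one sequenced molecule.

    For artifact molecules the terminal palindrome has length
    ``artifact_len = fill_len + stem_len`` where the 3'-terminal
    ``fill_len`` bases are artificial and the adjacent ``stem_len`` bases
    are genomic.  ``duplicate_of`` names the original molecule for PCR
    copies.
    """

    molecule_id: str
    frag_start: int
    frag_end: int
    strand: str
    is_artifact: bool
    fill_len: int
    stem_len: int
    artifact_len: int
    molecule_length: int
    gc: float
    duplicate_of: Optional[str] = None


def generate_genome(length: int, gc_target: float, seed: int) -> SyntheticGenome:
    """i.i.d. genome with P(G)=P(C)=gc_target/2, P(A)=P(T)=(1-gc_target)/2."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not (0.0 < gc_target < 1.0):
        raise ValueError("gc_target must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"GCAT", dtype=np.uint8)
    p = np.array([gc_target / 2, gc_target / 2, (1 - gc_target) / 2, (1 - gc_target) / 2])
    seq = rng.choice(alphabet, size=length, p=p).tobytes().decode("ascii")
    return SyntheticGenome(seq, gc_target, seed)


def draw_fragments(
    genome: SyntheticGenome,
    n: int,
    mean_len: float = 60.0,
    shape: float = 0.35,
    seed: int = 0,
) -> list[Fragment]:
    """Draw ``n`` fragments with log-normally distributed lengths.

    ``mean_len`` is the arithmetic mean of the (untruncated) length
    distribution and ``shape`` the log-scale standard deviation; lengths are
    truncated to ``[20, len(genome)]``.  Start positions and strands are
    uniform.
    """
    if mean_len < 20:
        raise ValueError("mean_len must be >= 20")
    rng = np.random.default_rng(seed)
    glen = len(genome)
    mu = math.log(mean_len) - shape**2 / 2.0
    lengths = np.clip(np.rint(rng.lognormal(mu, shape, size=n)), 20, glen).astype(int)
    out: list[Fragment] = []
    seq = genome.sequence
    for L in lengths:
        start = int(rng.integers(0, glen - L + 1))
        end = start + int(L)
        strand = "+" if rng.random() < 0.5 else "-"
        s = seq[start:end]
        if strand == "-":
            s = reverse_complement(s)
        out.append(Fragment(start, end, strand, s, melting_temperature(s)))
    return out


def apply_deamination(
    fragment: Fragment,
    rate_5prime: float,
    decay_per_base: float,
    seed: int = 0,
) -> Fragment:
    """Cytosine-deamination damage: C->T near the 5' end, G->A near the 3' end.

    A ``C`` at 5' position ``p`` flips with probability
    ``rate_5prime * decay_per_base**p``; ``G`` bases are mirrored from the
    3' end.  Typical ancient-DNA rates are a few percent at the terminal
    position, decaying inwards.
    """
    if not (0.0 <= rate_5prime <= 1.0 and 0.0 <= decay_per_base <= 1.0):
        raise ValueError("deamination rates must lie in [0, 1]")
    if rate_5prime == 0.0:
        return fragment
    rng = np.random.default_rng(seed)
    seq = list(fragment.sequence)
    n = len(seq)
    for p in range(n):
        if seq[p] == "C" and rng.random() < rate_5prime * decay_per_base**p:
            seq[p] = "T"
        q = n - 1 - p
        if seq[q] == "G" and rng.random() < rate_5prime * decay_per_base**p:
            seq[q] = "A"
    new = "".join(seq)
    return replace(fragment, sequence=new, tm=melting_temperature(new))


def denature_probability(tm: float, step_temp: float, protocol: LibraryProtocol) -> float:
    """Probability that a duplex of melting temperature ``tm`` denatures at
    ``step_temp``: a logistic in ``(step_temp - tm - offset) * slope``."""
    x = (step_temp - tm - protocol.denature_midpoint_offset) * protocol.denature_slope
    # clip to avoid overflow in exp for extreme temperatures
    x = max(-60.0, min(60.0, x))
    return 1.0 / (1.0 + math.exp(-x))


def find_hairpin(
    strand: str, min_stem: int = 4, max_fill: int = 20
) -> Optional[tuple[int, int, int]]:
    """Search a single strand for a foldable hairpin stem.

    Looks for a 5'-proximal stem half ``strand[i:i+m]`` (``i <= max_fill``,
    ``m >= min_stem``) whose reverse complement occurs at ``strand[j:j+m]``
    with an unpaired loop of at least 3 bases in between (``j >= i+m+3``).
    When the strand folds at such a stem, the 3' tail beyond ``j+m`` is
    chewable and the ``i`` bases 5' of the stem template the fill-in.

    Selection is deterministic: smallest ``i`` (shortest fill-in forms
    first), then largest ``m`` (longest, most stable stem), then largest
    ``j`` (fold closest to the 3' end).  Returns ``(i, j, m)`` or ``None``.
    """
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    n = len(strand)
    for i in range(0, min(max_fill, n) + 1):
        # largest m that still fits a loop of >= 3 and a second stem half
        m_hi = (n - i - _MIN_LOOP) // 2
        for m in range(m_hi, min_stem - 1, -1):
            target = reverse_complement(strand[i : i + m])
            if "N" in target:
                continue
            j = strand.rfind(target, i + m + _MIN_LOOP)
            if j >= 0:
                return (i, j, m)
    return None


def form_artifact(strand: str, i: int, j: int, m: int) -> str:
    """Chew back the 3' tail beyond the stem and fill in against the 5' end.

    Returns ``strand[:j+m] + reverse_complement(strand[:i])``: everything 3'
    of the annealed stem is removed by exonuclease, then the polymerase
    extends the recessed 3' end copying the 5' prefix, so the product ends
    in an ``i + m`` base interrupted palindrome (``m`` genomic stem bases
    plus ``i`` artificial fill-in bases).
    """
    n = len(strand)
    if not (0 <= i and i + m <= n and j + m <= n and j >= i + m + _MIN_LOOP and m >= 1):
        raise ValueError(f"invalid stem triple (i={i}, j={j}, m={m}) for strand of length {n}")
    if strand[j : j + m] != reverse_complement(strand[i : i + m]):
        raise ValueError("stem halves are not reverse complementary")
    return strand[: j + m] + reverse_complement(strand[:i])


def _stem_stable(stem: str, ligation_temp: float) -> bool:
    tm = wallace_tm(stem) if len(stem) <= 13 else melting_temperature(stem)
    return tm >= ligation_temp


def build_library(
    fragments: Sequence[Fragment],
    protocol: LibraryProtocol,
    seed: int = 0,
) -> tuple[list[Molecule], list[HairpinTruth]]:
    """Run the library-preparation model over a set of fragments.

    Per fragment: (1) denature to ssDNA with probability given by
    :func:`denature_probability` at the hottest pre-ligation step; (2) if
    single-stranded, search for a hairpin stem and, when the stem duplex is
    stable at the ligation temperature, form the artifact molecule; (3)
    apply the amplifiability rule — double-stranded molecules always
    amplify, hairpin constructs amplify only under the ``forked_AT`` scheme,
    and bare ssDNA never does; (4) PCR duplication emits extra copies with a
    Poisson count whose mean is a logistic function of molecule length and
    GC favouring short, AT-rich templates.

    Returns the sequencable molecules and one truth record per molecule
    (PCR copies carry ``duplicate_of``).
    """
    rng = np.random.default_rng(seed)
    hot = protocol.hottest_preligation_temp
    molecules: list[Molecule] = []
    truths: list[HairpinTruth] = []
    # PCR bias: mean extra copies rises for short, AT-rich molecules.
    lam_max = 0.03 * protocol.pcr_cycles
    len_ref, gc_ref = 60.0, 0.45

    for k, frag in enumerate(fragments):
        p_ss = denature_probability(frag.tm, hot, protocol)
        is_ss = rng.random() < p_ss
        seq: Optional[str] = None
        is_artifact = False
        fill = stem = 0
        if is_ss:
            hit = find_hairpin(frag.sequence, protocol.min_stem, protocol.max_fill)
            if hit is not None:
                i, j, m = hit
                if _stem_stable(frag.sequence[i : i + m], protocol.ligation_temp):
                    if protocol.adapter_scheme == "forked_AT":
                        seq = form_artifact(frag.sequence, i, j, m)
                        is_artifact = True
                        fill, stem = i, m
                    # blunt / stem_loop_blunt: hairpin cannot be ligated -> drop
        else:
            seq = frag.sequence
        if seq is None:
            continue

        mol_id = f"mol{k:06d}"
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        base_truth = HairpinTruth(
            molecule_id=mol_id,
            frag_start=frag.start,
            frag_end=frag.end,
            strand=frag.strand,
            is_artifact=is_artifact,
            fill_len=fill,
            stem_len=stem,
            artifact_len=fill + stem if is_artifact else 0,
            molecule_length=len(seq),
            gc=gc,
        )
        molecules.append(Molecule(mol_id, seq))
        truths.append(base_truth)

        if protocol.length_bias_strength > 0 and lam_max > 0:
            x = protocol.length_bias_strength * (
                (len_ref - len(seq)) / len_ref + 2.0 * (gc_ref - gc)
            )
            x = max(-60.0, min(60.0, x))
            lam = lam_max / (1.0 + math.exp(-x))
            extra = int(rng.poisson(lam))
            for d in range(extra):
                dup_id = f"{mol_id}.d{d}"
                molecules.append(Molecule(dup_id, seq))
                truths.append(
                    replace(base_truth, molecule_id=dup_id, duplicate_of=mol_id)
                )
    return molecules, truths


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for h in hits:
        choices = bases[bases != arr[h]]
        arr[h] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def sequence_library(
    molecules: Sequence[Molecule],
    read_len: int = 100,
    error_rate: float = 0.001,
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_R1, DEFAULT_ADAPTER_R2),
    seed: int = 0,
) -> list[tuple[NucleotideRead, NucleotideRead]]:
    """Paired-end sequencing of library molecules.

    R1 is the first ``read_len`` bases of the molecule, running through into
    the R1 adapter (padded with A) when the molecule is shorter than the
    read; R2 is the same from the reverse complement with the R2 adapter.
    Substitution errors are i.i.d. at ``error_rate``; qualities are drawn
    from a fixed high-quality profile (Phred 35-40).
    """
    rng = np.random.default_rng(seed)
    a1, a2 = adapters
    pairs: list[tuple[NucleotideRead, NucleotideRead]] = []
    for mol in molecules:
        fwd_t = mol.sequence + a1
        rev_t = reverse_complement(mol.sequence) + a2
        if len(fwd_t) < read_len:
            fwd_t += "A" * (read_len - len(fwd_t))
        if len(rev_t) < read_len:
            rev_t += "A" * (read_len - len(rev_t))
        r1 = _apply_errors(fwd_t[:read_len], error_rate, rng)
        r2 = _apply_errors(rev_t[:read_len], error_rate, rng)
        q1 = rng.integers(35, 41, size=read_len).tolist()
        q2 = rng.integers(35, 41, size=read_len).tolist()
        pairs.append(
            (
                NucleotideRead(mol.id, r1, q1),
                NucleotideRead(mol.id, r2, q2),
            )
        )
    return pairs
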