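"""End-to-end simulate -> sequence -> trim -> collapse convenience layer.

Chains the simulator, adapter trimming and pair collapsing into the single
entry point used by the command line, the examples and the acceptance
measurements.  Everything is driven by one seed; independent seeds for the
genome, fragment draw, library build and sequencing are spawned from it
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .collapse import CollapseParams, ReadPair, collapse_pair, trim_adapter
from .hairpinsim import (
    DEFAULT_ADAPTER_R1,
    DEFAULT_ADAPTER_R2,
    Fragment,
    HairpinTruth,
    LibraryProtocol,
    SyntheticGenome,
    build_library,
    draw_fragments,
    generate_genome,
    sequence_library,
    truseq_like,
)
from .seqcore import NucleotideRead

__all__ = ["SimulatedLibrary", "simulate_library"]


@dataclass
class SimulatedLibrary:
    """Everything produced by one simulated library run."""

    genome: SyntheticGenome
    protocol: LibraryProtocol
    pairs: list[tuple[NucleotideRead, NucleotideRead]]
    collapsed: list[NucleotideRead]
    truths: list[HairpinTruth]
    n_fragments: int

    @property
    def truth_by_id(self) -> dict[str, HairpinTruth]:
        return {t.molecule_id: t for t in self.truths}

    @property
    def collapsed_truths(self) -> list[HairpinTruth]:
        by_id = self.truth_by_id
        return [by_id[r.id] for r in self.collapsed if r.id in by_id]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def simulate_library(
    protocol: Optional[LibraryProtocol] = None,
    n_fragments: int = 10_000,
    genome_length: int = 100_000,
    gc_target: float = 0.40,
    mean_fragment_length: float = 60.0,
    length_shape: float = 0.35,
    read_len: int = 100,
    seed: int = 0,
    genome: Optional[SyntheticGenome] = None,
    collapse_params: Optional[CollapseParams] = None,
    deamination_rate: float = 0.0,
    deamination_decay: float = 0.5,
) -> SimulatedLibrary:
    """Simulate a full library and return its collapsed reads plus truth.

    Fragments are drawn from ``genome`` (generated if not supplied), pushed
    through the library-preparation model of ``protocol`` (TruSeq-like by
    default), sequenced as pairs, adapter-trimmed and collapsed.  Molecule
    identifiers link collapsed reads back to their truth records.
    """
    if protocol is None:
        protocol = truseq_like()
    if collapse_params is None:
        collapse_params = CollapseParams()
    s_genome, s_frag, s_build, s_seq, s_deam = _spawn_seeds(seed, 5)
    if genome is None:
        genome = generate_genome(genome_length, gc_target, s_genome)
    fragments = draw_fragments(
        genome, n_fragments, mean_fragment_length, length_shape, s_frag
    )
    if deamination_rate > 0:
        from .hairpinsim import apply_deamination

        rng = np.random.default_rng(s_deam)
        fragments = [
            apply_deamination(
                f, deamination_rate, deamination_decay, int(rng.integers(2**31 - 1))
            )
            for f in fragments
        ]
    molecules, truths = build_library(fragments, protocol, s_build)
    pairs = sequence_library(
        molecules, read_len=read_len, error_rate=protocol.error_rate, seed=s_seq
    )
    collapsed: list[NucleotideRead] = []
    for r1, r2 in pairs:
        t1 = trim_adapter(r1, DEFAULT_ADAPTER_R1)
        t2 = trim_adapter(r2, DEFAULT_ADAPTER_R2)
        if len(t1) == 0 or len(t2) == 0:
            continue
        merged = collapse_pair(ReadPair(t1, t2), collapse_params)
        if merged is not None:
            collapsed.append(merged)
    return SimulatedLibrary(
        genome=genome,
        protocol=protocol,
        pairs=pairs,
        collapsed=collapsed,
        truths=truths,
        n_fragments=n_fragments,
    )
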