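"""Tests for the hairpin-artifact library simulator."""

import math

import numpy as np
import pytest

from palinclip.collapse import ReadPair, collapse_pair
from palinclip.hairpinsim import (
    DEFAULT_ADAPTER_R1,
    LibraryProtocol,
    apply_deamination,
    blunt_like,
    build_library,
    denature_probability,
    draw_fragments,
    find_hairpin,
    form_artifact,
    generate_genome,
    microplex_like,
    sequence_library,
    truseq_like,
)
from palinclip.seqcore import (
    melting_temperature,
    reverse_complement,
    terminal_palindrome_length,
)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(10_000, 0.45, seed=3)
        b = generate_genome(10_000, 0.45, seed=3)
        assert a.sequence == b.sequence

    def test_gc_within_three_sd(self):
        n, g = 50_000, 0.45
        genome = generate_genome(n, g, seed=3)
        gc = (genome.sequence.count("G") + genome.sequence.count("C")) / n
        sd = math.sqrt(g * (1 - g) / n)
        assert abs(gc - g) <= 3 * sd

    @pytest.mark.parametrize("bad_gc", [0.0, 1.0, -0.1, 1.5])
    def test_gc_bounds_rejected(self, bad_gc):
        with pytest.raises(ValueError):
            generate_genome(10_000, bad_gc, seed=0)

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(999, 0.5, seed=0)


class TestDrawFragments:
    def test_mean_length(self, small_genome):
        frags = draw_fragments(small_genome, 5000, mean_len=70, shape=0.35, seed=9)
        lengths = np.array([len(f) for f in frags])
        se = lengths.std(ddof=1) / math.sqrt(len(lengths))
        assert abs(lengths.mean() - 70) <= 3 * se

    def test_zero_fragments(self, small_genome):
        assert draw_fragments(small_genome, 0, seed=0) == []

    def test_sequence_matches_genome_slice(self, small_genome):
        for frag in draw_fragments(small_genome, 100, seed=4):
            s = small_genome.sequence[frag.start : frag.end]
            expected = s if frag.strand == "+" else reverse_complement(s)
            assert frag.sequence == expected
            assert frag.tm == melting_temperature(frag.sequence)

    def test_mean_len_validated(self, small_genome):
        with pytest.raises(ValueError):
            draw_fragments(small_genome, 10, mean_len=10)


class TestDeamination:
    def test_rate_zero_identity(self, small_genome):
        frag = draw_fragments(small_genome, 1, seed=0)[0]
        assert apply_deamination(frag, 0.0, 0.5, seed=1).sequence == frag.sequence

    def test_saturation(self, small_genome):
        frag = draw_fragments(small_genome, 1, seed=0)[0]
        out = apply_deamination(frag, 1.0, 1.0, seed=1)
        assert "C" not in out.sequence and "G" not in out.sequence

    def test_terminal_rate_recovered(self, small_genome):
        frags = [f for f in draw_fragments(small_genome, 8000, seed=2)
                 if f.sequence[0] == "C"]
        rate = 0.3
        flips = sum(
            apply_deamination(f, rate, 0.5, seed=i).sequence[0] == "T"
            for i, f in enumerate(frags)
        )
        n = len(frags)
        sd = math.sqrt(rate * (1 - rate) / n)
        assert abs(flips / n - rate) <= 4 * sd


class TestDenatureProbability:
    def test_midpoint(self):
        proto = LibraryProtocol(denature_midpoint_offset=0.0)
        assert denature_probability(70.0, 70.0, proto) == pytest.approx(0.5)

    def test_saturation(self):
        proto = LibraryProtocol(denature_midpoint_offset=0.0)
        assert denature_probability(70.0, -1000.0, proto) < 1e-12
        assert denature_probability(70.0, 1000.0, proto) > 1 - 1e-12

    def test_monotone_in_temperature_and_tm(self):
        proto = LibraryProtocol()
        ps = [denature_probability(70.0, t, proto) for t in range(40, 100)]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        # lower GC -> lower Tm -> higher denaturation at fixed step
        lo = melting_temperature("AT" * 20)
        hi = melting_temperature("GC" * 20)
        assert denature_probability(lo, 70.0, proto) > denature_probability(hi, 70.0, proto)


class TestFindHairpin:
    def test_worked_example(self):
        assert find_hairpin("TTACGAAAAATCGT", min_stem=4) == (2, 10, 4)

    def test_homopolymer_has_no_stem(self):
        assert find_hairpin("A" * 10, min_stem=4) is None

    def test_postcondition_audit(self, rng):
        """Any returned (i, j, m) satisfies the reverse-complement identity,
        the fill/stem bounds and the minimum loop."""
        found = 0
        for _ in range(1000):
            n = int(rng.integers(20, 120))
            strand = "".join(rng.choice(list("ACGT"), size=n))
            hit = find_hairpin(strand, min_stem=4, max_fill=20)
            if hit is None:
                continue
            found += 1
            i, j, m = hit
            assert 0 <= i <= 20 and m >= 4
            assert j >= i + m + 3 and j + m <= n
            assert strand[j : j + m] == reverse_complement(strand[i : i + m])
        assert found > 100  # the audit actually exercised hits

    def test_selection_prefers_smallest_fill(self):
        # two stems: one at i=0, one at i=3; the smaller fill must win
        stem0 = "ACGG"
        strand = stem0 + "TTTTT" + reverse_complement(stem0) + "TTTT"
        hit = find_hairpin(strand, min_stem=4)
        assert hit is not None and hit[0] == 0


class TestFormArtifact:
    def test_worked_example(self):
        t = form_artifact("TTACGAAAAATCGT", 2, 10, 4)
        assert t == "TTACGAAAAATCGTAA"
        assert terminal_palindrome_length(t) == 6

    def test_zero_fill_chewback_only(self):
        strand = "ACGGTTTTTCCGTAAAA"  # stem ACGG at i=0 pairs CCGT at j=9
        assert strand[9:13] == reverse_complement(strand[0:4])
        t = form_artifact(strand, 0, 9, 4)
        assert t == strand[:13]  # 3' tail chewed, no fill-in
        assert terminal_palindrome_length(t) >= 4

    def test_tail_removed(self):
        strand = "TTACGAAAAATCGTGGGG"  # 4-base 3' tail beyond the stem
        t = form_artifact(strand, 2, 10, 4)
        assert t == "TTACGAAAAATCGTAA"
        assert len(t) == 10 + 4 + 2

    def test_invalid_stem_rejected(self):
        with pytest.raises(ValueError):
            form_artifact("TTACGAAAAATCGT", 2, 10, 5)  # halves not complementary
        with pytest.raises(ValueError):
            form_artifact("TTACGAAAAATCGT", 2, 5, 4)  # loop below minimum

    def test_guaranteed_palindrome_on_random_hits(self, rng):
        for _ in range(300):
            n = int(rng.integers(24, 120))
            strand = "".join(rng.choice(list("ACGT"), size=n))
            hit = find_hairpin(strand, min_stem=4, max_fill=20)
            if hit is None:
                continue
            i, j, m = hit
            t = form_artifact(strand, i, j, m)
            assert terminal_palindrome_length(t) >= i + m


class TestBuildLibrary:
    def _fragments(self, n=400, seed=5):
        genome = generate_genome(10_000, 0.40, seed=1)
        return draw_fragments(genome, n, seed=seed)

    def test_no_denaturation_means_no_artifacts(self):
        proto = truseq_like(denature_midpoint_offset=500.0)  # p ~ 0 everywhere
        mols, truths = build_library(self._fragments(), proto, seed=2)
        assert mols and not any(t.is_artifact for t in truths)

    def test_blunt_scheme_never_emits_artifacts(self):
        proto = blunt_like(denature_midpoint_offset=-500.0)  # p ~ 1: all ssDNA
        mols, truths = build_library(self._fragments(), proto, seed=2)
        assert not any(t.is_artifact for t in truths)
        assert len(mols) == 0  # every fragment denatured; none ligatable

    def test_stem_loop_scheme_never_emits_artifacts(self):
        proto = microplex_like(denature_midpoint_offset=-500.0)
        _, truths = build_library(self._fragments(), proto, seed=2)
        assert not any(t.is_artifact for t in truths)

    def test_truth_bookkeeping_under_forced_denaturation(self):
        """With denaturation forced on, artifact molecules are exactly the
        fragments with a findable, ligation-stable stem, and every truth
        record is internally consistent."""
        frags = self._fragments(600)
        proto = truseq_like(denature_midpoint_offset=-500.0, length_bias_strength=0.0)
        mols, truths = build_library(frags, proto, seed=2)
        assert len(mols) == len(truths)
        assert all(t.is_artifact for t in truths)
        by_id = {m.id: m for m in mols}
        for t in truths:
            assert t.stem_len >= proto.min_stem
            assert t.artifact_len == t.fill_len + t.stem_len
            mol = by_id[t.molecule_id]
            assert terminal_palindrome_length(mol.sequence) >= t.artifact_len
            assert t.molecule_length == len(mol.sequence)

    def test_duplicates_reference_their_original(self):
        proto = truseq_like(length_bias_strength=6.0, pcr_cycles=30)
        mols, truths = build_library(self._fragments(800), proto, seed=2)
        by_id = {m.id: m for m in mols}
        dups = [t for t in truths if t.duplicate_of is not None]
        assert dups  # bias strong enough to produce some copies
        for t in dups:
            assert by_id[t.molecule_id].sequence == by_id[t.duplicate_of].sequence

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            LibraryProtocol(adapter_scheme="nested_pcr")


class TestSequenceLibrary:
    def test_adapter_readthrough_layout(self):
        from palinclip.hairpinsim import Molecule

        mol = Molecule("m0", "ACGT" * 15)  # 60 bp
        (r1, r2), = sequence_library([mol], read_len=100, error_rate=0.0, seed=0)
        assert r1.sequence[:60] == mol.sequence
        assert r1.sequence[60:100] == (DEFAULT_ADAPTER_R1 + "A" * 100)[:40]
        assert r2.sequence[:60] == reverse_complement(mol.sequence)
        assert len(r1) == len(r2) == 100
        assert len(r1.qualities) == 100

    def test_error_free_pairs_collapse_to_molecule(self):
        from palinclip.collapse import trim_adapter
        from palinclip.hairpinsim import DEFAULT_ADAPTER_R2, Molecule

        genome = generate_genome(5000, 0.4, seed=7)
        mols = [
            Molecule(f"m{i}", f.sequence)
            for i, f in enumerate(draw_fragments(genome, 150, seed=8))
        ]
        pairs = sequence_library(mols, error_rate=0.0, seed=3)
        for mol, (r1, r2) in zip(mols, pairs):
            t1 = trim_adapter(r1, DEFAULT_ADAPTER_R1)
            t2 = trim_adapter(r2, DEFAULT_ADAPTER_R2)
            merged = collapse_pair(ReadPair(t1, t2))
            if len(mol.sequence) >= 25:
                assert merged is not None and merged.sequence == mol.sequence

    def test_error_rate_recovered(self):
        from palinclip.hairpinsim import Molecule

        mol = Molecule("m0", "ACGT" * 50)  # 200 bp, no adapter within read
        pairs = sequence_library([mol] * 300, read_len=100, error_rate=0.01, seed=5)
        mism = total = 0
        for r1, _ in pairs:
            mism += sum(a != b for a, b in zip(r1.sequence, mol.sequence[:100]))
            total += 100
        rate = mism / total
        sd = math.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) <= 4 * sd

    def test_deterministic_under_seed(self):
        from palinclip.hairpinsim import Molecule

        mols = [Molecule("m0", "ACGTACGTACGTACGTACGTACGTACGT")]
        a = sequence_library(mols, error_rate=0.05, seed=9)
        b = sequence_library(mols, error_rate=0.05, seed=9)
        assert a[0][0].sequence == b[0][0].sequence
        assert a[0][0].qualities == b[0][0].qualities
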