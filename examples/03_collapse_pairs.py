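"""Merge overlapping mate pairs into collapsed fragment reads.

Short degraded fragments are read through by both mates; the pair is merged
when the best overlap is at least 11 bases with at most 33% mismatches.
At a disagreement the higher-quality base wins; merged qualities take the
best contributing score.
"""

from palinclip import NucleotideRead, ReadPair, collapse_pair, reverse_complement

frag = "ACGTTGCAAGGCTTACGGATCCATTGCAAGTGCAACT"  # 37 bp "fragment"

# reverse mate carries one sequencing error (position 10, low quality)
rev_template = list(frag)
rev_template[10] = "T"
pair = ReadPair(
    NucleotideRead("p1", frag, [40] * len(frag)),
    NucleotideRead("p1", reverse_complement("".join(rev_template)), [10] * len(frag)),
)
merged = collapse_pair(pair)
print("fragment:", frag)
print("merged  :", merged.sequence)
print("identical despite the reverse-mate error:", merged.sequence == frag)
print("quality at the disputed base:", merged.qualities[10], "(forward read, q40, won)")

# a 190 bp fragment leaves only a 10-base overlap for 100 bp reads -> rejected
import numpy as np

rng = np.random.default_rng(0)
long_frag = "".join(rng.choice(list("ACGT"), size=190))
pair = ReadPair(
    NucleotideRead("p2", long_frag[:100]),
    NucleotideRead("p2", reverse_complement(long_frag)[:100]),
)
print("190 bp fragment (10-base overlap) collapses:", collapse_pair(pair) is not None)
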