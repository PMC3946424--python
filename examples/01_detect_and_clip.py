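"""Detect and clip a 3'-terminal interrupted palindrome in single reads.

A read whose last L bases are the reverse complement of its first L bases
carries a candidate hairpin artifact; palindromes of at least 4 bases are
clipped from the 3' end only (the 5' copy is genomic and stays).
"""

from palinclip import NucleotideRead, clip_palindrome, terminal_palindrome_length

reads = [
    NucleotideRead("artifact_read", "ACGTACCCCCTACGT"),  # ends with revcomp("ACGTA")
    NucleotideRead("chance_3bp", "ACGAAAACGT"),          # 3-base palindrome: reported, kept
    NucleotideRead("clean_read", "AAAAGGGGTTTTCCCA"),
]

for read in reads:
    clipped, call = clip_palindrome(read, min_clip=4)
    print(
        f"{read.id:>14}: L={call.palindrome_length}  clipped={call.clipped}  "
        f"{read.sequence} -> {clipped.sequence}"
    )

# L is the number of consecutive complementary end pairs, capped at half the
# read so the 5' and 3' sections stay disjoint.
print("\nL of a fully self-complementary 20-mer:",
      terminal_palindrome_length("ACGT" * 5))
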