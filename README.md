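# palinclip

Detection, quantification and clipping of 3'-terminal **interrupted
palindromes** in sequencing reads from degraded (historic/ancient) DNA —
plus a generative simulator of the hairpin-loop library-preparation
mechanism that creates them.

## The problem

Reads from historic samples prepared with A-tailed *forked* adapters
(TruSeq-like protocols) frequently end in an exact reverse complement of
their own 5' start: the last `L` bases equal
`revcomp(first L bases)`, with unrelated sequence in between. The 5' copy
is genomic; the 3' copy is artificial. The mechanism: short double-stranded
fragments denature at warm library-prep steps; the single strand folds into
a hairpin wherever a short internal reverse complement (stem, `m` bases)
pairs a 3'-proximal with a 5'-proximal region; exonucleases chew back the
unannealed 3' tail; a polymerase fills in the recessed 3' end using the
strand's own 5' prefix (`i` bases) as template. The product carries an
`i + m` base terminal palindrome, amplifies only under forked-adapter
schemes, and — because the fill-in does not match the reference — drags
down alignment rates until it is clipped.

The detector counts consecutive Watson–Crick-complementary end pairs
`(seq[t], seq[n-1-t])` from `t = 0`, capped at `floor(n/2)`:

    L = max k <= n/2  such that  seq[n-k:] == revcomp(seq[:k])

Palindromes with `L >= 4` ("longer than three bases") are counted as
artifact content and clipped from the 3' end only. For uniform random
sequence the chance background is `(1/4)^4 = 0.390625%`.

## Worked example

```python
from palinclip import NucleotideRead, clip_palindrome

read = NucleotideRead("artifact_read", "ACGTACCCCCTACGT")
clipped, call = clip_palindrome(read, min_clip=4)
print(call.palindrome_length, call.clipped, clipped.sequence)
```

The last five bases `TACGT` are the reverse complement of the first five
`ACGTA`, so this prints `5 True ACGTACCCCC`: a 5-base palindrome, clipped
from the 3' end; the genomic 5' copy stays.

Simulating the protocol contrast (`python examples/02_simulate_library.py`):

```
truseq_like: 2693 collapsed reads, palindrome content 68.14%, mean length 54.2 bp, GC 40.6%
   mean Tm: palindromic 64.3 C vs clean 73.3 C (AT-rich, low-melting fragments denature and fold first)
microplex_like: 3677 collapsed reads, palindrome content 0.52%, mean length 58.4 bp, GC 39.9%
```

The forked-adapter library accumulates palindromes in two thirds of its
reads (historic TruSeq libraries: 42–78%), while the stem-loop blunt
protocol stays at the ~0.4% chance background; artifact reads melt ~9 °C
lower because Tm-coupled denaturation selects AT-rich fragments. And the
alignment consequence (`python examples/04_alignment_gain.py`):

```
883 collapsed reads, 100% artifact, mean fill-in 7.4 bases
mapped before clipping: 153
mapped after clipping : 883  (5.8x gain)
```

## What's in the box

| module | contents |
| --- | --- |
| `palinclip.seqcore` | reverse complement, palindrome detection/clipping, GC, melting temperature, dinucleotide repeats, duplicate fraction |
| `palinclip.collapse` | adapter trimming and quality-aware paired-end overlap collapsing (min overlap 11, mismatch rate ≤ 0.33, min length 25) |
| `palinclip.hairpinsim` | synthetic genomes, fragment draws, deamination, logistic denaturation, hairpin search, artifact formation, protocol presets, PCR bias, paired-end sequencing with ground truth |
| `palinclip.toymap` | exhaustive ungapped mapper (3% mismatch, uniqueness rule) and per-position substitution profiles |
| `palinclip.report` | palindrome content, seeded reservoir subsampling, per-library summaries stratified by palindrome status |
| `palinclip.pipeline` | one-call simulate → sequence → trim → collapse |
| `palinclip.evaluation` | the benchmark experiments (oracle agreement, backgrounds, recovery, contrasts, alignment gain, linearity, stratification) |

A thin CLI wraps the library: `palinclip simulate | collapse | detect |
clip | stats | subsample | evaluate` (see `palinclip --help`). The
`examples/` scripts are short narrative walkthroughs, one per capability.

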