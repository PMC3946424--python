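# Methods

## The artifact and its detection

Libraries prepared from degraded (historic/ancient) DNA with A-tailed
forked adapters can contain reads whose 3'-terminal bases are an exact
reverse complement of the read's own 5' start, separated by unrelated
sequence — an *interrupted palindrome*. The proposed mechanism: a short
double-stranded fragment denatures during a warm library-preparation step;
the single strand folds back on itself wherever a short internal reverse
complement (the *stem*, length `m`) can pair a 3'-proximal region with a
5'-proximal one around an unpaired loop; 3'→5' exonucleases remove any
unannealed 3' tail beyond the stem; a polymerase then fills in the recessed
3' end using the strand's own 5' prefix (length `i`, the *fill-in*) as
template. The product ends in an `i + m` base palindrome of which the stem
section is genomic and the fill-in is artificial. Forked adapters ligate
onto the double-stranded stem, so only forked-adapter protocols amplify the
construct; blunt-end and stem-loop protocols drop it.

The detector (`seqcore.terminal_palindrome_length`) counts consecutive
complementary end pairs `(seq[t], seq[n-1-t])` from `t = 0`, stopping at the
first non-complementary pair or at `floor(n/2)`. The cap keeps the 5' and
3' sections disjoint; an uncapped definition would let a fully
self-complementary read overlap its own two halves. By the nested-match
property this linear scan equals the brute-force "largest k whose suffix
equals the reverse-complemented prefix" search, which the test suite
verifies against an independent oracle on 10^5 random reads. `N` is never
complementary to anything (including `N`), so low-quality bases cannot
inflate calls. Clipping (`clip_palindrome`) removes the last `L` bases in a
single pass when `L >= min_clip` (default 4, i.e. "longer than three
bases"); the 5' end is never modified, and the call records a `residual`
flag when a second palindrome remains after clipping rather than iterating.

For i.i.d. uniform reads the chance of `L >= 4` is `(1/4)^4 = 0.390625%`,
which is both the analytic validation target for the detector and the
expected background content of libraries without the artifact.

## Auxiliary read statistics

* GC content counts `G + C` over the full read length; `N` stays in the
  denominator.
* Melting temperature uses the salt-unadjusted long-sequence formula
  `Tm = 64.9 + 41 (nGC − 16.4) / n` for `n > 13`; for 13 bases or fewer it
  falls back to the Wallace rule `2(A+T) + 4(G+C)` with a warning, since
  the long formula is undefined there in the source it follows.
* The duplicate fraction is `(total − distinct) / total` over full-sequence
  identity — a reference-free surrogate for alignment-based duplicate
  marking that is exactly reproducible.
* The dinucleotide-repeat span reports the longest tandem run (complete
  copies) of a two-base motif with distinct bases; homopolymers and runs
  under two copies score 0.

## Paired-end collapse

`collapse.collapse_pair` is a functional re-implementation of the classic
adapter-trim-and-collapse workflow, not a byte-compatible clone of any
particular tool; its contract is the round-trip property (error-free pairs
reconstruct their fragment exactly). Defaults: minimum overlap 11,
mismatch rate at most 0.33 inside the overlap, merged reads under 25 bases
discarded, terminal `N` runs trimmed. The reverse complement of the
reverse mate is slid over the forward mate; among offsets with overlap at
least the minimum, the fewest-mismatch overlap wins, ties going to the
longer overlap (candidates below the minimum overlap are excluded *before*
ranking — otherwise a chance one-base perfect overlap would outrank any
true overlap containing a sequencing error). At a disagreement the
higher-quality base wins, forward on ties; the merged quality at every
position is the best contributing score, taken literally from the
best-of-either rule.

The merged read spans `[0, offset + len(reverse))` in forward coordinates:
the forward mate anchors the insert's 5' end and the reverse mate its 3'
end, so reverse bases left of the forward start and forward bases right of
the reverse end are adapter read-through and are dropped. This matters for
inserts one or two bases shorter than the read length, whose adapter stub
is below the adapter trimmer's minimum overlap (3 bases — short chance
suffix matches must not nibble adapter-free reads).

## The simulator

`hairpinsim` generates libraries with per-molecule ground truth.

* **Genome**: i.i.d. bases with `P(G)=P(C)=gc/2`; default GC 0.40,
  matching the 35–45% range of historic libraries.
* **Fragments**: log-normal lengths (default mean 60 bp, log-sd 0.35,
  truncated at 20 bp), uniform start and strand. Historic collapsed-read
  lengths average roughly 44–81 bp; 60 bp sits mid-range.
* **Denaturation**: each fragment becomes single-stranded with probability
  `logistic((T_step − Tm − offset) · slope)` at the hottest pre-ligation
  step (default: max of 37 °C A-tailing and a 70 °C inactivation hold).
  Defaults `offset = −3 °C`, `slope = 0.6 /°C`. This logistic form is a
  modelling choice — the mechanism's direction (short, AT-rich fragments
  denature first) is established, its rates are not.
* **Hairpin search** (`find_hairpin`): fill `i ≤ max_fill` (default 20),
  stem `m ≥ min_stem` (default 4), loop of at least 3 unpaired bases
  (steric minimum). Selection is deterministic: smallest fill, then
  longest stem, then the fold closest to the 3' end. Longest-stem-first
  means chance complementarity adjacent to a stem is absorbed into the stem
  wherever the loop minimum allows, which is why detected `L` equals truth
  `i + m` for essentially all artifacts; the residual ~1% comes from
  hairpins whose loop is already minimal (3–4 bases), where one more
  genuinely complementary pair can extend the detected palindrome past the
  mechanistic length (capped at `floor(n/2)`).
* **Stem stability**: the stem duplex must survive ligation (default
  10 °C), using the Wallace rule for stems of ≤ 13 bp.
* **Artifact formation** (`form_artifact`): product =
  `strand[:j+m] + revcomp(strand[:i])`. The untemplated A overhang added
  before ligation is treated as part of the adapter (as read trimmers do),
  so it does not appear in molecule sequences.
* **Amplifiability**: double-stranded molecules always amplify; hairpin
  constructs amplify only under `forked_AT`; bare ssDNA never does.
  Stem-loop blunt (Microplex-like) hairpins are treated exactly like blunt
  ones — that protocol's near-zero artifact content is attributed to its
  ligation scheme, not a separate mechanism.
* **PCR duplication**: each molecule emits `1 + Poisson(λ)` copies with
  `λ = 0.03 · cycles · logistic(b · ((60 − len)/60 + 2(0.45 − gc)))`,
  `b = length_bias_strength` (default 3) — a stylised short/AT-rich
  amplification preference. Only relative enrichment of artifact over
  clean reads is meaningful; absolute fold is not calibrated (the measured
  ~2× enrichment is below the 3–37× range seen in real libraries).
* **Deamination** (off by default): C→T flips at 5' position `p` with
  probability `rate · decay^p`, mirrored G→A from the 3' end; applied to
  fragments before library preparation.
* **Sequencing**: 100 bp paired reads; adapter read-through (standard
  read-through adapter sequences, A-padded) when the molecule is shorter
  than the read; i.i.d. substitution errors (default 0.1%); Phred 35–40
  qualities. All randomness flows from one seed; identical configurations
  give byte-identical output.

With these defaults the forked-adapter library lands at ~65–68% palindrome
content (the historic TruSeq libraries show 42–78%), while blunt and
stem-loop libraries sit at the ~0.4% chance background (their real
counterparts: ~0.1–0.4%). Stratification falls out of the Tm-coupling
rather than being imposed: artifact reads average ~64 °C Tm against ~73 °C
for clean reads (real libraries: 62 vs 74 °C), and are shorter and
AT-richer. The mean artifact palindrome length comes out near 9.7 bp; the
real libraries' second mode averages ~11 bp — the smallest-fill-first
selection rule shortens fills slightly relative to reality.

What the generator does *not* emulate: indels, per-cycle quality decay,
uracil-intolerant polymerase chemistry, single-stranded library protocols,
hairpin-formation kinetics (all rates are configurable parameters, not
claims), real genome repeat structure, or contaminant DNA. Passing tests
therefore demonstrate internal consistency of the mechanism and detector,
not field performance on real libraries.

## Toy mapper

`toymap.map_read` scores every ungapped placement of a read on both strands
of a small genome by mismatch count. A read is mapped when the best
placement is unique at its mismatch count and the mismatch fraction is at
most 3% (the stringency typical for degraded-DNA alignment); uniqueness
stands in for a mapping-quality cutoff, which is not modelled. Ungapped
matching is adequate for the short fragments simulated here and is a
documented divergence from gapped aligners. `alignability` reports mapped
fractions under both denominators (collapsed reads and untrimmed pairs),
since published percentages use both. `positional_mismatch_profile`
classifies read-versus-genome substitutions (C→T, G→A, other) at offsets
1–25 from each read end, oriented to the read.

On simulated high-artifact libraries, clipping raises the mapped-read count
by ~5–6× (the real comparison showed better than 2×), and across libraries
sweeping hairpin rates 0–80% the palindrome-read count explains >99% of the
variance in post-clip alignment gain, matching the reported R² = 99%
linearity.

## Numerical and edge-case conventions

* Empty sequences: palindrome length 0; GC, Tm, duplicate fraction and
  library summaries reject empty input.
* Logistic arguments are clipped to ±60 before exponentiation.
* All tie-breaks (overlap choice, stem selection, mapping position,
  equal-quality disagreements) are deterministic and documented above.
* Sub-seeds for pipeline stages are spawned from the user seed via
  `numpy.random.SeedSequence`, and every value is kept below 2^31.

## Benchmark problem sizes

The packaged benchmarks (`palinclip.evaluation`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 10^5 random reads
for oracle agreement; 10^6 uniform 70-mers for the chance background; 10^4
fragments on a uniform 10 kb genome for mechanism recovery; 10^4 fragments
per scheme for the protocol contrast; 4×10^3 fragments for the alignment
gain; eight libraries of 1.2×10^3 fragments for the linearity sweep;
1.2×10^4 fragments for stratification; and 10^4 pairs for the collapse
round-trip. These sizes give stable estimates (binomial standard errors
well under the asserted margins) at desk scale.
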