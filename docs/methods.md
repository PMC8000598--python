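# Methods

This note documents the models, statistical procedures and design
choices behind `netseq-rdna`, and what the synthetic-data tests do and
do not establish about real data.

## The measurement model

NET-seq reads report polymerase positions: each sequenced fragment is
the 3′ end of a nascent transcript, so the genomic position of the
read's 5′ end is the last incorporated nucleotide (LNT) of the
polymerase that carried it. Occupancy at a position is the count of
read 5′ ends there, normalised by the track's plus-strand total. High
occupancy is read as slow transcription or pausing; the method cannot
measure absolute polymerase loading (initiation), only the shape of the
distribution along the template.

## The toy locus and its geometry

The template is a random-sequence genome carrying two identical,
annotated copies of a 35S-like transcription unit (regions ETS1, 18S,
ITS1, 5.8S, ITS2, 25S, ETS2; default lengths 100, 180, 80, 60, 80, 340,
60 nt — a ~7.7× scaled-down version of the yeast unit that keeps every
region longer than the pause-logo flank while keeping per-position
counts high at test-scale read numbers). Transcription-direction
coordinates are 1-based starting at the ETS1 end.

The unit is placed so that it runs right-to-left on the genomic plus
strand. With that geometry a nascent fragment ending at LNT `x` covers
unit positions `x−L+1 … x`, whose plus-strand projection is the genomic
interval `[pos(x), pos(x)+L)` — i.e. on-target inserts align to the
plus strand with their leftmost coordinate exactly at the LNT. Counting
plus-strand read 5′ ends then reads polymerase positions off directly,
and plus-strand-total normalisation applies literally. This is a
modelling convenience, not a claim about the geometry of any real
genome assembly. Positions within one maximal fragment length of the
unit's 5′ edge cannot produce a full fragment and are excluded from
sampling (probability zero in the recorded ground truth).

Both copies are byte-identical, so every on-target insert matches both;
the aligner reports one interval per matching copy and the
copy-combination step sums them. Each read therefore contributes two
counts instead of one — a constant factor absorbed by normalisation.

## The generative model

The LNT of each fresh on-target read is drawn from

    w(x) ∝ (1 − δ)^x · exp(β · g(x))

- `δ` (`termination_prob`): per-nucleotide premature-termination
  probability. A polymerase reaches position `x` only if it survived
  `x` single-step termination trials, giving the geometric decay that
  encodes processivity. Defaults: 5·10⁻⁴ (wild-type-like) and 2.5·10⁻³
  (mutant-like, a five-fold defect), chosen so the 3′/5′ occupancy
  ratio over the 900-nt unit is ≈0.64 for the wild type and ≈0.10 for
  the mutant — a visible but not degenerate gradient.
- `g(x)`: G fraction of the 10 sense-strand positions downstream of
  `x` (truncated at the unit's 3′ end), the window in which
  sequence-dependent pausing acts.
- `β` (`pause_gc_weight`): coupling of dwell weight to downstream G
  content; default 0 for the wild type and 2.0 for the mutant, so an
  all-G downstream window raises the dwell weight e²≈7.4-fold over an
  all-A window — strong enough for ~20 pause windows to carry a
  detectable G signal, weak enough that the occupancy gradient still
  dominates the track.

Reads are `AG + 8-nt UMI + TG + insert`, with the 3′ linker
`CTGTAGGCACCAT` plus a 0–6-nt random tail appended with probability
0.9 (read-through of the linker is the common case on short inserts).
Insert lengths are uniform on 20–40 nt, long enough for effectively
unique exact matching against a ~2.3-kb genome. PCR duplicates
(probability 0.1 per emitted read) are verbatim copies of a uniformly
chosen earlier read; off-target molecules (5% of fresh reads) are
random sequence guaranteed to fail the 5′ format. UMIs are uniform over
4⁸.

What the generator does *not* emulate: base-call errors and quality
variation, partial/truncated linkers, rDNA copy-number differences
between strains, chromatin context, and the long-tailed peak structure
of real occupancy (real tracks have orders-of-magnitude dynamic range;
the synthetic tracks are Poisson-like around a smooth trend). Passing
tests therefore establish that the *computational chain* is correct and
calibrated under a known model — not that the biological conclusions
would survive the noise structure of a real library.

## Preprocessing dialect

Duplicate removal collapses identical full read sequences; because the
UMI is embedded in the read, identical sequence implies identical UMI
and fragment, which is exactly the PCR-duplicate signature. The 5′
format match is anchored and exact (no mismatches, no indels): a read
is on-target iff it is ≥13 nt, starts with `AG` and has `TG` at
positions 11–12; the first 12 nt are removed and positions 3–10 kept as
the UMI. Linker trimming truncates at the *first* occurrence of the
full linker; reads whose insert becomes empty are discarded. Tolerant
matching (mismatched prefixes, partial 3′ linkers, quality trimming) is
deliberately out of scope.

Two small caveats follow from this design. The chain is not strictly
idempotent: one insert in ~256 starts with the format pattern by
chance, and distinct molecules can share an insert once the UMI is
stripped. Neither affects a single forward pass.

## Statistical procedures

**Replicate concordance** is Spearman rank correlation of normalised
tracks (average ranks for ties; constant tracks are rejected rather
than returning NaN). Note that concordance measures reproducible
*structure*: a flat track plus noise gives a low ρ even when the
pipeline is perfect.

**Per-position comparison** is a two-sided pooled-variance (Student)
two-sample *t*-test on the 3-vs-3 normalised replicate values, with no
multiple-testing correction (the per-position significance band is
displayed raw). The pooled test was chosen over the Welch variant
deliberately: with *n* = 3 per group the Welch–Satterthwaite
degrees-of-freedom approximation is poor and the Welch test's true
level is ≈0.035 at nominal 0.05 *even for exactly normal data*, while
the pooled test is exact under normality and the replicates are
exchangeable same-protocol libraries. Positions where both strains have
zero variance (typically zero counts) get *p* = 1. A position is
classed `increased`/`decreased` only if *p* < α *and* the mutant median
is above/below the wild-type median.

Residual discreteness matters at desk scale: with ~23 combined counts
per position, the *t* statistic takes a discrete value set and the
measured null level is ≈0.047–0.049 rather than 0.050 — slightly
conservative, as any non-randomised test on such counts must be.

**Moving averages** are centred rolling means; output positions lacking
a full window are omitted (length *n* − *w* + 1) rather than padded, to
avoid inventing values at the edges.

**K-S tests** compare the two strains' median tracks as value samples,
genome-wide and within each region, using the asymptotic two-sample
Kolmogorov–Smirnov test. A calibration caveat discovered during
development: when libraries differ stochastically in composition
(duplicates, off-target reads), each replicate's plus-strand total is
random, and normalising by it injects a small *coherent* scale
difference between strains; on near-flat tracks the K-S test then
rejects far too often in large regions (measured: the largest region
"significant" in ~2/3 of null repeats). With fixed library composition
the test is well calibrated. Null-calibration studies in the test suite
therefore use clean libraries (no duplicates, no off-target reads), and
K-S results on real tracks should be read with this sensitivity to
normalisation noise in mind.

**Pause sites** are positions whose median normalised occupancy reaches
the (1 − 0.025) quantile of window-eligible positions (a full ±30-nt
window must fit); ties at the threshold are all included, so the set
can slightly exceed 2.5% — deterministic and avoids arbitrary
dropping. Calling is per strain on the median-of-replicates track.

**Difference logo.** Per column the height is the Jensen–Shannon
divergence (base 2, bounded by 1 bit) between the two strains' base
distributions; per-base signed contributions partition the height in
proportion to `p_mut(b) − p_wt(b)` (positive = overrepresented in the
mutant), so absolute contributions sum exactly to the height. The
*p*-value pools the two columns' base observations, reshuffles strain
labels preserving group sizes (a multivariate-hypergeometric split;
the smaller group is drawn so the result is invariant to argument
order), and applies the +1/(n+1) correction so *p* = 0 is impossible.
No pseudocounts are used: with tens of windows per strain zero cells
occur and the divergence stays finite (0·log 0 ≡ 0). The permutation
scheme implements the published description of the difference-logo
test; it is not a re-implementation of any particular package's
internals, and the per-base partition rule is this package's own
declared choice.

## Problem sizes in the test suite

The acceptance-level tests run the full read pipeline at study scale:
null calibration uses 200 repeats of 3 + 3 libraries × 10,000 reads;
the processivity- and sequence-recovery studies use 50 seeded runs of
3 + 3 libraries × 20,000 reads; difference logos use 1000 permutations
per column. On the 900-nt default unit these sizes give ~23 combined
counts per position and ~22 pause windows per strain — enough for the
qualitative recoveries to succeed in ≥95% of runs while the whole suite
stays desk-scale. `scripts/acceptance.py` uses the same sizes with a
30-repeat null study.

## Known limitations

- Exact-match alignment only; any sequencing error would drop a read.
- The per-position test assumes approximate normality of three
  replicate values; at very low counts its *p*-values are coarse.
- K-S calibration depends on library-composition stability (above).
- With ~22 windows per strain, permutation *p*-values are granular and
  single-column significance calls are weak evidence; the summed signed
  contributions over a label range (e.g. G over +1…+10) are the robust
  readout.
- The generator's eligibility rule (no partial fragments at the 5′
  edge) leaves the first `max fragment length − 1` positions structurally
  empty; analyses that average over the 5′ end should note this.
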