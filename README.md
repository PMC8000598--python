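# netseq-rdna

Single-nucleotide RNA polymerase I occupancy analysis for NET-seq
libraries on the ribosomal DNA transcription unit.

NET-seq (native elongating transcript sequencing) captures nascent
transcripts still held by the polymerase; the 5′ end of each sequenced
read marks the 3′ end of the nascent RNA — the last incorporated
nucleotide (LNT) — and therefore the polymerase's position on the
template at single-nucleotide resolution. This package implements the
analysis chain for comparing Pol I occupancy between two yeast-like
strains (e.g. wild type versus a transcription-elongation-factor
deletion) across the 35S transcription unit (ETS1, 18S, ITS1, 5.8S,
ITS2, 25S, ETS2):

1. **Preprocessing** — exact PCR-duplicate removal, anchored matching of
   the 5′ library format `AG + NNNNNNNN (UMI) + TG` with 12-nt prefix
   removal, and trimming at the 3′ linker `CTGTAGGCACCAT`.
2. **Occupancy** — exact-match alignment to a two-copy toy rDNA locus,
   per-position counting of read 5′ ends by strand (the plus-strand
   count at position *i* is the number of reads whose alignment starts
   there), summation of the two identical gene copies into one
   transcription-direction coordinate system, and normalisation of each
   track by its plus-strand total, so occupancy *oᵢ = cᵢ / Σⱼ cⱼ*.
3. **Comparison** — Spearman rank correlation ρ between replicate
   tracks; per-position two-sample *t*-tests (3 vs 3 replicates)
   classifying each coordinate as increased / none / decreased occupancy
   in the mutant; centred moving averages (windows 200 and 2000 nt); and
   two-sample Kolmogorov–Smirnov tests genome-wide and per region.
4. **Pause-site sequence context** — pause sites are the top 2.5% of
   median occupancy; ±30-nt sense-strand windows around each LNT (label
   −1) give per-column base frequencies, and a difference logo scores
   each column by the Jensen–Shannon divergence (bits)
   *JSD(p, q) = ½ KL(p‖m) + ½ KL(q‖m)*, *m = (p+q)/2*, partitioned into
   signed per-base contributions with permutation *p*-values (pooled
   label reshuffles, +1/(n+1) correction, significant if *p* < 0.05).

A synthetic-data generator with known ground truth drives all testing:
the LNT of each simulated read is drawn with weight
`(1 − δ)^x · exp(β · g(x))`, where `δ` is the per-nucleotide
premature-termination probability (processivity), `g(x)` the G fraction
of the 10 template positions downstream of `x`, and `β` the
pause–sequence coupling; libraries include PCR duplicates and
off-target reads.

## Worked example

```python
from netseq_rdna import (
    WT_PARAMS, SPT4D_PARAMS, generate_template,
    median_track, positionwise_comparison, spearman_concordance,
)
from netseq_rdna.pipeline import simulate_library_tracks

locus = generate_template(seed=1)            # 900-nt unit, two copies
wt  = simulate_library_tracks(locus, WT_PARAMS,    "WT",    3, 20000, seed=11)
mut = simulate_library_tracks(locus, SPT4D_PARAMS, "spt4d", 3, 20000, seed=12)

print(f"WT replicate concordance rho  = {spearman_concordance(wt[0], wt[1]):.3f}")
print(f"mut replicate concordance rho = {spearman_concordance(mut[0], mut[1]):.3f}")
result = positionwise_comparison(wt, mut)
print(f"genome-wide K-S p = {result.genomewide_ks[1]:.3g}")
print(result.positions["occupancy_class"].value_counts().to_dict())
```

prints (exact values depend on the seeds):

```
WT replicate concordance rho  = 0.340
mut replicate concordance rho = 0.892
genome-wide K-S p = 1.17e-73
{'none': 453, 'decreased': 287, 'increased': 160}
```

Spearman concordance measures how much *reproducible structure* two
replicates share: the synthetic wild type is nearly uniform, so most of
its between-position variance is multinomial noise and ρ is modest,
whereas the mutant's strong 5′→3′ occupancy gradient and sequence-driven
pause sites reproduce across replicates and push ρ toward 1. The
mutant's elevated termination probability piles polymerases up at the 5′
end and depletes the 3′ end: positions classed *increased* cluster 5′ of
positions classed *decreased*, and the genome-wide K-S test firmly
rejects equality of the two occupancy distributions.

The same pipeline is available from the shell:

```sh
netseq-rdna all --outdir out/ --seed 1 --n-reads 20000
netseq-rdna simulate --n-reads 20000 --seed 1 --outdir sim/
netseq-rdna preprocess --in sim/reads.fastq --out sim/trimmed.fastq
```

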