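# promarch

Promoter-architecture analysis of CAGE transcription-start-site data.

During oocyte growth, the general transcription machinery is rewired: a
TBPL2–TFIIA module takes over from canonical TBP/TFIID, and the promoters it
drives differ in kind, not just in level. CAGE (Cap Analysis of Gene
Expression) maps TSSs at single-base resolution, and contrasting a WT sample
against a knockout lacking the oocyte-specific factor reveals two promoter
codes: factor-**dependent** promoters that are *sharp* (initiation focused
on a few bases) and carry a TATA-like A/T-rich **W-box** around −30, and
factor-**independent** promoters that are *broad* and TATA-less. Some
promoters carry both codes and **shift** their TSS usage between
conditions.

`promarch` implements that comparison as a reusable, tested pipeline over
per-sample CTSS tables (`chrom  pos  strand  count`, 1-based):

1. **Subtraction** — WT positions that carry any mutant tags are removed,
   leaving the factor-dependent TSS set; the mutant set passes through as
   the independent set.
2. **Power-law normalization** — each sample's reverse-cumulative count
   distribution N(x) is fitted by least squares in log–log space on counts
   in [5, 1000] and quantile-matched onto a referent power law with slope
   α = 1.53 and total T = 10⁶ tags, giving tags-per-million (TPM). With the
   fitted law N_s(x) = B_s·x^(−α_s) and referent N_r(y) = B_r·y^(−α_r),
   B_r = T/ζ(α_r), each count maps to y = (B_s·x^(−α_s)/B_r)^(−1/α_r).
3. **TSS clustering** (distclu) — CTSSs ≥ 1 TPM join single-linkage along
   each (chrom, strand) at gaps ≤ 20 bp; singletons are kept only above
   5 TPM. Each tag cluster gets a dominant TSS (argmax TPM) and an
   **interquantile width** (the span between the 0.1 and 0.9 crossings of
   cumulative cluster signal) — small width = sharp promoter.
4. **Consensus clusters** — per-sample clusters ≥ 3 TPM, trimmed to their
   interquantile span, merge across samples at gaps ≤ 100 bp.
5. **SOM expression profiling** — per-cluster expression profiles (scaled
   to sum 1) above 3 TPM are mapped onto a 3×2 self-organising map,
   separating condition-specific promoter classes.
6. **Shifting promoters** — per-cluster cumulative TSS distributions of the
   two samples are compared with a two-sample Kolmogorov–Smirnov test
   (effective sample sizes from raw tag counts), selected at
   Benjamini–Hochberg FDR ≤ 0.01 with no score cutoff.
7. **Core-promoter motifs** — WW-dinucleotide (AA/AT/TA/TT) occurrence maps
   on −250/+250 windows ordered by width, best TATA-PWM relative match in
   the −35/−20 window (packaged JASPAR-derived TBP matrix), two-sided
   Wilcoxon rank-sum comparisons, and information-content matrices for
   sequence logos.

A synthetic-data generator (`promarch.synthetic`) produces genomes and
two-condition CTSS datasets with exactly this structure — Zipf-distributed
tag counts, planted W-boxes, sharp/broad/shifting promoter classes — plus a
ground-truth table, so every stage is testable by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study:

```bash
python analysis/01_simulate.py            # synthetic study -> results/study/
python analysis/02_run_pipeline.py        # full pipeline   -> results/pipeline/
python analysis/03_promoter_architecture.py
python analysis/04_shifting_promoters.py
```

`03_promoter_architecture.py` links clusters back to the planted truth and
prints:

```
median_iq_width_sharp_bp: 5.0
median_iq_width_broad_bp: 60.0
width_wilcoxon_p: 7.798913267567978e-188
median_tata_match_sharp_pct: 74.89
median_tata_match_broad_pct: 62.16
tata_wilcoxon_p: 9.521849237907143e-66
```

Clusters at true sharp W-box promoters are an order of magnitude narrower
than at true broad promoters (5 vs 60 bp median interquantile width) and
score markedly higher against the TBP PWM — the sharp/TATA vs broad/TATA-less
contrast the pipeline is built to expose. `04_shifting_promoters.py` shows
the KS detector recovering planted 50-bp shifts (92 of 96 scored shifting
promoters selected at FDR ≤ 0.01, median recovered offset 54 bp).

The same analysis is available as a CLI: `promarch simulate`, `promarch
run-all --wt wt.ctss.tsv --mutant mutant.ctss.tsv --genome genome.fa --out
run/ --seed 1`, plus per-stage subcommands (`subtract`, `normalize`,
`cluster`, `consensus`, `som`, `shift`, `motifs`).

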