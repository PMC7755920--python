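# Methods

## Data model and coordinate conventions

The atomic observation is a CTSS: one genomic position on one strand with a
raw CAGE tag count (≥ 1). Datasets are tables sorted by (chrom, strand,
pos) with unique positions; duplicate input rows are summed on read. CTSS
positions are 1-based (the CAGEr dialect); BED output is 0-based half-open.

Relative coordinates around a TSS use the no-zero convention: the TSS is
+1 and the first upstream base is −1, so a window written −U/+D contains
exactly U + D bases. This is the only convention under which the analysis
windows used here (−35/−20, −35/+5, −250/+250, W-box −31..−24) have
consistent sizes. Windows that leave the contig are padded with N rather
than rejected, so genome-edge promoters survive batch runs; N bases score
as background in PWM scans and are ignored in logo frequencies.

A note on the W-box: the motif is commonly described as a 7-bp element,
but the interval convention used throughout this package is −31..−24,
which spans 8 positions under the no-zero mapping; the interval is taken
as authoritative and the planted synthetic W-box is an 8-mer over {A, T}.

## Subtraction

To isolate factor-dependent transcription, every WT position that carries
tags in the mutant is removed outright — a position-set difference, not a
count subtraction. Counts at surviving positions are untouched. The
threshold for "present in mutant" is a raw count ≥ 1 by default
(`clustering.min_mutant_count`), exposed as config because the choice is a
judgment call on sequencing noise. Subtraction runs on raw counts, before
normalization; the pipeline order is fixed.

## Power-law normalization

CAGE per-position counts are approximately Zipfian. Each sample is fitted
by unweighted least squares on (log10 x, log10 N(x)) for counts x in
[5, 1000] with N(x) > 0, where N(x) is the number of positions with count
≥ x evaluated at distinct observed values; α_sample = −slope. Counts are
then mapped onto a referent law with α_ref = 1.53 and total T = 10⁶ by the
unique monotone transform equating the two reverse-cumulative laws:

    y(x) = (B_s · x^(−α_s) / B_r)^(−1/α_r),   B_r = T / ζ(α_r)

The referent intercept B_r is chosen so that the referent's total tag
count Σ_{x≥1} N_r(x) equals T (the identity Σ N(x) = Σ tags holds for any
count distribution); ζ is evaluated with scipy to full double precision
and cached. The transform is strictly increasing, so equal raw counts get
equal TPM and within-sample ranking is preserved. The defining, testable
contract is the refit: normalized values refitted in [5, 1000] give slope
1.53, and their sum lands near 10⁶.

When a sample has fewer than two distinct counts inside the fit range the
fit is degenerate and the pipeline falls back to simple tags-per-million
(count · 10⁶ / total) with a warning.

Two finite-sample caveats shape the package's standard study conditions
(n = 5·10⁵ positions, per-position counts capped at 150, exponent 1.9):

* the quantile map conserves total signal only when the sample's position
  count is comparable to the referent's own (B_r ≈ 4·10⁵ positions at
  T = 10⁶); far smaller samples lack the referent's low-TPM head and sum
  well short of T;
* the unweighted log–log fit is leverage-sensitive to sparse singleton
  points in the extreme tail (observed values whose expected N(x) ≪ 1 but
  realized N ≥ 1 by construction); capping the generator's count support
  keeps every fit point well populated and the fitted slope stable.

Both effects were characterised analytically and numerically before the
defaults were frozen; they are properties of the estimator, not of the
implementation.

## TSS clustering and sharpness

Clustering follows distclu semantics: CTSSs with ≥ 1 TPM (threshold
applied before clustering) join single-linkage along each (chrom, strand)
whenever consecutive passing positions are ≤ 20 bp apart. Single-CTSS
clusters are dropped unless ≥ 5 TPM. The dominant TSS is the argmax-TPM
position; ties break to the most 5′ position on the strand — the rule is
arbitrary but must be deterministic for reproducible sequence windows.

The interquantile width scans positions in genomic order and takes the
first position where cumulative signal reaches 0.1 of the total and the
first where it reaches 0.9; width = difference + 1. Widths are computed in
genomic order regardless of strand (they are strand-symmetric); dominant
TSSs and sequence windows are strand-aware. A small epsilon
(10⁻⁹ · total) guards the cumulative comparisons against float rounding at
exact quantile boundaries.

## Consensus clusters, expression, SOM

Per-sample clusters ≥ 3 TPM are trimmed to their interquantile span,
pooled across samples, and merged on (chrom, strand) when the gap is
≤ 100 bp; consensus bounds are the union of merged members. Merging is
idempotent. Consensus expression per sample sums all of the sample's CTSS
TPM inside the bounds — not only member-cluster signal — which is robust
to per-sample cluster fragmentation and gives shift scoring the full
per-position signal it needs.

Profiles with ≥ 3 TPM in at least one sample (mirroring the single-sample
pass rule used for clustering) are scaled to sum 1 and mapped onto a 3×2
self-organising map. The SOM is a standard online Kohonen map implemented
in-package: prototypes initialised from randomly drawn profiles, Gaussian
neighborhood with radius decaying linearly from max(xdim, ydim)/2 to 0.3,
learning rate 0.5 → 0.02, and 100 iterations per profile; training is
deterministic given the seed. The two condition-specific groups of
interest are labelled post hoc as the nodes whose prototypes put maximal
weight on each condition — reported as labels, never hard-coded node
indices, because node identity depends on the seed.

## Shifting promoters

For each consensus cluster with ≥ 3 TPM in both samples, per-position
cumulative TSS-usage fractions are computed 5′→3′ on the strand and
compared with a two-sample KS statistic D = max |F_dep − F_indep|. The
p-value is the asymptotic Kolmogorov tail with the Stephens small-sample
factor, λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n₁n₂/(n₁+n₂), with n₁, n₂
taken from raw tag counts (p-values need counts, not normalized signal;
`shifting.use_raw_counts` exposes the choice). Selection is BH-FDR ≤ 0.01
with the score threshold at −∞, i.e. KS-FDR-only. The reported shift
score — the signed cumulative difference (independent − dependent) at the
argmax position, positive when the dependent sample sits 3′ — and the
dominant-TSS offset with its 5′/3′ direction call are descriptive outputs
and never gate selection.

Tags within one cluster are not independent draws, and the asymptotic
formula on discrete positions is conservative under ties; the null
false-discovery proportion measured on all-null synthetic panels runs
well below the nominal FDR.

## Core-promoter motifs

WW (AA/AT/TA/TT) dinucleotide occurrence is scored per position on
equal-length oriented windows (last base unscored), rows ordered by
ascending interquantile width; quantitative tests run on the unsmoothed
0/1 matrix, with 2D Gaussian smoothing available for rendering only.

PWM scoring is log-odds with a 0.01 pseudocount per cell and uniform
background (both config): relative score = 100·(S − S_min)/(S_max −
S_min), so the consensus scores 100% and the per-column-worst sequence 0%.
The packaged TBP position frequency matrix is the JASPAR-derived profile
(15 columns); any JASPAR-format matrix is accepted. The best-match scan
takes the maximum over all starts where the motif fits fully inside the
−35/−20 window (16 bases, so a 15-mer has two valid starts).

Wilcoxon rank-sum comparisons use midranks for ties, exact enumeration for
n₁+n₂ ≤ 12 and the tie-corrected continuity-corrected normal approximation
otherwise. Logo matrices report per-position base frequencies and
information content IC = 2 − H bits with no small-sample correction.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical features the analysis exploits:

* **Expression**: per-promoter weights are inverse-CDF Pareto quantiles at
  ranks 1..n, w_r = ((r − 0.5)/n)^(−1/α) with α = 1.9 by default, so the
  weight CCDF is ∝ w^(−α) on a truncated support; tags are allocated
  multinomially (totals conserve exactly). A position-level sampler
  (`sample_power_law_counts`) draws i.i.d. counts with P(X ≥ x) = x^(−α)
  exactly for normalization studies.
* **Classes**: sharp promoters (Gaussian TSS spread, sd 1 bp) carry a
  planted W-box 8-mer over {A, T} at −31..−24 of the WT dominant TSS and
  are WT-specific; broad promoters (sd 25 bp) are mutant-dominated with a
  20% WT leak at the same positions, so subtraction has realistic work to
  do; shifting promoters are two sharpish components 50 bp apart used with
  opposite mixture weights (0.9/0.1) in the two conditions. A
  sharp-no-motif class is available to decouple sharpness from TATA
  content. Strand is uniform per promoter to exercise orientation code.
* **Study conditions**: 500 sharp + 500 broad + 100 shifting promoters on
  a 2 × 700 kb genome (42% GC), 10⁶ tags per condition.

The per-position count law of a simulated sample inherits the Zipf
exponent only where the library is deep enough that the weakest promoter's
peak count sits below the fit range; with sharp promoters (few positions
per promoter) the truncated weight support leaves floor artifacts in the
low-count region, so exponent-recovery tests use the broad class at
2·10⁶ tags where the law is clean. Not emulated: read-level artifacts
(mapping, the reverse-transcriptase G addition), carrier chemistry,
sequence-dependent initiation preferences outside the planted motif, and
biological replicate structure. Passing recovery tests therefore shows the
pipeline recovers planted structure from data satisfying its distributional
assumptions — not that real libraries satisfy them.

## Numerical and degenerate-input choices

* Empty mutant input: subtraction passes WT through; an empty sample flows
  through the pipeline as an empty normalized table rather than aborting.
* Degenerate power-law fit → simple-TPM fallback with a warning.
* SOM with < 2 profiles above threshold → error (profiling is skipped with
  a warning at pipeline level).
* Shift scoring skips clusters lacking 3 TPM in either sample; skipped
  clusters are absent from the results table, and BH adjustment runs over
  scored clusters only.
* All stochastic stages consume numpy `default_rng` seeds recorded in the
  run manifest; deterministic stages are bit-reproducible, and the
  manifest carries SHA-256 checksums of every output.

## Known limitations

* Equivalence with any particular external implementation of the
  normalization map is not claimed; the refit contract defines the
  behaviour.
* The KS p-value is asymptotic; no exact enumeration for tiny clusters.
* Consensus merging is interval-based and ignores per-sample dominant-TSS
  agreement; very long promoters can chain across a ≤ 100 bp gap.
* The SOM is a minimal online implementation; on degenerate inputs (all
  profiles identical) all profiles share one node, and node numbering is
  seed-dependent by design.
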