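# Methods

## Study design and model

The pipeline targets a two-pair near-isogenic-line (NIL) design: pairs 1 and 2
share a recurrent genetic background and segregate only for the allele
(recurrent F271 vs donor F288) at one introgressed QTL region. The default
layout is unbalanced — 2/1/2/2 replicates for classes 1^F271, 1^F288, 2^F271,
2^F288 (7 samples) — mirroring the field experiment in which one 1^F288
replicate was lost.

Counts for gene *g*, sample *s* follow a negative binomial with
`var = mu + phi * mu^2` and log link:

```
log mu_gs = log(effective library size_s) + x_s' beta_g
```

Effective library sizes are TMM-scaled column sums. The full design is
`~ allele + nil_pair + allele:nil_pair` with treatment coding (F271, pair 1
baseline), so the reported log2 fold change is F288 relative to F271.

### TMM normalization

Per sample against a reference (the sample whose upper-quartile count fraction
is closest to the mean), gene-wise log2 ratios M and average log abundances A
are formed over genes nonzero in both samples; genes in the top/bottom 30% of
M or 5% of A are trimmed; the factor is the inverse-variance-weighted mean of
the remaining M values (asymptotic binomial variances), and factors are
rescaled to geometric mean 1. A pure depth change therefore moves a sample's
library size, not its factor (exactly so for proportional columns; for noisy
columns the inverse-variance weights shift the factor by O(1/count)).

### Dispersion

A single common dispersion is estimated by maximizing the Cox-Reid adjusted
profile likelihood (`loglik - 0.5 log det X'WX` per gene) summed over a
deterministic, mean-stratified subsample of 200 genes, via bounded scalar
optimization of log phi on [1e-6, 10]. The Cox-Reid term matters here: with 4
coefficients on 7 samples, the unadjusted profile likelihood underestimates
phi by roughly the residual-df ratio. Per-gene dispersions default to the
common value; 7 samples do not support stable gene-wise estimation, and no
trended/tagwise empirical-Bayes machinery is attempted.

### GLM fitting and testing

Each gene's GLM is fitted by iteratively reweighted least squares at fixed
dispersion (working weights `mu/(1 + phi mu)`), declared converged when the
relative deviance change drops below 1e-8 (100 iterations maximum;
non-convergence is flagged on the result, never dropped). Linear predictors
are clamped to [-50, 50] so that structurally zero classes (SPE genes) reach a
stable boundary fit instead of diverging. Nested models are compared by the
likelihood-ratio statistic (deviance difference) against chi-squared — the
canonical GLM test for this setting; negative statistics beyond convergence
noise (1e-8 relative) raise an error, smaller ones clamp to zero.

### The stepwise procedure

* **Step I** (all 7 samples): LRT for the interaction (full vs additive
  model) and for the NIL main effect (additive vs allele-only), each
  BH-corrected at 0.05 across genes within its own family.
* **Step II** (per pair): allele vs intercept, BH at 0.05 within each pair's
  family.
* **Step III**: each pair's step II set minus every gene significant for NIL
  or interaction in step I.
* **Final**: intersection of the two step III sets. Direction is the sign of
  the per-pair allele log2FC and must agree across pairs; discordant genes
  stay in the final set but are excluded from the Up/Down lists (the contract
  must define the edge case even though concordance is the norm).

BH families follow the step structure (interaction, NIL, allele-pair-1,
allele-pair-2) rather than pooling all tests. Genes with zero total count are
removed before fitting; no expression filter is applied beyond that.

**Power note.** With a single replicate in class 1^F288 and dispersion 0.1,
the pair-1 allele test's asymptotic z for a 4-fold change is
`ln 4 / sqrt(phi (1/2 + 1/1)) ≈ 3.6`; after BH this caps joint (both-pair)
sensitivity near 0.5–0.65 regardless of sequencing depth (edgeR's
glmFit/glmLRT on identical simulated counts lands in the same range). The
procedure's strong guarantee under these conditions is *specificity* —
final-set contamination by NIL-only/interaction genes stays below 5% — while
sensitivity for 4-fold effects is power-limited by the design; 8-fold planted
effects are recovered at ≥ 80%.

### SPE calling

SPE_F288 requires count ≤ `max_silent` (default 0) in every F271 sample of
both pairs and ≥ `min_expressed` (default 1) in every F288 sample; SPE_F271 is
symmetric. With structural zeros this is exact; the thresholds exist for
contaminated libraries.

## Trait association

Expression is log2 CPM with pseudo-count 0.5 on TMM effective library sizes
(natural-log display is available for heatmaps; the analysis scale is a
configuration choice, as only monotone-linear transforms of class means enter
the correlations). Per-gene class means over the 4 genotype classes are
correlated with each trait; significance uses the exact inversion of
`t = r sqrt((n-2)/(1-r^2))`:

```
r* = t* / sqrt(t*^2 + n - 2),  t* = t quantile(1 - alpha/2, n - 2)
```

At n = 4, alpha = 0.05: r* = 0.9500. Correlating class means (n = 4) rather
than samples (n = 7) is the default because the significance rule is
instantiated at n = 4; per-sample correlation is available. Zero-variance
vectors yield an undefined r: the record is returned flagged not-significant
with r = 0 and a warning. r is clamped to [−1, 1] after floating-point
rounding to protect the sqrt(1 − r²) domain.

Heatmap ordering uses UPGMA (average linkage, Euclidean) via scipy; scipy's
internal tie-breaking is accepted as the deterministic rule.

## Co-expression network

Edges join gene pairs with |Pearson r| **strictly greater than** 0.995 over
the 4 class means; connected components of ≥ 2 nodes are labeled M1…Mk by
decreasing size (ties by lexicographically smallest member), and isolated
genes keep the label NA — reconciling a network that "incorporates" fewer
genes than its input list. Note the threshold is the published working value:
the exact t-rule at n = 4, alpha = 0.01 gives 0.990, not 0.995; both are
exposed (`threshold=`), the literal 0.995 is the default, and the discrepancy
is deliberately surfaced rather than resolved. Module–trait summaries count
genes with |r| > 0.95 for at least one trait, for the degradability trait
(IVNDFD), and for ≥ 2 of the trio {IVNDFD, Hcell/NDF, Cell/NDF}.

## Preferentially located motifs

Promoters are 1,000 bp upstream of the TSS plus the 5′UTR, on the coding
strand (minus-strand genes reverse-complemented at extraction so positional
logic is strand-free); UTRs shorter than 10 bp are excluded as likely
misannotated TSSs. Matching is IUPAC-degenerate, overlapping matches count, an
N in the sequence never matches, and scanning defaults to the promoter strand
(catalog motifs are conventionally strand-annotated), with `strands="both"`
reporting reverse-complement matches at their leftmost promoter coordinate.

Occurrence start positions are aggregated into width-W bins anchored at
−1,000. Rates are count/coverage, where coverage counts promoters spanning the
whole bin — so variable UTR lengths do not fabricate positional decay.
Ordinary least squares of rate on bin midpoint over the fully covered
background bins in [−1,000, −300) yields the background model, and a new bin
at midpoint x is compared against the 95% upper **prediction** bound

```
U(x) = a x + b + t(0.975, m-2) * s * sqrt(1 + 1/m + (x - xbar)^2 / Sxx)
```

(a mean-confidence band would over-flag, since the comparison is against a
single new bin observation). A motif is a PLM iff some search-region bin
([−300, max UTR)) with coverage ≥ 50% of promoters exceeds its bound; the peak
is the maximal-exceedance bin.

**Bin width.** The default is W = 100 bp. The exceedance rule applies an
uncorrected per-bin 95% bound across all search bins, so the per-motif
false-positive rate is roughly `1 - 0.975^(#search bins)`: at W = 10 (~30
fully covered search bins) that is > 50%, which would make the detector
useless as a screen; at W = 100 there are 3 fully covered search bins and the
measured false-positive rate on unplanted libraries is ~7%, with power ~1.0
for a planted bias (half of promoters, Gaussian position SD 15 bp). Width is
configurable (`width=`, must divide the 700 bp background region) and the
binning itself is exercised at W = 10 in tests.

## Enrichment

Upper-tail hypergeometric p-values, `P(X >= k)` for a term with K of N
universe genes hitting k of an n-gene list, via the regularized survival
function; BH across tested terms. The universe is every annotated gene
(configurable to an expressed-gene background, the statistically stricter
option); terms with zero hits in the list are not tested by default, which
sets the BH family size and matches common practice.

## Synthetic data

The generator is first-class, tested code that defines the conditions under
which the pipeline's statistical claims are verified:

* **Counts**: baseline means log-normal (meanlog 5.5, sdlog 1.5 — median ~245
  counts/gene, emulating tens-of-millions-read internode libraries scaled to
  2,000 genes); NB dispersion 0.1; library-size factors log-uniform on
  [0.7, 1.4] to exercise TMM. Categories are assigned by exact partition:
  allele-only genes shift the mean identically in both pairs (log2FC ±2 by
  default), NIL-only genes differ between pairs but not alleles, interaction
  genes express the allele effect in one pair only, and SPE genes are
  structural zeros (mean 0) in the silent class — "not measurable" is modeled
  as absence, not low expression — with the expressed-class mean floored at 50.
* **Traits**: linear combinations (coefficients ±1) of 5 allele-category
  genes' class-mean log2 expression plus Gaussian noise (SD 0.05), over the 4
  classes.
* **Promoters**: i.i.d. uniform ACGT, UTR lengths uniform on [10, 100], the
  planted motif (CATGTG by default) inserted at a Gaussian(−50, 15) position
  in half the promoters; decoy motifs are random hexamers never planted.
* **Annotations**: one term assigned to a chosen category with probability
  0.9 vs 0.05 elsewhere, plus uniform background terms.

All randomness flows from one integer seed; identical config + seed is
bit-identical. What the generator does **not** emulate: gene–gene correlation
beyond the planted class structure, GC/length biases, trended dispersion,
multi-environment phenotype variance, real promoter composition (repeats,
CpG/GC gradients) and motif co-occurrence. Passing tests therefore certify
the procedures' behaviour under their own model assumptions, not performance
on any particular real dataset.

## Numerical and design notes

* Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
  converted at the boundary. Missing values in delimited inputs are rejected
  rather than imputed — every downstream statistic assumes complete cases.
* Problem sizes in the shipped checks (2,000-gene simulations, 200-promoter
  libraries, 20–200 replicate libraries) are chosen so the full suite and the
  reproduction script run in minutes on one CPU while keeping Monte-Carlo
  error well inside the asserted margins.
* The packaged reference table is checksum-verified at load; its printed
  correlations, module labels and SPE flags internally reproduce the
  published summary counts (52/73 trends, module sizes 77/24/5/4/2/2/2, 54
  and 45 module-M1 trait counts) under this package's significance rule.
* `stepwise_sets_from_significance` exposes the pure set algebra of steps
  III–IV, including the reading in which a gene absent from step I cannot be
  cleared of NIL effects (`step1_tested`); `run_stepwise` tests every gene in
  every step, where both readings coincide.
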