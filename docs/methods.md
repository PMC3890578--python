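# Methods

## The replication gold standard

The framework's premise: *cis*-acting genetic regulation of gene
expression is among the most reproducible signals in transcriptomics, so a
catalog of previously established SNP:gene pairs should replicate in any
well-handled data set drawn from a comparable tissue. Every quality-control
or adjustment step is therefore scored by how it changes three replication
metrics, computed per processing condition:

* **%p<0.05** — the fraction of tested catalog pairs whose
  inflation-adjusted p-value falls below 0.05;
* **%q<0.05** — the fraction below 0.05 after Storey q-value conversion;
* **π₁ = 1 − π₀** — the estimated proportion of non-null catalog pairs.

Catalog pairs that cannot be tested (constant genotype after filtering,
too few samples) are excluded from all three denominators and reported
separately, so the metrics are fractions of *tested* associations.

### The association model

For a catalog pair (SNP *s*, gene *g*) the package fits ordinary least
squares of normalized log2 expression on minor-allele dosage (0/1/2) plus
a covariate matrix, dropping masked entries and missing genotypes
pairwise. The genotype t statistic is referred to a t distribution with
n − c − 2 degrees of freedom (c = number of covariates; intercept and
dosage account for the other two). The engine is a direct
normal-equations/least-squares solver because the scoring loop runs it
tens of thousands of times over small, per-pair sample subsets; the test
suite verifies it against statsmodels OLS to 1e-8 relative tolerance.

### Inflation adjustment

A genome-wide *cis* scan — all SNP:gene pairs with the SNP within 1 Mb of
either gene end (inclusive boundary; SNPs inside the gene body count;
strand ignored) — supplies the inflation factor
λ = median(χ²₁(p)) / 0.45494. Catalog p-values are genomic-control
adjusted: their 1-df chi-square quantiles are divided by max(λ, 1) and
mapped back through the survival function. λ < 1 is reported raw but never
used to deflate (standard genomic-control practice; the adjustment's
purpose is to correct overstatement, not to manufacture signal).

### Storey q-values

π₀ is estimated at a fixed tuning value λ₀ = 0.5:
π₀ = #{p > 0.5} / (m · 0.5), clipped to [0, 1]. q-values follow the
standard descending-minimum recursion
(q₍m₎ = π₀·p₍m₎; q₍i₎ = min(π₀·p₍i₎·m/i, q₍i+1₎)), which makes q monotone
in p and order-invariant. A fixed λ₀ (rather than the smoother-based
automatic choice) keeps the estimator stable at catalog sizes of a few
hundred pairs.

## Identity and contamination

**IBS DST.** For two genotype vectors over jointly non-missing SNPs,
DST = (N_IBS2 + 0.5·N_IBS1)/N, where IBS2 means identical calls, IBS1
calls sharing exactly one allele, IBS0 opposite homozygotes. Self-matches
approach 1.0; unrelated pairs in a homogeneous cohort sit near 0.7–0.8.
Identity fails only when the best match is not the labeled sample; a
correct best match with DST below 0.90 is flagged *borderline* and sent to
DR investigation — the two-stage logic keeps mild contamination separate
from outright swaps.

**Discordance Ratio.** Among RNA genotype calls that are heterozygous, the
fraction whose DNA genotype is homozygous. Clean deep libraries give
DR ≈ 0 (sequencing error only); DR ≥ 0.2 marks a library as contaminated,
and DR < 0.1 qualifies a library as a high-confidence input for mixing
calibration. Both thresholds are configuration defaults, not hard-coded.
A sample with *no* heterozygous RNA calls raises a distinct error rather
than returning 0, since an undefined ratio and a perfect one mean
different things.

**Het calling from RNA evidence.** Variant-caller internals are out of
scope, so RNA genotypes are called from per-site allele depths with a
simple depth-aware rule: heterozygous iff each allele has ≥ 2 supporting
reads and the minor allele carries ≥ 15% of reads; otherwise the majority
homozygote (ties to reference). Calls with ≤ 20 reads are withheld. The
rule reproduces DR ≈ 0 for clean high-depth libraries; it is a stand-in
for a consensus caller, not a reimplementation of one.

**Mixing calibration.** Read evidence from two high-confidence libraries
is combined at controlled purities (10:90 … 50:50, plus the unmixed 100):
per SNP, the target depth is the recipient's depth n; k ~ Binomial(n,
purity/100) reads are drawn without replacement from the recipient's
reads and n−k from the donor's. Mixing a library with itself, or at
purity 100, is an exact no-op. The mean DR per purity across clean pairs
forms a calibration curve; an observed DR is inverted against it (linear
interpolation inside the bracketing segment, ties at a knot resolving to
the lower-contamination endpoint; the curve is made monotone by a running
maximum before inversion so sampling noise cannot break it). DR at or
below the unmixed baseline reports "consistent with clean"; DR above the
most-contaminated point reports the top bin.

## Expression QC

**Normalization.** Two reference normalizers are built in, and any
externally produced log2 matrix can be ingested instead:

* `log2_depth`: log2(count / library_size × 10⁶ + 0.5) — depth only;
* `gc_quantile`: within-sample full-quantile normalization across 10
  equal-frequency GC bins (each bin's distribution mapped to the mean
  quantile function across bins), then between-sample full-quantile
  normalization, then log2 with a 0.5 offset. Ranks use midranks for
  ties, so results are exactly invariant to gene order. On generator
  fixtures this removes ≳ 95% of the GC trend in mean expression.

**Gene filters.** Two nested gene sets with inclusive boundaries:
*analysis* genes with summed log2 expression across samples ≥ 100, and
*decomposition* genes with summed counts ≥ 10 (used for PCA surrogates).

**Global sample outliers.** PCA with samples as observations and genes as
variables, centered, unscaled (the `prcomp` convention; component sign is
arbitrary). A sample is dropped iff any of its first 6 PC scores deviates
strictly more than 3 population SDs from that component's mean score.
Outlier statistics include the candidate sample (classical rule;
leave-one-out is available as a flag on the per-gene rule). The defaults
flag roughly one sample per 60 in null data — the expected 3-SD tail.

**Per-gene outliers.** Per gene, values strictly more than 3 population
SDs from the gene's mean are masked from that gene only. The rule is a
single, non-iterative pass: because excluding a flagged value shrinks the
SD, a second pass can occasionally add flags (about 0.3% of genes on null
fixtures); iterating to convergence would drift toward over-masking, so
the single pass is deliberate. Zero-variance genes and genes with fewer
than 3 usable samples produce no flags. Masked entries are excluded from
every downstream statistic and imputed by the gene's unmasked mean only
inside PCA decompositions, which cannot skip entries.

**Surrogate covariates.** PC scores over the decomposition genes, after
masking. SVA/ISVA/PEER-style factors are accepted as externally supplied
matrices; their algorithms are out of scope. Surrogates are recomputed
after every sample-drop stage, since scores depend on the retained sample
set.

## Pipeline order

normalize → PC outlier removal → identity/DR checks (drop swaps, then
contaminated) → renormalize on retained samples → per-gene masking → gene
filters → surrogates → replication per covariate condition → comparison.
RNA samples are matched against *all* DNA samples, including dropped
ones, so a swap with an already-removed donor remains detectable. The run
manifest accounts for every sample (initial = retained + dropped, one
reason each) and echoes all thresholds; wall-clock timings go to a
separate sidecar so the manifest is byte-reproducible. Known covariates
for eQTL conditions are age, sex and site/cohort (one-hot beyond two
levels); case status is excluded from eQTL covariates and used only by
the differential-expression check.

## The synthetic-data generator

No public generative model exists for the paired genotype/RNA-seq data
this pipeline consumes, so the generator's distributions are this
package's own choices, documented here.

* **Genotypes**: Hardy–Weinberg calls at MAF uniform on (0.05, 0.5],
  SNP positions uniform over two synthetic 40 Mb chromosomes (~37 SNPs
  per Mb, so every gene has *cis* SNPs and most SNPs are *trans* to any
  given gene). Defaults: 60 samples, 3,000 SNPs.
* **Expression**: per-gene latent log2 value = baseline N(7, 1) +
  additive eQTL effects (effect × dosage) + per-(gene, site) batch effect
  N(0, batch_sd) + a smooth GC/length bias whose slope varies per sample
  (so GC-aware normalization has something to remove) + N(0, noise_sd)
  measurement noise. Counts are Poisson around library-size-scaled
  proportions (library sizes uniform on 1–2 M), giving mean gene depths
  of a few hundred reads so counting noise (~0.1 log2 SD) sits below the
  0.25 log2 measurement noise. A negative-binomial layer was considered
  and omitted: the scoring framework is agnostic to the count law, and
  Poisson keeps the power analysis transparent.
* **Catalog**: 900 SNP:gene pairs by default, 30% carrying a planted
  effect of fixed magnitude 0.25 log2/allele with random sign (fixed
  magnitude keeps per-pair power well-defined; 0.25 puts the average pair
  near 90% power at n = 60, with low-MAF pairs substantially below — a
  deliberately mixed-power catalog). All catalog SNPs are placed within
  800 kb of their gene so the 1 Mb scan can always rediscover them; a
  planted effect outside the window is an error.
* **Contamination**: a recipient's *biological* expression profile is
  mixed with the donor's on the linear scale, and measurement noise is
  drawn after mixing — a mixed library is assayed once, it does not
  average two independent noise realizations. RNA genotype evidence mixes
  the same way: each read originates from the donor with probability
  equal to the contaminating fraction, then flips alleles at the
  sequencing error rate (0.5%). A fraction of 1.0 expresses a sample
  swap. Depth is Poisson(50) per site.
* **Outliers**: global outlier samples are shifted by a stated number of
  per-gene SDs with random sign per gene (a signed shift survives depth
  normalization, which a uniform shift would not); per-gene outliers
  shift single entries by 8 SDs at rate 0.001 by default.
* **Covariates**: age N(45, 15) clipped to [18, 90], sex Bernoulli(0.5),
  site uniform over 2 levels, status Bernoulli(0.4). Only site carries an
  expression effect by default; age/sex/status are plumbing for covariate
  designs and the differential-expression check.
* **Determinism**: every operation draws from its own stream seeded by
  (config seed, operation key), so each artifact is reproducible from the
  config alone regardless of call order.

What the generator does *not* emulate: isoform structure and splicing,
allele-specific expression, read-level alignment artifacts, library
degradation, cell-type heterogeneity, linkage disequilibrium between
SNPs, and population structure. Passing tests therefore demonstrate that
the statistics and decision rules behave as specified on data matching
the model's assumptions — not that the pipeline is robust to every
failure mode of real libraries.

## Numerical and design notes

* Population SD (ddof = 0) throughout the outlier rules; both 3-SD rules
  are strict inequalities, so a value at exactly 3 SD is not flagged.
  All other thresholds (≥ 100 summed log2, ≥ 10 counts, 1 Mb window) are
  inclusive.
* Genotypes are minor-allele dosage; missing genotypes are dropped per
  test; λ is clamped at 1 for adjustment but reported raw.
* The per-pair regression refuses rank-deficient covariate designs with
  an error naming the collinear columns, and distinguishes untested pairs
  (constant genotype, zero-variance expression, too few samples) from
  p = 1.
* The condition sweep reuses shared intermediates: normalization, outlier
  masks and surrogates are computed once per data configuration, and only
  the covariate design varies across replication conditions.

## Known limitations

* **Single-sample removal is nearly neutral by construction.** A sample
  contaminated at fraction f attenuates each pair's fitted slope by about
  f/n, so removing it restores roughly t·f/n of the statistic while
  costing t/(2n) in sample size — a net gain only when f exceeds ~0.5.
  Under the pure read-admixture model, dropping one 40%-contaminated
  sample therefore leaves the replication metrics essentially unchanged
  (directional win rates near chance), and the benefit of removal grows
  with the contamination burden and fraction. In real studies
  contaminated libraries tend to be degraded in ways beyond admixture,
  which is why removal helps more in practice than admixture alone
  predicts; modeling that degradation is out of scope here.
* π₀ estimation at fixed λ₀ = 0.5 is slightly conservative when many
  alternatives have moderate power (their p-values above 0.5 inflate π₀).
* The het-calling rule is a stand-in; DR values are comparable within a
  data set processed by one rule, not across callers.
* The GC-quantile normalizer is a simplified two-stage scheme, not a
  reimplementation of conditional-quantile or within-lane loess methods;
  externally normalized matrices can be supplied where those are wanted.
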