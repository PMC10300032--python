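# Methods

This note documents the models implemented in `mthetqtl`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Coordinates and the heteroplasmy model

All positions are 1-based inclusive on the circular MT genome. The default
length is 16571 (hg19 chrM); `mt_length=16569` switches to rCRS. The
control-region score windows are 16043–16238 and 16469–262; the second is
stored as a (start, end) pair with start > end and expanded into the two
arcs 16469–L_MT and 1–262, so it adapts to the configured length.

A site's alternate fraction uses the single most frequent non-reference
allele over total depth. When several alternate alleles are present the
minors inflate the denominator but are not scored; this keeps the
statistic a two-allele fraction, and ties are broken deterministically
(larger count, then lexicographic). Indel alleles are represented as
strings (`T-G` for a deletion of G after T, `A+CT` for an insertion), in
line with site names like `65_TG/T` used for control-region indels.

The heteroplasmic band is strictly open: `0.05 < f < 0.95`. Fractions at
exactly 0.05 or 0.95 are classified absent / stable variant and contribute
zero to every score. Zero-depth rows get status `no_coverage` with an
undefined (NaN) fraction rather than f = 0, so missing coverage can never
masquerade as confirmed absence. No minimum-depth or base-quality filter
is applied before calling; both are deliberate pass-throughs (the
amplicon designs this targets run at depths where binomial noise at
depth ≥ 500 keeps |f̂ − f| well inside the 0.05 band), and the pileup
reader exposes the raw counts so callers can impose their own.

The per-site presence rule and the windowed scores share one parameterized
band (`lower`, `upper`): for biallelic sites the "≥ 5% discordant reads"
presence rule and the 0.05–0.95 score indicator coincide, so a single rule
serves both.

## Association models

Logistic models are fit by iteratively reweighted least squares with Wald
z-tests, from first principles; ordinary least squares uses the closed
form with classical t-tests. Design matrices one-hot encode categoricals
dropping a reference level, drop constant columns, and drop samples with
any missing value (complete-case; no imputation). Rank-deficient designs
raise an error naming the collinear columns. Separation is detected as
coefficient divergence past |β| > 15 on the logit scale during IRLS and
reported as a flagged result with an infinite-estimate sentinel — a scan
over dozens of (variant, site) pairs must tolerate degenerate cells
without dying and without silently reporting a finite estimate.

hetQTL scans apply MAF ≥ 0.05 to variants and carrier count ≥ 5 to sites,
then BH-FDR jointly across all (variant, site) pairs — joint rather than
per-site adjustment is the more conservative reading and makes the
significant-site counts per variant comparable. The eQTL scan filters
genes to those detected (count > 0) in at least five samples, transforms
to log2(count + 1), and tests the genotype slope per (variant, gene) pair
with BH-FDR across pairs. A `cis_window` argument (default 1 Mb) exists
for generality; every MT variant–gene pair lies within it.

QC removes samples below 80% genotyping rate, duplicated genotype rows
(only when the panel has ≥ 5 variants, below which identical haploid rows
arise by chance) and sex-discordant samples when both reported and genetic
sex are available; variants with MAF ≤ 0.09 are removed. A
Hardy–Weinberg exact test (conditional on allele counts) is provided, but
the HWE filter is **off by default**: haploid MT calls coded as
homozygous diploids always show zero heterozygotes, so the diploid test
rejects every variant with two common alleles — the convention is
reproducible via `apply_hwe=True` but is not meaningful for MT data.

The total-heteroplasmy disease model is OLS of the per-sample count of
heteroplasmic sites on diagnosis plus covariates; a count this small
(0–9) gains nothing from a link function and the single p-value is what
is reported.

The heteroplasmy-score association regresses `het_total` on each SNP with
the first two genotype principal components as ancestry covariates. The
PCA mean-imputes missing calls, centres and unit-scales columns, and takes
left singular vectors — the standard GWAS stratification control.

Replication enrichment: with `n_tested` previously reported QTL pairs
testable in the new data, the null count of nominal hits at level α is
`n_tested · α` exactly, and the enrichment p-value is the exact binomial
upper tail P(X ≥ n_nominal). Sign concordance is computed over the
nominal hits against the reference effect directions. The binomial tail
assumes independent pairs; for LD-pruned reference panels that is the
standard approximation.

## Causal inference test

For trio (L, G, T) with covariates residualized out of G and T first:

* p1: F-test for L in G ~ L;
* p2: F-test for L in T ~ L;
* p3: partial F for L in G ~ T + L;
* p4: equivalence-style test of "L independent of T given G". The
  observed statistic is the partial F for L in T ~ G + L. Its reference
  distribution comes from semi-parametric permutation of the mediator:
  G\* = fitted(G ~ L) + permuted residuals, which preserves the L–G
  association while destroying any G–T information. If G truly transmits
  the L–T association, conditioning on the real G absorbs it (small
  observed F) while conditioning on G\* cannot (large permuted F), so
  p4 = (1 + #{F\* ≤ F_obs}) / (B + 1) is small exactly under mediation.
  Permuting L within mediator strata was considered and rejected: that
  scheme realises a conditional-independence null under which p4 is
  uniform for truly mediated trios, leaving the omnibus test unable to
  call causal chains.

The omnibus p is the maximum of the four components. Because the test
requires all four conditions simultaneously, the relevant null for error
control is the least favourable partial null (three conditions hold, one
at its boundary), under which the max-p statistic is exactly calibrated —
so the single-trio FDR is floored at the omnibus p and never undercuts it.
Across a collection of trios (network construction), q-values use the
plug-in permutation estimator: trait labels are permuted (preserving the
shared locus→anchor leg while voiding each candidate), the expected null
count at each observed omnibus p is averaged over replicates, and q =
expected/observed, floored at the trio's omnibus p, clipped to [0, 1] and
made monotone. For the permuted replicates the condition-4 statistic and
its reference share the same central-F limit, so p4 there uses the
analytic lower tail rather than a nested permutation — this keeps the
cost linear in the permutation count without changing the null behaviour.

Simulated operating characteristics at n = 300, effect 0.8, 200
permutations: causal chains called in ≈ 95–98% of replicates; independent
models (L → G, L → T, G ⊥ T | L) in ≈ 2%; reactive chains (L → T → G) in
≈ 0%; fully null trios at ≈ the nominal 5%.

Network construction anchors on a fixed mediator gene, screens candidates
by Pearson correlation with the anchor (p < 0.05 by default — testing
uncorrelated genes wastes permutations on trios that cannot satisfy the
conditions), and reports edges with q < 0.05 ranked by |anchor–candidate
correlation|, top 45 by default.

## Copy number

X/22 and M/22 abundance ratios are Z-standardized within assay batch
using the sample mean and the n−1 standard deviation; each batch needs at
least two samples. Group comparisons use Welch's unequal-variance t-test
(two-sided) with the mean Z difference as the estimate; Welch is the
safe default when nothing is known about variance homogeneity between
e.g. sexes.

## Synthetic cohorts

`simulate_cohort` draws, from a single seed:

* **Genotypes** — haploid calls for one causal variant (default position
  10398, A>G) carried by designated haplogroups (default one group at
  frequency 0.35), tag SNPs matching the causal allele with concordance
  0.95 (near-complete linkage, as haplogroup markers travel), and
  independent background variants with frequencies 0.10–0.45. An optional
  divergent-lineage block flips the non-causal panel for the last k
  samples, for stratification studies.
* **Heteroplasmy** — per (sample, site) presence ~
  Bernoulli(logistic(β₀ + β₁·g)) over nine control-region sites (five
  causal, default β₁ = 1.0, baseline prevalence 0.10), with fractions
  Uniform(0.06, 0.5) so every planted event is detectable under the
  0.05/0.95 rule.
* **Pileups** — per-position depths Poisson(500), alternate reads
  Binomial(depth, f) at heteroplasmic sites and Binomial(depth, 0.005)
  sequencing error elsewhere, covering exactly the two amplicon windows.
* **Expression** — negative-binomial counts (dispersion 0.2) for the 37
  MT-encoded genes with base means log-uniform on 50–5000; the target
  gene's mean is multiplied by 2^(effect·g), default effect −0.5.
* **Covariates** — diagnosis, study, sex, age at death, education, PMI,
  RIN, batch and ten standard-normal ancestry PCs, matching a brain-bank
  cohort's table.
* **Fragment quantifications** — two batches with distinct scale factors,
  10% log-normal noise, 2× X abundance in females, and an optional
  multiplicative genotype effect on the M fragment (default none).

What the generator does **not** emulate: read-level artefacts (mapping
error, strand bias, NUMT contamination), phylogenetically realistic
haplogroup trees, correlated expression networks beyond the planted
eQTL, or covariate–outcome confounding. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to the full messiness of cohort sequencing data.

## Problem sizes used in the automated checks

The statistical acceptance checks run at the scales the analyses are
designed for while staying desk-sized: 100–200 replicate cohorts of
n = 400 for hetQTL recovery and calibration, n = 60 for eQTL recovery
(the LCL-style design), 200 replicate trios of n = 300 with 200
permutations for CIT, and 60–100 replicates of the 30 + 30 copy-number
design. `scripts/acceptance.py` recomputes all of them from a single seed.

## Known limitations

* The mpileup parser handles the 6-column text dialect; BAM-level
  processing is out of scope by design.
* Base and mapping qualities are ignored (documented hook).
* The HWE convention on haploid data is reproducible but statistically
  meaningless (see above).
* The CIT cannot distinguish complete mediation from a pleiotropic locus
  whose two effects are perfectly correlated through an unmeasured
  variable — a limitation of the test itself, not the implementation.
* Mixed models, kinship, trans-eQTL scans and nuclear-genome eQTLs are
  out of scope.
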