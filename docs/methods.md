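# Methods

## Problem and model

`exprweight` tests whether the rare variants (minor allele frequency,
MAF < 0.01) in a gene are associated with a quantitative trait measured in
families, and uses paired gene-expression data to prioritise genes whose
rare-variant burden plausibly acts *through* expression. The pipeline has
three statistical layers.

### 1. Family structure and stratification

The trait vector over n related individuals is modelled as
Y ~ MVN(mu, Sigma), with Sigma a SNP-based genetic relationship matrix
(GRM). We estimate Sigma from a common-variant panel with the standard
(Astle–Balding/VanRaden) estimator

    Sigma_kl = (1/M) sum_m (g_km - 2 p_m)(g_lm - 2 p_m) / (2 p_m (1 - p_m)),

over the M markers with MAF at or above `kinship_maf` (default 0.05),
allele frequencies taken from the analysed sample itself. Premultiplying
by Sigma^(-1/2) (symmetric eigendecomposition, eigenvalues floored at
`eigen_floor` = 1e-6 because empirical GRMs are near-singular) gives
Y* ~ MVN(mu, I): individuals become exchangeable, which is what licenses
the permutation inference below. Population stratification is then removed
by taking ordinary-least-squares residuals of Y* on an intercept plus the
top K = 3 classical multidimensional-scaling axes of the standardized
genotype matrix (identical to principal-component scores; column signs are
fixed by the largest-magnitude loading so results are deterministic).

Two conventions here are analyst choices the data cannot decide:

* **GRM scale.** The matrix is on the "relationship" scale (self ≈ 1,
  parent–child ≈ 0.5), i.e. twice the kinship coefficient. Any global
  rescaling of Sigma rescales Y* uniformly and cancels in permutation
  p-values; the `scale` argument of `estimate_kinship` exposes it anyway.
* **Order of operations.** We transform first and residualize second, so
  the intercept and axis effects are absorbed after decorrelation.

### 2. Gene-level rare-variant test (sequential sum test with selection)

For a gene with k rare variants, the pooled regressor is
x = sum_i gamma_i SNP_i with gamma_i = v_i s_i, s_i in {+1, -1, 0}
(positive, negative, excluded) and per-variant weights v_i = 1. The signs
are selected greedily: initialize all +1, sweep the variants once in
genomic order, and at each position keep the value of s_i maximizing the
score statistic of x against the residualized phenotype, holding the other
entries fixed. The score statistic for the pooled slope reduces to
n·r² under the maximum-likelihood variance estimate; a constant x scores 0.
Ties prefer +1 over −1 over 0, except an exact +1/−1 tie (which the squared
statistic cannot break — always the case at k = 1) resolves to the sign of
the pooled covariance, so a lone negatively associated variant is coded −1.
Monomorphic variants are forced to 0.

Significance comes from B permutations of the phenotype (default 500); the
p-value is (b+1)/(B+1) with b the number of permuted statistics at or above
the observed one — never zero, with floor 1/501 ≈ 0.002 at B = 500. The
**selection is re-run inside every permutation**, so the optimism of the
data-adaptive sign search is part of the null distribution. Freezing the
observed signs instead (exposed as `reselect=False` for diagnosis only)
inflates the empirical type-I error from ≈0.05 to >0.2 in the regression
test that guards this choice. The number of greedy sweeps is configurable
(`passes`, default 1: deterministic and fast; additional sweeps start from
the previous selection).

Permutations are drawn from a per-gene RNG stream derived from the root
seed plus a CRC-32 hash of the gene id, so results are independent of the
order in which genes are processed.

### 3. Expression-informed weights and weighted-Bonferroni adjustment

For gene i with per-individual burden g_i (row sum of its rare-allele
counts) and each expression probe E_j, two OLS regressions are fitted on
the same decorrelated, residualized phenotype P the test uses:

    E_j = b0 + b_gE·g_i + c·P + e      ->  w_gE = (b_gE / SE)^2
    P   = b0 + b_EP·E_j + c·g_i + e    ->  w_EP = (b_EP / SE)^2

Standard errors use the unbiased (n−3) residual-variance estimator. The
crude weight of gene i is max_j (w_gE × w_EP): the product vanishes when
either link is absent and is amplified when the gene drives
phenotype-associated expression. Degenerate fits (constant regressor,
collinearity, zero residual variance with the coefficient inestimable)
yield weight 0 — "no usable expression evidence" — rather than an error.
All probes are scanned; there is no cis-window restriction.

Crude weights are divided by their mean over the tested gene set, per
phenotype, so normalized weights w* average exactly 1; rejecting genes with
p_i / w*_i ≤ alpha then preserves family-wise error control (FWER) for any
positive weights with mean 1. Adjusted p-values are min(1, p/w*). Because
genuinely causal variants may act without altering expression, results
carry two flags per phenotype — small raw p and small adjusted p — and
either warrants follow-up.

The phenotype entering the weight regressions is the decorrelated residual
(not the raw trait): family structure is then handled uniformly across the
test and the weights. Applying the regressions to raw traits would leave
family covariance in both standard errors.

## Synthetic data generator

The generator emulates a family sequencing study with paired expression:

* **Pedigrees.** `n_families` = 65 nuclear families of 2 parents +
  2 children (260 individuals, matching the scale of a ~260-person family
  study). Founders are unrelated; the expected relationship matrix (self 1,
  parent–child and sib 0.5, spouses 0) is returned for validation.
* **Genotypes.** Founder haplotypes are Bernoulli(MAF) per variant;
  offspring are produced by Mendelian gene-dropping with no linkage.
  Rare variants (target MAF uniform on 0.002–0.009, the open interval below
  the 0.01 threshold) are grouped into `n_genes` = 200 genes of 2–49
  variants; a separate panel of 5000 common markers (MAF 0.05–0.5) on
  another chromosome feeds kinship estimation, mirroring the use of a
  genome-wide panel. With rare alleles this sparse, some variants are
  realized monomorphic and some genes drop below 2 polymorphic rare
  variants; the pipeline's gene filter handles this as it would in real
  data.
* **Expression and phenotype.** Linear-Gaussian structural equations with
  per-gene truth labels: *causal chain* (E_j = b_gE·g + e, P += b_EP·E_j),
  *direct* (P += b_gP·g, expression independent), *reactive*
  (P += b_gP·g and E_j = b_EP·P + e — expression responds to the
  phenotype), and *null*. P additionally receives a polygenic family effect
  MVN(0, sd_A²·R) with R the pedigree-expected relationship matrix, and
  unit-variance noise; visit-level records add visit noise (SD 0.5,
  3 visits). A second measurement shares the genetic architecture with its
  own polygenic and noise draws; reactive probes track the first
  measurement.
* **Effect sizes.** Defaults b_gE = 2.5, b_EP = 1.0, b_gP = 1.0 per rare
  allele on the unit-noise scale. These are calibrated so that a typical
  causal-chain gene attains a raw permutation p-value in the 0.002–0.05
  range at n ≈ 260 with B = 500 — the regime the method is designed for:
  detectable single-gene signals that benefit from prioritisation, not
  trivially significant ones. Rare-variant effects of this magnitude
  (≈1–2.5 phenotypic SD per allele) are the standard "large effect, low
  frequency" assumption that motivates burden testing.

What the generator does **not** emulate: linkage disequilibrium among rare
variants, genotyping/imputation error, non-Gaussian trait distributions,
admixture beyond an optional two-population founder split, and
probe-level measurement artefacts. Passing tests therefore demonstrate the
statistical machinery (calibration, FWER control, power ordering) under a
clean linear-Gaussian data-generating process, not robustness to the messiness
of real cohorts.

## Simulation studies (tests and `scripts/acceptance.py`)

Problem sizes are chosen to characterise the method well on a single CPU:

* **Type-I error**: 500 independent null genes (2–49 rare variants,
  n = 300 unrelated individuals, B = 200); the rejection rate at
  alpha = 0.05 must fall in the 95% binomial band [0.032, 0.071].
* **FWER**: one 65-family genotype panel with 200 genes; 200 replicates
  each redraw null phenotype + expression (the decorrelation transform
  depends only on genotypes, so refreshing genotypes would add Monte-Carlo
  noise without changing the null), test all eligible genes at B = 99,
  build weights, and apply weighted Bonferroni at alpha = 0.05. The
  fraction of replicates with any rejection must not exceed alpha plus
  binomial slack. With a permutation floor of 0.01 at B = 99, a rejection
  requires a normalized weight ≥ m/(alpha·(B+1)) ≈ 39 — the observed FWER
  is conservative, as expected for weighted Bonferroni with estimated,
  mean-one weights.
* **Power ordering**: 200 fully fresh replicates of a 20-gene study with
  20% causal-chain genes at default effects, B = 499 (so the permutation
  floor 0.002 sits below the Bonferroni threshold 0.05/20 = 0.0025).
  Weighted power must be at least unweighted power; a one-sided binomial
  test on discordant causal-gene rejections must show no evidence in the
  opposite direction. In these runs the weighting roughly doubles
  causal-gene detections at the same family-wise error level (the exact
  powers per seed are what `scripts/acceptance.py` reports).

## Numerical choices

* Missing genotypes are mean-imputed (2×MAF per variant), preserving allele
  frequency; missing expression values drop that sample from that probe's
  regressions only.
* Multiallelic VCF records are rejected unless explicitly split.
* Degenerate designs are detected by condition number (>1e12 → weight 0);
  an exactly zero standard error is treated as inestimable (weight 0),
  while a numerically tiny one yields the intended "extremely large"
  weight for near-perfect fits.
* The greedy selection compares statistics on the unnormalised
  U²/(sᵀAs) scale: permutations of y preserve its variance, so the
  per-column normalisation cancels.
* Eigenvalue floor 1e-6 before Lambda^(-1/2); stratification axes are
  deterministic up to machine precision.

## Known limitations

* The single greedy pass can return a locally optimal sign assignment;
  the exhaustive 3^k optimum is only approached, never guaranteed
  (tests assert it is bounded by the exhaustive optimum and never below
  the all-+1 burden baseline).
* Permutation p-values have resolution 1/(B+1); genome-wide weighted
  Bonferroni at small alpha/m needs either large B or large weights.
* Weights are estimated from the same data used for testing; the FWER
  guarantee holds for weights normalized to mean 1, but power claims are
  conditional on the informativeness of the expression panel.
* The pipeline is complete-case across genotype, expression and phenotype;
  partial-overlap designs (expression on a subset) are a documented
  extension point, not implemented.
* Genes with ≥50 rare variants are excluded by design (effect dilution);
  a moving-window analysis for such genes is out of scope.
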