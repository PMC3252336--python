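# Methods

## The MB-MDR procedure

For a pair of bi-allelic SNPs, samples fall into 9 two-locus genotype
cells (cell index 3·g₁ + g₂ with allele counts g ∈ {0,1,2}; orientation is
fixed package-wide as 0 = homozygous major, 1 = heterozygote,
2 = homozygous minor).

**Step 1.** Each cell is tested against all remaining samples. Without
covariates this is the classical pooled-variance Student t-test (df =
n − 2); with covariates it is the Wald t of the cell indicator in an OLS
fit of the trait on intercept + covariates + indicator (df = n − q − 2).
The two coincide at q = 0, which keeps unadjusted and adjusted scans on a
single formula. Welch-type unequal-variance tests are deliberately not
used: the adjusted test is homoskedastic OLS, and internal consistency
between the unadjusted and adjusted branches matters more than robustness
to variance heterogeneity that the simulation design never generates.

**Step 2.** Cells with two-sided p < α₁ (default 0.1) are labelled H or L
by the sign of the statistic; everything else — including cells smaller
than `min_cell` or leaving fewer than `min_cell` samples in the comparison
group — is O (no evidence). The pair statistic is
max(t_H, −t_L, 0), where t_H is the test of the pooled H cells against the
rest and t_L likewise for the L cells, each with the same covariates as
step 1.

**Step 3.** Significance over all C(m,2) pairs is assessed by step-down
(free step-down) maxT: hypotheses are ranked by decreasing observed
statistic (ties broken by pair order for reproducibility), successive
maxima of each permutation's statistics are taken from the bottom of the
ranking upward, adjusted p for rank i is (1 + #{b : u_i^b ≥ T₍ᵢ₎})/(B + 1),
and monotonicity is enforced down the ranking. Pairs with adjusted
p ≤ 0.05 are declared significant. The single-locus variant uses the same
three steps on the 3 genotype cells of each SNP.

**Permutation scheme.** The trait vector is permuted as a whole and the
complete step-1/2 computation is re-run per permutation. Covariate designs
are fixed functions of the genotypes and are re-applied identically to
every permutation; permutations are sampled with replacement from the
permutation group, one independent substream per permutation spawned from
a single master seed. One caveat is inherited from the method itself: for
the selection-gated on-the-fly strategies the per-pair null hypotheses are
no longer exchangeable across pairs, so the maxT assumptions are strained;
this behaviour is reproduced, not repaired.

## Vectorised implementation

Both step-1 and step-2 tests are Wald statistics of a 0/1 indicator, so by
Frisch–Waugh–Lovell the whole scan reduces, per pair, to two slim matrix
products: the 9-column one-hot cell-membership matrix (a function of the
genotypes only) and the trait matrix (observed column plus all B
permutations) are residualised on the covariates, and every statistic in
the scan derives from their 9 × (B+1) cross-product, the 9 × 9 Gram matrix
and per-column residual sums of squares. For unadjusted scans the Gram
matrix has the closed form diag(N) − NNᵀ/n and the centred trait matrix is
shared across pairs. One H02 replicate (n = 2000, 20 SNPs, B = 199) scans
in ≈ 0.2 s on one CPU; an on-the-fly adjusted scan costs roughly 3× that.
A scalar reference path (one OLS fit per test) implements the same
contracts readably, and the suite checks the two paths agree to 1e-9.

### Numerical conventions

* An indicator lying in the covariate span (residual norm² ≤ 1e-9) is
  untestable and contributes no label / a zero statistic — matching the
  scalar path, where the singular normal-equations fit returns no test.
* A perfect fit (zero residual variance) with a non-zero coefficient
  yields p = 0 with a warning (±∞ statistic), rather than aborting a scan;
  with a numerically zero coefficient (e.g. a constant trait) it is "no
  evidence", statistic 0.
* Rank-deficient residualisation designs drop dependent columns with a
  warning.
* maxT ties in the step-down ordering are broken by original pair order
  (stable sort).
* Bradley's interval is open; a rate numerically equal to an endpoint
  (relative tolerance 1e-12) counts as outside.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α₁ | 0.1 | step-1 cell-test level; larger values label more cells H/L |
| min_cell | 10 | smallest testable cell; the method's "sufficient sample size" rule, which has no canonical value — 10 gives ≥ 5 expected minor-allele homozygotes at n = 2000 even at MAF 0.07 and is exposed as a setting |
| B | 999 | trait permutations; adjusted p-values live on the grid k/(B+1) |
| FWER level | 0.05 | significance threshold on adjusted p |
| coding | additive / codominant | 1-column allele count vs 2-column genotype indicators in all screening and adjustment regressions; one scheme is used consistently per analysis |

## Simulation framework

Each replicate draws m SNPs (default 100) independently (linkage
equilibrium) from HWE genotype frequencies: SNP1 and SNP2 at shared MAF
p ∈ {0.1, 0.25, 0.5}, SNP3 and SNP4 at MAFs drawn per replicate from
U(0.05, 0.5) (their MAFs are design-free, so they are drawn like the noise
loci; exposed in the configuration), and the remaining SNPs at per-replicate
U(0.05, 0.5) MAFs. The trait is

y = d·P(g₁, g₂) + β₃·g₃ + β₄·1(g₄ = 1) + ε,  ε ~ N(0, σ²_e),

with P the binary mean pattern of model **M27** (high iff at least one
minor allele at both loci) or **M170** (high iff exactly one locus is
heterozygous), d = √(g²/Var(P)) scaling the two-locus genetic variance to
the target g² ∈ {0.01, …, 0.1}, β₃ = √(σ²₃ / 2p₃(1−p₃)) an additive main
effect, β₄ = √(σ²₄ / q₄(1−q₄)) with q₄ the heterozygote frequency an
over-dominant one, and σ²₃, σ²₄ ~ U(0, 0.06) drawn independently per
replicate. The environmental variance σ²_e = 1 − g² − σ²₃ − σ²₄ fixes the
total phenotypic variance at 1, so g² reads as broad-sense heritability of
the two-locus system. The low mean μ_L is fixed at 0 without loss of
generality. Null scenarios: **H01** removes the two-locus effect (d = 0)
but keeps SNP3/SNP4; **H02** removes every genetic effect. The full grid —
2 models × 3 MAFs × 5 heritabilities plus the two nulls at each MAF — is
36 settings; replicates are generated from per-replicate seed substreams
so any single replicate is reproducible in isolation.

What the simulator deliberately omits: linkage disequilibrium, genotyping
error, missingness, population structure, covariates, and non-Gaussian
environmental noise. Passing tests therefore demonstrate the statistical
mechanics of the method — error control, the coding contrast, the cost of
over-correction — under idealised marker data, not robustness to the
artefacts of real genotype panels.

### Analytic variance decomposition

With HWE cell probabilities f(i)f(j), the genetic variance of the scaled
pattern is the variance of the 9 cell means; per-locus main effects are
the variances of the marginal (conditional-mean) genotype values; the
additive part per locus is Cov(allele count, marginal mean)²/Var(allele
count) — the frequency-weighted least-squares line through the marginal
means — dominance the remainder, and epistasis the total minus the summed
main effects. All ratios are computed exactly, no simulation. The M170
pattern at MAF 0.5 has constant marginal means, hence zero main-effects
variance: the additive and dominance shares of the main-effects variance
are 0/0 there and are reported as NaN (the main/total and
epistasis/total shares, 0 and 1, remain well defined).

## Main-effect adjustment strategies

Residual-based selection runs on the original trait: `sr_perm` keeps SNPs
whose single-SNP regression F is maxT-significant at 0.05 (the permutation
null calibrates F across coding schemes with different df); `sr_alpha`
keeps raw p < 0.05; `sr_topk` the k smallest raw p (presets 5/10/15,
minimum 5 because four loci may carry main effects); `mr_aic` runs
bidirectional stepwise selection over SNP blocks (a SNP enters/leaves with
all its coded columns) under Gaussian AIC = n·ln(RSS/n) + 2·#parameters,
starting from the intercept-only model — the search start is exposed
(`start="full"`) since a full-model start is defensible but slower at 100
SNPs. An empty selection passes the original trait through unchanged.

On-the-fly adjustment enters coded columns of the pair under investigation
(`pair_always`), or of pair members flagged significant by a prior
single-locus MB-MDR scan (`one_d_significant`) or a maxT-corrected
single-SNP regression scan (`list_significant`), as covariates in both
MB-MDR steps; none, one or both pair members may end up adjusted for.

## Evaluation layer

Per replicate the scan yields a set of significant pairs; across
replicates these are summarised as power (causal pair detected), fp_any
(any other pair significant; under nulls this is the familywise type-I
error), and the SNP3/SNP4 pairing categories (SNP3 with a partner other
than SNP4, the specific SNP3–SNP4 pair, SNP4 with a partner other than
SNP3) that isolate main-effect leakage. fp_any counts replicates with at
least one offending pair, not per-pair events. Bradley's liberal
robustness criterion accepts an empirical rate inside the open interval
(α/2, 3α/2).

## Problem sizes used in the shipped checks

The package's own test suite and the acceptance script run the study at
desk scale, chosen so Monte Carlo error stays small relative to the
effects being demonstrated: familywise error under H02 uses 400 replicates
of n = 2000 with 20 SNPs and B = 199 (binomial standard error ≈ 0.011 at a
true rate of 0.05); the H01 inflation check uses 50 replicates with 50
SNPs; the coding contrast uses 50 replicates per coding with 20 SNPs; the
power check 50 replicates. The full-scale design (100 SNPs, 500
replicates, B = 999 across all 36 settings) runs through the same code
path via `mbmdr study` configuration files and is intended for
cluster-scale verification.

## Known limitations

* Interactions of order > 2, binary traits, and family designs are out of
  scope.
* The 2-parameter (−1,0,1)/(−½,½,−½) coding that represents additive and
  dominance scales jointly is not implemented; additive and codominant are
  the two supported schemes.
* maxT exchangeability is strained for the selection-gated on-the-fly
  strategies (see above).
* With B = 199 the smallest attainable adjusted p is 1/200; scans aiming
  at thresholds much below 0.05 need correspondingly larger B.
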