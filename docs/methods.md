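# Methods

## Scope

`greml` implements the GREML analysis chain for case-control traits:
genetic relationship matrices from SNP genotypes, restricted maximum
likelihood estimation of variance components (univariate, multi-GRM
partitioned, and bivariate), conversion of observed-scale case-control
estimates to the liability scale, sibling-recurrence-risk expression of a
liability heritability, a GWAS quality-control battery, and a
liability-threshold simulator used to validate every stage.  Genotype
imputation, eQTL discovery, variant annotation and ancestry matching are
out of scope; annotation sets enter only as boolean SNP masks.

## The estimation model

For `n` individuals and phenotype vector `y` (0/1 for case-control),

    y = X b + sum_j g_j + e,   cov(g_j) = sigma2_j A_j,   cov(e) = sigma2_e I,

where each `A_j` is the GRM of one SNP partition.  Off-diagonal entries are
the allele-frequency-standardised cross-products averaged over pairwise
non-missing SNPs; the diagonal uses the inbreeding-adjusted form, which
matches the cross-product diagonal in expectation under HWE (both options
are exposed and tested against each other).  Allele frequencies are
computed on the analysis sample after QC, with the counted allele fixed as
A1 throughout; missing genotypes are excluded pairwise via per-pair
denominators rather than mean-imputed.

### AI-REML

The restricted log-likelihood (constants dropped) is
`-1/2 [log|V| + log|X'V^-1X| + y'Py]`.  Components start at
`Vp/(m+1)`, take one EM step, then Newton steps on the average-information
matrix with step-halving whenever the likelihood would decrease.
Components are constrained to `>= 1e-6 * Vp`; a component pinned there is
flagged as a boundary solution (this floor is what produces the
`0.000001`-style estimates familiar from null analyses).  Convergence
requires both `|delta logL| < 1e-6` and a maximum relative parameter change
below `1e-8`, within 100 iterations.  Standard errors come from the inverse
AI matrix; variance shares (`h2` on the observed scale) carry delta-method
SEs.

Two numerically equivalent routes implement the same objective.  With a
single GRM, the model is rotated into the GRM's eigenbasis, where `V` is
diagonal and every iteration costs `O(n p^2)`; with multiple kernels (MAF
bins, annotations, chromosomes, the bivariate blocks) a dense Cholesky
route is used.  The two are cross-checked against each other, against a
grid-search/Nelder-Mead maximisation of the pure-definition likelihood
function, and against a finite-difference gradient check at the optimum.

### Likelihood-ratio tests

Testing a variance component pinned at zero uses the 50:50 mixture of a
point mass and chi-square(1), i.e. `p = 0.5 * P(chi2_1 > LRT)` (so an LRT of
exactly 0 reports p = 0.5).  The genetic-correlation test reports both the
two-sided chi-square(1) tail and its one-sided half, since both conventions
appear in practice.

### Liability conversion

`h2_liab = h2_obs * K^2(1-K)^2 / (z^2 P(1-P))`.  The factor is linear in
`h2_obs`, so the SE scales identically.  Prevalence-sensitivity grids
re-apply the transform across a range of assumed `K`.  Sibling recurrence
risk is computed from the bivariate-normal orthant probability at liability
correlation `a * h2_liab` (additive sharing only, `a = 0.5` for first-degree
relatives); the orthant probability uses scipy's bivariate normal CDF
(Genz's algorithm), validated against the arcsine closed form and a
10^7-draw Monte-Carlo oracle.

### Bivariate model

Two traits on disjoint samples sharing a SNP panel are stacked; `V` is
built from within- and cross-sample GRM blocks scaled by
`(sigma2_g1, sigma2_g2, cov_g12)` plus trait-specific residuals.  The
residual covariance is structurally zero — with no overlapping individuals
it is not identifiable — which matches the split-control design the model
is intended for.  `rg` outside [-1, 1] is clamped and flagged, never
silently truncated.  `rg` is reported on the observed scale; it is
invariant under the liability transform's linear rescaling.

## The simulator

The generator realises exactly the model the estimator assumes, so that
parameter recovery is a meaningful check of the estimation chain:

- Genotypes are independent biallelic SNPs in HWE (no LD), with MAF drawn
  from a configurable spectrum.  The default spectrum places 5% of SNPs in
  a rare tranche (MAF uniform on 0.005–0.05) and the rest uniform on
  0.05–0.5, mimicking a genotyping array with a modest rare tail; tranche
  support is confined to (0.001, 0.5].
- Causal effects are drawn per partition on the standardised-genotype scale
  (equal expected variance per causal SNP within a partition — the
  MAF-coupling the GRM itself assumes), and each partition's effect vector
  is rescaled so its squared norm equals `share * h2` exactly.  The
  residual is N(0, 1-h2), so liability variance is 1 by construction.
- Ascertainment: individuals are generated in chunks (default 10,000, up to
  100 chunks) and screened against the threshold `Phi^-1(1-K)`; cases are
  collected until the quota is met and controls are a uniform reservoir
  sample of the unaffected.  Only causal-SNP genotypes are materialised
  during screening; non-causal genotypes of retained individuals are drawn
  afterwards, which is distributionally exact because they are independent
  of liability.
- Bivariate presets draw per-SNP effect pairs from a bivariate normal with
  correlation `rg` before per-trait rescaling.
- The platform-artifact injector resamples a random SNP subset in one
  platform group at a shifted allele frequency, creating exactly the
  artifact class the QC platform scan is designed to catch.
- All randomness flows through named substreams spawned from one seed;
  every output is bit-reproducible.

What the simulator does **not** emulate: linkage disequilibrium (an
optional concern the joint-REML partitioning is designed to handle in real
data), demographic structure, genotyping error beyond the platform
artifact, and the X chromosome.  Passing recovery tests therefore
demonstrate the correctness of the estimation machinery under the model's
own assumptions, not robustness to LD or stratification in real cohorts.

### Shipped presets

| preset | h2 (liability) | K | structure |
|---|---|---|---|
| TS_GLOBAL | 0.58 | 0.008 | single partition |
| OCD_GLOBAL | 0.37 | 0.025 | single partition |
| TS_MAF | 0.58 | 0.008 | rare bin (MAF 0.001–0.05) share 0.21, remainder equal across the five common bins |
| OCD_MAF | 0.37 | 0.025 | rare-bin share 0, remainder equal |
| TS_GENIC | 0.58 | 0.008 | genic share 0.53 |
| OCD_GENIC | 0.37 | 0.025 | genic share 0.40 |
| TSOCD_BIVAR | 0.58 / 0.37 | 0.008 / 0.025 | rg = 0.41 |
| OCD_EARLY | 0.43 | 0.025 | single partition |

Case fractions default to the source cohorts' ratios (TS 617/4733, OCD
1061/5297, early-onset OCD 732/4717).  Causal counts default to 500 for
single-partition presets (80–100 per bin for partitioned ones) — a
polygenic but finite architecture; with effects normalised per partition,
recovery results are insensitive to this count.  The effect-size/MAF
coupling of real rare-variant architectures is unknown; presets encode
only variance shares, with the standardised-scale (alpha = -1) coupling as
the single implemented default.

## Quality control

Fixed filter order: SNP call rate (default 0.98) and monomorphic SNPs →
differential case/control missingness (two-sided Fisher exact, p < 0.05) →
Hardy-Weinberg exact conditional test (p < 0.05; cases+controls pooled by
default, controls-only available) → platform logistic scan (dosage term
Wald p < 0.001 adjusting for 10 PCs; non-convergent fits fail QC) → sample
call rate (0.999) → relatedness pruning (greedy removal of the individual
with most pairs above the pi-hat cutoff, ties keeping cases, then the
lexicographically smaller id).  pi-hat is operationalised as the GRM
off-diagonal, which coincides with IBD-based estimates in expectation on
unlinked common SNPs.  Because sample removal shifts the SNP-level
statistics, the battery iterates (bounded at 5 passes) until nothing more
drops, making the output a genuine fixed point.

A practical caveat for simulated panels: the GRM off-diagonal null noise is
about `1/sqrt(M)`, so with only a few thousand SNPs the conventional 0.05
pi-hat cutoff sits within ~2 sd of pure noise and will discard unrelated
individuals; small-panel demonstrations scale the cutoff up accordingly.
The HWE test is the exact conditional test without the mid-p correction,
for reproducibility.

## Validation designs and problem sizes

The replicate designs in `greml.designs` (used identically by the test
suite and `scripts/acceptance.py`) are sized to run comfortably on one CPU:
global, early-onset and six-bin MAF designs use n = 2,000 (at the source
cohorts' case fractions) with 5,000 independent SNPs and 10 replicates; the
bivariate design uses two disjoint samples of 1,000 with 15 replicates
(per-replicate r̂g noise is large at that size, sd ≈ 0.25); the genic
partition design uses n = 1,500 with 4,000 SNPs.  At these sizes the
Monte-Carlo standard error of a 10-replicate mean liability-h2 is ≈ 0.02,
of a partition share ≈ 1–2 percentage points, and of the 15-replicate mean
r̂g ≈ 0.06.

## Known limitations

- **Ascertainment bias of REML case-control estimates.**  Under strong
  ascertainment the observed-scale REML estimate combined with the linear
  liability transform is downward biased; the effect grows as K falls and
  the case enrichment P/K rises.  At the TS design point (K = 0.008,
  P ≈ 0.13, h2 = 0.58) the pipeline recovers ≈ 0.50 on average — about 13%
  low — while at the OCD design points (K = 0.025) recovery is within
  Monte-Carlo error.  This is a property of the estimator, not of the
  implementation: on the same simulated data a PCGC-style moment estimator
  (regression of standardised phenotype products on GRM entries, which is
  consistent under ascertainment) recovers the simulated 0.58, and on
  unascertained quantitative traits the REML fit is unbiased.  The package
  deliberately implements the classical REML + linear-transform route, and
  its tests document the bias rather than masking it.
- **Genetic-correlation inflation under double ascertainment.**  The same
  attenuation acts on both genetic variances in the bivariate model while
  the genetic covariance is less affected, so r̂g = ĉ/sqrt(v̂g1 v̂g2) is
  inflated when both samples are strongly ascertained: with the TS/OCD
  attenuations measured above, the expected inflation is ≈ 1.13, and the
  replicate designs observe mean r̂g ≈ 0.52 for a simulated 0.41 (the heavy
  right tail of the ratio at these sample sizes, with occasional clamps at
  1, adds to this).  Again a property of the estimator at these design
  sizes, documented rather than corrected.
- The bivariate model supports exactly two traits and no sample overlap.
- No LD-aware or MAF-weighted GRMs; no dominance components; no
  Haseman–Elston/PCGC estimator in the library surface (it appears only as
  an independent oracle in the tests).
- The per-SNP platform scan refits a logistic regression per SNP and is the
  slowest QC stage on large panels.

## Design notes

- The spectral single-GRM route and the dense multi-kernel route were kept
  as one engine with two backends rather than two fitters, so every fit
  shares the same convergence and boundary logic.
- The package is organised as a library plus narrative examples; the
  end-to-end flows in `greml.pipeline` are plain functions (file-driven
  variants write GCTA-style `.hsq` tables, TSV reports and a JSON run
  manifest), which is how the analyses are meant to be composed from
  Python.
- Permutation nulls keep covariates attached to individuals and permute
  only phenotype labels, preserving covariate structure under the null;
  PCs are computed once per analysis sample and reused across permutations.
- "% of total heritability" in partition tables is the component's share of
  the summed genetic components of the same joint model.
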