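# Methods

## Scope and model

`snpher` estimates the narrow-sense SNP heritability of a binary trait
from hard-call genotypes of nominally unrelated individuals. The
phenotype y ∈ {0,1} is treated as quantitative on the observed scale
under the linear mixed model y ~ N(Xβ, σ_v²A + σ_e²I), where A is a
genomic relationship matrix; h²_obs = σ_v²/(σ_v²+σ_e²) is transformed to
the liability scale with the standard threshold-model factor
[K(1−K)/z²]·[K(1−K)/(P(1−P))]. This treats disease as the exceedance of
a latent Gaussian liability at threshold t = Φ⁻¹(1−K); the factor both
moves the estimate to the liability scale and corrects for case
ascertainment (sample case proportion P above population prevalence K).
The transform is exact only under that generative model and is known to
degrade for strong ascertainment of highly heritable traits; at the
parameter ranges exercised here (h² ≈ 0.25, K ≈ 0.125, P ≤ 0.5) the
residual bias is well below the sampling error, which the
parameter-recovery test measures directly.

## Kinship

Two constructions are provided.

**Allele-sharing GRM.** A_ij = (1/m) Σ_k (x_ik−2p_k)(x_jk−2p_k)/(2p_k(1−p_k)),
with p_k the counted-allele sample frequency. Each variant is
standardized to unit variance, i.e. rare and common variants are assumed
to contribute equally to heritability (the α = −1 convention). Missing
calls are mean-imputed (their standardized value is 0) and every pair is
normalized by the full variant count; this matches mainstream GREML
tooling and keeps A positive semidefinite. A strict pairwise-deletion
mode (per-pair variant counts, not guaranteed PSD) is available via
`pairwise_missing=True`.

**LD-weighted GRM.** Variant j contributes proportionally to
[2f_j(1−f_j)]^(1+α) · ϖ_j · r_j relative to the unit-variance baseline.
The LD weights ϖ ≥ 0 minimise Σ_j (Σ_{k∈window(j)} r²_jk ϖ_k − 1)² over
sliding windows (default 50 variants, half-window stride, overlapping
solutions averaged), solved per window by non-negative least squares
with a 1e-6 Tikhonov ridge so that rank-deficient systems (e.g. perfect
LD) resolve to the minimum-norm solution: two perfectly correlated
variants get weight ½ each, an isolated variant gets weight 1. Info
scores r_j default to 1 and can be read from an imputation sidecar
table. α defaults to −0.25 for the LD-weighted model (its customary
value) and −1 reproduces the allele-sharing GRM exactly when weights and
info are unit — the cross-method identity the test suite asserts at
1e-10. The matrix is normalized by the sum of effective weights, which
reduces to 1/m in the unit-weight case and keeps the expected diagonal
at 1. Bit-compatibility with any external LD-weighting software is a
non-goal; the solver satisfies the qualitative contract (high-LD regions
downweighted) with a deterministic desk-scale algorithm.

## QC

Variant filters run in a fixed order — autosome, biallelic,
missing-rate > 0.10, MAF < 0.05 (strict inequalities, computed on
non-missing calls), Hardy–Weinberg exact-test p below a cohort-specific
threshold (1e-5 default; 1e-12 is conventional for very large imputed
cohorts) — and each variant is charged to the first filter it fails, so
report counts are deterministic and conserve totals. The HWE test is the
two-sided conditional exact test (the array-QC standard), computed on
all samples by default with a controls-only switch; the test suite
checks it against full rational-arithmetic enumeration for every
genotype configuration with ≤ 50 samples. Cross-cohort harmonization
intersects variants on (chromosome, position, unordered allele pair),
flips dosages where the counted allele differs, and drops
strand-ambiguous A/T and C/G variants whose aligned frequencies disagree
by more than 0.2.

## Relatedness pruning and PCs

Pruning is greedy: while any retained pair exceeds the cutoff, the
sample in the most violating pairs is removed (ties to the lower index).
The conventional cutoff of 0.025 identifies genuine relatives when the
GRM is estimated from ≥10⁵ markers, where the per-pair sampling noise is
far below it. At desk scale (m = 5,000) the noise sd is
≈ √(ℓ̄/m) ≈ 0.02 — at the cutoff itself — so applying 0.025 to a
synthetic cohort of unrelated individuals removes most of the sample for
no informational gain. Synthetic-cohort pipeline runs therefore use a
cutoff of 0.25, which still removes duplicates and first-degree
relatives; the cutoff remains a config field and 0.025 stays the default
for realistically sized marker panels. Ancestry PCs are eigenvectors of
the double-centered GRM scaled by √eigenvalue, computed with a
deterministic dense solver and a fixed sign convention
(largest-magnitude loading positive), so runs are bit-reproducible.

## REML

Variance components are estimated by restricted maximum likelihood in
the eigenbasis of A (one n×n symmetric eigendecomposition per fit; all
subsequent iterations cost O(np²)). From the initialisation
σ_v² = σ_e² = var(y)/2 the solver takes one EM-REML step (globally
stable) and then average-information updates with step-halving, so the
restricted log-likelihood is non-decreasing along the accepted path.
Components are clamped to ≥ 1e-6·var(y); a component held at that floor
with a downhill score is frozen and the AI step is solved on the free
coordinate (active-set step), which is what lets null fits slide cleanly
to the boundary while the residual variance still converges.
Convergence requires relative log-likelihood change < 1e-8 and parameter
change < 1e-6·var(y) (up to 100 iterations); the component covariance is
the inverse AI matrix at the optimum, and the SE of h²_obs follows by
the delta method. A kinship matrix with min eigenvalue < −1e-8 is
rejected; A ∝ I is rejected as unidentifiable (only σ_v²+σ_e² would be
estimable). The SE transforms to the liability scale by the same
multiplicative factor as the estimate, since the factor is a constant
given (K, P); P is the case proportion of the analysed (post-QC,
post-pruning) sample, and K is a required user input with no default.

## Synthetic cohorts

The generator emulates a two-way admixed case–control cohort with every
estimand known:

* **Allele frequencies.** Ancestral π_j ~ U(maf_floor, 1−maf_floor)
  (floor 0.05 so most variants survive the 5% MAF filter); subpopulation
  frequencies are Balding–Nichols Beta draws with mean π_j and variance
  Fst·π_j(1−π_j), clipped to [0.01, 0.99]. Default Fst = 0.1, the right
  order for a West-African/European contrast.
* **Admixture.** Per-sample ancestry fraction q ~ Beta(8, 2)
  (mean 0.8, sd ≈ 0.12), a generic two-way admixture stand-in.
* **LD.** Haplotypes follow a first-order Markov chain within blocks of
  20 variants (blocks independent) with target adjacent correlation 0.7
  at the sample's mixed frequency q·p1 + (1−q)·p2. The pairwise
  correlation is capped where needed so both transition probabilities
  stay in [0,1]; marginal frequencies are then preserved exactly rather
  than distorted by probability clipping. All blocks advance in one
  vectorised sweep, so a 10,000 × 5,000 super-population simulates in
  seconds.
* **Phenotype.** n_causal variants (default m/10) get standardized
  effects β ~ N(0, h²/n_causal); the genetic values are rescaled so
  their sample variance equals h² exactly — with a few hundred causal
  variants under LD the unscaled realized h² would wander by more than
  the ±0.02 the truth record promises. Environmental noise is
  N(0, 1−h²); case iff liability > Φ⁻¹(1−K). Optional age, sex and
  ancestry terms shift the liability so covariate and structure
  adjustment can be exercised; all three are off by default.
* **Ascertainment.** All cases are kept and controls subsampled until
  the target case proportion P is hit (±1 sample); the super-population
  is sized with a 1.3× margin so the binomial shortfall probability is
  negligible. Age-decile case/control matching (retain
  min(cases, controls) per decile within an age range) is provided for
  EMR-style cohorts.

Randomness derives from a single seed through named substreams
(frequencies, genotypes, phenotype, ascertainment), so a fixed seed
reproduces a cohort bit-for-bit and changing one stage's draws leaves
the others untouched.

What the generator does **not** emulate: realistic recombination maps or
LD decay calibrated to any particular cohort, imputation error (info
scores default to 1), rare variants (MAF < 1%), non-additive
architecture, and relatives (no family structure). Passing
parameter-recovery tests therefore demonstrate correctness of the
estimation machinery under a correctly specified liability-threshold
model with α = −1 architecture, not robustness to the many
misspecifications real cohorts add; the α-mismatch between generator and
LD-weighted model (−1 vs −0.25) is the one deliberate exception.

## Reference study conditions and problem sizes

The packaged validation runs use cohorts of n = 2,000 (1,000 cases /
1,000 controls) drawn from ~10,400-individual super-populations, with
m = 5,000 variants, true liability h² = 0.25, K = 0.125, P = 0.50; the
parameter-recovery check averages 10 independent cohorts and asks the
mean liability-scale estimate to land within ±0.06 of truth with ±2 SE
coverage in ≥ 8/10, the null check uses h² = 0, and the confounding
check adds an ancestry shift of 1 liability SD at Fst = 0.1. At these
sizes a single estimate carries an SE of ≈ 0.04–0.05 on the liability
scale, so the recovery tolerances are a little over one SE of the
10-seed mean.

## Numerical conventions

* Counted allele is BIM allele-1 throughout; all downstream math is
  orientation-invariant. Positions are 1-based; variant identity for
  harmonization is (chrom, pos, unordered allele pair).
* GRMs are stored in the GCTA binary triplet (float32 lower triangle)
  though computed in float64; PLINK BED I/O is SNP-major with the
  standard 2-bit coding.
* Internal phenotype coding is 0/1 (PLINK 1/2 translated at the disk
  boundary; −9/NA map to missing).
* Monomorphic variants are rejected by the kinship layer (QC removes
  them first in the normal flow); the HWE p-value of a monomorphic
  variant is 1 by convention.
* Eigen-decompositions use LAPACK's deterministic dense symmetric
  solver; no randomized methods anywhere, so every result is exactly
  reproducible for a fixed seed.

## Known limitations

Estimation assumes hard calls (no dosage uncertainty beyond the info
score), a single variance component (no partitioned GRMs), and
cross-sectional binary phenotypes. The LD-weight solver is a windowed
approximation; weights are not interchangeable with those of external
LD-weighting software. The greedy pruner guarantees a violation-free
retained set but not a maximum one (exhaustive search on small instances
shows it within 2 of the optimum). SEs come from the inverse AI matrix
and the delta method, which slightly understate uncertainty when a
component sits at the boundary.
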