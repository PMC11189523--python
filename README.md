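# snpher

SNP-based heritability estimation for binary traits in admixed
case–control cohorts.

Twin and family studies put the heritability of common diseases such as
type 2 diabetes anywhere between 25% and 80%; SNP-based methods estimate
the additive share captured by genotyped common variants directly from
unrelated individuals, by correlating genome-wide genetic sharing with
phenotypic sharing. `snpher` implements that analysis end to end for a
0/1 disease phenotype — variant QC, genomic relationship matrices,
relatedness pruning, ancestry principal components, restricted
maximum-likelihood variance components, and the liability-scale
transformation — together with a synthetic admixed cohort generator so
the whole pipeline can be validated against known truth without any
access-controlled genotype data.

## The model

Genetic sharing between individuals *i* and *j* is summarised by the
allele-sharing GRM

$$A_{ij} = \frac{1}{m}\sum_{k=1}^{m}
\frac{(x_{ik}-2p_k)(x_{jk}-2p_k)}{2p_k(1-p_k)},$$

with hard-call dosages *x* and counted-allele frequencies *p*. An
alternative LD-weighted GRM lets variant *j* contribute in proportion to
$[2f_j(1-f_j)]^{1+\alpha}\,\varpi_j\,r_j$, where the non-negative weights
$\varpi_j$ solve a windowed least-squares system that equalises tagged
signal across LD regimes (small weights in high-LD regions), $r_j$ is an
imputation info score, and $\alpha$ sets the assumed MAF–heritability
relationship. With unit weights, unit info and $\alpha=-1$ the two GRMs
coincide exactly.

The 0/1 phenotype is analysed as quantitative under

$$\mathrm{var}(y) = A\sigma_v^2 + I\sigma_e^2,$$

with $(\sigma_v^2,\sigma_e^2)$ estimated by AI-REML (one EM step, then
average-information updates with step-halving) and
$h^2 = \sigma_v^2/(\sigma_v^2+\sigma_e^2)$ on the observed scale. Because
case–control sampling enriches cases (sample case proportion *P* above
the population prevalence *K*), the estimate is transformed to the
liability scale:

$$h^2_{liab} = h^2\,\frac{K(1-K)}{z^2}\,\frac{K(1-K)}{P(1-P)},$$

where $z$ is the standard normal density at the liability threshold
$\Phi^{-1}(1-K)$. Fixed-effect models follow the usual ladder: Model 1
(intercept only), Model 2 (+ ancestry PCs 1–4), Model 3 (+ age and sex).

## Worked example

Simulate an admixed case–control cohort with true liability-scale
h² = 0.25, prevalence K = 0.125, ascertained to P = 0.50, then estimate
heritability with the allele-sharing GRM under Model 2:

```sh
$ snpher simulate --n 1000 --m 3000 --seed 42 --out demo
wrote 1000 samples x 3000 variants to demo.*

$ snpher h2 --bfile demo --covar demo.covar --model 2 --method gcta \
        --prevalence 0.125 --grm-cutoff 0.25 --out demo_h2.tsv
h2_obs = 0.2772 (0.0667)  h2_liab = 0.3131 (0.0753)

$ snpher h2 --bfile demo --covar demo.covar --model 2 --method ldak \
        --prevalence 0.125 --grm-cutoff 0.25 --out demo_h2_ldak.tsv
h2_obs = 0.2612 (0.0655)  h2_liab = 0.2950 (0.0740)
```

The first number is the observed-scale estimate with its standard error;
the second is the liability-scale estimate after the (K, P) transform
(factor ≈ 1.129 at K = 0.125, P = 0.5). Both methods recover the
generating h² of 0.25 within one standard error on this single cohort;
averaging over seeds tightens the recovery (see below). The LD-weighted
estimate is slightly more conservative, the expected behaviour when LD
is modelled explicitly.

The full pipeline (QC → GRMs → pruning → PCs → REML → liability scale,
both methods × three models) runs from a YAML config:

```sh
snpher pipeline --config run.yaml
```

and persists QC reports, GCTA-format binary GRMs, PC tables, REML
traces, and a results table per method × model.

Library use mirrors the CLI:

```python
from snpher import CohortConfig, generate_cohort, QCConfig, filter_variants, estimate_h2

g, y, covar, truth = generate_cohort(CohortConfig(seed=1))
g, report = filter_variants(g, QCConfig())
est = estimate_h2(g, y, covar, model="2", method="gcta", K=0.125)
print(est.h2_liab, est.se_liab)
```

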