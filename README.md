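# transmeta

Trans-ancestry meta-regression of GWAS summary statistics, with heterogeneity
partitioning, Bayes'-factor fine-mapping, and a reproducible simulation
harness.

## The problem

Meta-analysing genome-wide association studies (GWAS) across genetically
diverse populations increases sample size, but allelic effect sizes often
differ between studies in ways that are *correlated with ancestry* — through
population-specific LD with the causal variant, gene–environment interaction,
or differential imputation quality. Fixed-effects inverse-variance-weighted
(IVW) meta-analysis assumes a single shared effect and loses power (and
fine-mapping resolution) whenever that assumption fails; unstructured
random-effects models ignore the fact that genetically similar studies should
have similar effects.

`transmeta` aggregates per-study summary statistics with a weighted
**meta-regression on axes of genetic variation**. It is aimed at analysts
running multi-ancestry consortium meta-analyses from standard flat-file
summary statistics.

## The model

For each pair of studies, a distance is computed from effect-allele
frequencies over a thinned marker set (one marker with MAF ≥ 5% in every
study per 1 Mb bin):

    d_kk' = sqrt( Σ_j I_j (p_kj − p_k'j)² / Σ_j I_j )

Classical (Torgerson) multi-dimensional scaling of the K×K matrix **D**
yields T ≤ K−2 axes of genetic variation x_k per study. For variant j with
per-study allelic effects b_kj and variances v_kj, the meta-regression

    E[b_kj] = α_j + Σ_t β_tj x_kt,    weights w_k = 1 / v_kj,

treats the variances as known, so deviance differences are weighted-RSS
differences and give chi-squared tests that partition the evidence:

| test | statistic | df |
|---|---|---|
| association | X_assoc = Σ w b² − RSS_full | T + 1 |
| ancestry-correlated heterogeneity | RSS_intercept − RSS_full | T |
| residual heterogeneity | RSS_full | K_j − T − 1 |
| contribution of axis t | RSS_(drop t) − RSS_full | 1 |

An approximate Bayes' factor in favour of association, ln Λ_j = (X_assoc −
(T+1) ln K_j)/2, feeds single-causal-variant fine-mapping: posteriors
π_j = Λ_j / Σ_i Λ_i over a locus and the 99% credible set (ranked variants
accumulated until cumulative posterior ≥ 0.99). Fixed-effects IVW pooling
with Cochran's Q, and Wakefield-style approximate Bayes' factors with an
N(0, 0.2²) effect prior, are provided as the standard comparators.

The `simulate` module regenerates the method's operating characteristics
end-to-end: hierarchical Balding–Nichols allele-frequency drift over 26
populations in five ancestry groups, retrospective HWE case-control
genotypes under population-specific odds-ratios ψ, vectorised additive
logistic fits, mosaic-copying haplotype loci with population-specific LD,
and power / type-I-error / credible-set-calibration experiment runners.

## Worked example

One variant observed in six studies — three of one ancestry group with
effects near 0.2, three of another with effects near zero — fitted on a
single axis of variation that separates the groups:

```python
import numpy as np
from transmeta import fit_variant

betas = np.array([0.21, 0.18, 0.25, 0.02, -0.01, 0.04])
ses   = np.array([0.05, 0.06, 0.05, 0.05, 0.06, 0.05])
axes  = np.array([[-0.30], [-0.28], [-0.33], [0.29], [0.31], [0.31]])

res = fit_variant(betas, ses**2, axes)
```

prints (via the fields of ``res``):

```
alpha = 0.1178 (0.0215)
beta1 = -0.3266 (0.0707)
association:      X =   51.559  df = 2  P = 6.37e-12
ancestry het:     X =   21.340  df = 1  P = 3.85e-06
residual het:     X =    0.909  df = 4  P = 0.923
lnBF = 23.988
```

The variant is strongly associated overall; the effect declines along the
axis (β₁ < 0), so essentially all heterogeneity is ancestry-correlated
(P = 3.9×10⁻⁶) with none left over (residual P = 0.92).

The simulation harness shows why this matters. Under an African-specific
effect (ψ = 1.25 in the seven African-ancestry populations, no effect
elsewhere; 1,000 cases and 1,000 controls per population):

```python
from transmeta.simulate import run_power_experiment
res = run_power_experiment("african_specific", n_replicates=500, rng_seed=42)
print(res.rates.to_string(index=False))
```

```
           test    threshold   n  n_reject  rate    mc_se
 mr_association 5.000000e-02 500       496 0.992 0.003984
 mr_association 5.000000e-08 500       426 0.852 0.015881
 fe_association 5.000000e-02 500       448 0.896 0.013652
 fe_association 5.000000e-08 500        72 0.144 0.015701
mr_ancestry_het 5.000000e-02 500       496 0.992 0.003984
mr_residual_het 5.000000e-02 500        23 0.046 0.009368
      cochran_q 5.000000e-02 500       476 0.952 0.009560
```

At genome-wide significance the meta-regression detects the signal in 85% of
replicates against 14% for fixed effects, and its ancestry-heterogeneity
test (99%) outpaces Cochran's Q (95%) while the residual-heterogeneity test
stays at its nominal 5% level.

## Command line

```
transmeta axes            study1.txt study2.txt ... --pc 2
transmeta meta            study1.txt study2.txt ... --pc 3 --method both
transmeta finemap         --results meta.tsv --locus 11:2400000-3400000
transmeta simulate-power  --scenario african_specific --reps 1000 --seed 7
transmeta simulate-finemap --scenario homogeneous --reps 200 --seed 7
```

Input files are whitespace/tab-delimited with columns MARKERNAME CHROMOSOME
POSITION EA NEA EAF N BETA SE (remappable with `--cols`); studies are aligned
to a common effect allele with automatic beta/frequency flipping. All outputs
are tab-delimited with a `#` header recording the parameters and seed.

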