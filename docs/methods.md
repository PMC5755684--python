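# Methods

This note records the statistical model, the simulation engine, the numerical
choices, and the limits of what the bundled experiments can demonstrate.

## Meta-regression model

Per-study allelic effects b_kj at variant j are modelled as Gaussian with
**known** variances v_kj (the squared reported standard errors):

    b_kj ~ N( α_j + Σ_{t=1..T} β_tj x_kt ,  v_kj ).

Because the variances are treated as known, −2·log-likelihood differences
between nested models reduce exactly to differences of weighted residual sums
of squares with weights w_k = 1/v_kj, and the likelihood-ratio statistics are
chi-squared with the parameter-count degrees of freedom: T+1 for the joint
association test (all parameters vs none), T for ancestry-correlated
heterogeneity (axes vs intercept-only), K_j−T−1 for residual heterogeneity
(the full model's weighted RSS against its saturated limit), and 1 for each
single-axis deletion test. No residual scale is estimated — estimating one
would destroy these reference distributions.

With T = 0 the machinery collapses to fixed-effects IVW meta-analysis: the
association statistic equals the squared pooled z, and the residual statistic
equals Cochran's Q. This identity is enforced to 1e-10 in the tests and makes
the comparator module an independent cross-check of the regression path.

The axes x_kt are genome-wide study properties. Variants missing from some
studies are fitted on their contributing subset against the *same* global
axes (never recomputed per variant), with degrees of freedom using K_j. The
axes are mean-centred, so the intercept α_j is interpretable as the allelic
effect for a hypothetical study at the ancestry centroid.

### Axes of genetic variation

Distances between studies are root mean squared effect-allele-frequency
differences over a thinned marker set: one marker per 1 Mb bin, required to
be present with MAF ≥ 5% in **every** study (listwise completeness; the bin
representative is the qualifying marker nearest the bin midpoint, ties to the
lower position, so the selection is deterministic). Scaling is classical
(Torgerson): double-centre −½D², eigendecompose, scale eigenvectors by root
eigenvalues. Classical scaling operates on squared distances, so whether the
distance is stored as the root mean square (default, "Euclidean" scale) or
the raw mean square (`root=False`) has no effect on the axes; both are
exposed. T is capped at K−2 so the residual-heterogeneity test retains at
least one degree of freedom. Sign indeterminacy is resolved by making the
largest-magnitude entry of each axis positive. There is no automatic choice
of T: diverse consortia typically need 2–3 axes, and the experiment runners
default to T = 3 for the 26-population panel.

### Bayes' factors and credible sets

The approximate Bayes' factor in favour of association is

    ln Λ_j = ( X_assoc,j − (T+1) ln K_j ) / 2,

a BIC-style penalisation of the association chi-squared by the number of
fitted parameters over the K_j contributing studies. Posterior probabilities
over a locus assume a single causal variant: π_j = Λ_j / Σ_i Λ_i, computed
in log space (log-sum-exp) so association statistics in the hundreds do not
overflow. The 99% credible set is the smallest prefix of the Λ-ranked
variants reaching cumulative posterior 0.99; ties break on ascending genomic
position for deterministic output. For the fixed-effects comparator, the
Bayes' factor is the Wakefield approximation from the pooled (b, se) with an
N(0, 0.2²) prior on the log-odds ratio.

### Genomic control

λ is the median association statistic over the null chi-squared median at
the test's df, computed at the full multi-df statistic (the multi-df
mechanics are a package choice; the median-ratio convention is retained).
λ < 1 is reported but never used to sharpen evidence. Study-level control
inflates per-study variances by max(λ_k, 1) before aggregation; output-level
control divides the association statistic by λ and recomputes p-values and
ln BF.

## Input handling

Variant identity is (chromosome, position, unordered allele pair); marker
names are labels only, since they differ between cohorts. Coordinates are
1-based. The reference effect allele of a variant is taken from the first
study carrying it; other studies are aligned by flipping beta and
complementing the frequency when their orientation is reversed, and rejected
(`allele_mismatch`) otherwise. Strand-ambiguous A/T and C/G variants are
harmonised literally and flagged, never strand-corrected. Duplicate marker
rows within one file keep the first occurrence with a logged count. Rows
failing validation (non-positive SE or N, frequency outside [0,1],
unparseable numbers, malformed alleles) are dropped and tallied per reason in
the QC report. The presence filter keeps variants whose contributing studies
cover at least a fraction (default 0.5) of the total sample size, where each
study's size is its largest reported per-variant N.

## Simulation engine

The generator emulates a 26-population reference panel in five ancestry
groups (7 African, 4 Admixed-American, 5 East Asian, 5 European, 5 South
Asian; 1000 Genomes Phase 3 population codes), with 1,000 cases and 1,000
controls per population throughout — the sizes used by all bundled
experiments.

**Allele frequencies.** Ancestral frequency p₀ ~ Uniform(0.05, 0.95); group
frequencies drift by a Balding–Nichols Beta draw with variance
F_b·p₀(1−p₀); populations drift around their group value with F_w = 0.02.
The between-group F_b is per-group and deliberately unequal —
AFR 0.10, AMR 0.08, EAS 0.06, EUR 0.035, SAS 0.035 (star approximation:
pairwise group F_ST ≈ the sum of two branch values; AMR's large value
reflects its drifted Native-American ancestry component). Unequal drift is a
structural feature, not a tuning knob: with equal drift the five group means
form a near-regular simplex whose top-3 principal axes drop one group
contrast entirely, and the meta-regression becomes blind to effects specific
to the dropped group — unlike real continental panels, where three axes
separate all five groups precisely because drift magnitudes differ. Causal
variants are rejection-resampled until MAF > 1% in every population
(distance markers: MAF > 5%).

**Case-control genotypes.** Controls are multinomial from Hardy–Weinberg
proportions; cases from HWE tilted by ψ^g (retrospective rare-disease
sampling). This makes the additive per-population log-odds ratio
identifiable as ln ψ exactly, without committing to a prevalence model. The
per-population additive logistic fit is a vectorised two-parameter
Newton–Raphson on the 2×3 genotype count table (checked against statsmodels
IRLS to 1e-8); fits with monomorphic genotypes, missing phenotype classes or
separation (|b| ≥ 10 or singular information) are flagged invalid.

**Heterogeneity scenarios.** ψ vectors follow the verbal definitions:
homogeneous ψ = 1.10 everywhere (and a `null` alias with ψ ≡ 1);
african_specific ψ = 1.25 in AFR only; eurasian — no effect in AFR, ψ = 1.10
in EAS, ψ^½ in EUR/SAS/AMR; native_american — ψ ~ Uniform(1.15, 1.30) drawn
once per AMR population; non_ancestral — ψ = 1.35 in one random population
per group. All magnitudes are overridable.

**Fine-mapping loci.** A locus of n variants (default 64 over 1 Mb, causal
mid-locus) starts from an ancestral panel of 200 haplotypes built
site-by-site as a thresholded AR(1) Gaussian (correlation exp(−gap/100 kb)),
i.e. a first-order Markov chain with exact Bernoulli(f_j) marginals and
distance-decaying LD. Each group takes a bottlenecked subsample of 12 panel
haplotypes (drift ≈ 1/bottleneck between groups), and each population draws
its 240-haplotype pool by Li–Stephens-style mosaic copying over its group's
subsample with per-bp switch rate 1e-5 (switch probability 1−exp(−rate·gap)
between adjacent sites). Cohorts are haplotype pairs; cases are drawn with
probability ∝ ψ^g at the causal site. Variants whose fit fails in some
populations are aggregated over the fitting subset with zero weight
elsewhere.

**Experiment runners.** Axes are derived once per experiment from an
independent 2,000-marker drifted panel (their role as genome-wide study
properties), then applied to every replicate. All randomness flows from one
seed through named `SeedSequence` substreams (scenario, axes, frequencies,
genotypes, one per locus replicate), so runs are bit-reproducible and any
replicate can be regenerated in isolation.

## What the experiments do and do not show

The bundled experiments reproduce the method's operating characteristics at
the design scale: 1,000 replicates for type-I error and power, 200 replicate
loci of 64 variants (within-test comparisons use up to 96) for credible-set
calibration — sizes chosen to give binomial Monte-Carlo standard errors of
~0.7% on a 5% rate and ~1.5% on power, and to keep the full suite in tens of
seconds. Against those conditions:

* the 3-axis association test holds its size at P < 0.05 (measured 0.041 -
  0.049 across seeds, within three binomial SE of 0.05);
* 99% credible sets from meta-regression Bayes' factors cover the causal
  variant in ≥ 99% of homogeneous-scenario loci;
* under ancestry-restricted effects, meta-regression dominates fixed effects
  both in power (e.g. 85% vs 14% at genome-wide significance,
  african_specific) and in resolution (median credible set smaller by more
  than an order of magnitude, native_american), while the
  ancestry-heterogeneity test outpaces Cochran's Q.

Two deliberate gaps between the generator and real panels matter when
reading absolute numbers. First, the synthetic causal-frequency spectrum
(uniform ancestral frequency with drift, MAF > 1% rejection) carries less
average heterozygosity than a real reference panel's set of variants common
in *all* 26 populations, which concentrates at mid-frequencies; the
homogeneous-scenario power at ψ = 1.10 therefore measures ~67% here where a
1000-Genomes-based design reports ~80% — a property of the frequency
spectrum, not of the test (its noncentrality matches the analytic value for
the synthetic spectrum). Second, mosaic loci are far shorter than a real
2 Mb fine-mapping region (tens of variants, not thousands), so credible-set
*sizes* are comparable only as ratios between methods, never as absolute
counts. Calibration quantities (type-I error, coverage) transfer; absolute
power and set sizes do not.

Other limitations: single-causal-variant fine-mapping only (no conditional
dissection, no functional priors); no modelling of imputation error or
array-thinned genotypes; admixture is represented only through a drifted
group, not through individual-level mixture, so heterogeneity tracking
admixture *proportions* within a group is outside the generator's reach.
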