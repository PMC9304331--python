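# Methods

`jointgp` implements a joint-learning approach to genomic prediction for
polyploid grasses: continuous allele-proportion genotype codes, Bayesian
kernel regression models fitted by Gibbs sampling, an ensemble of
classification and regression feature-selection (FS) techniques whose
combined marker sets drive the final predictive models, and a simplified
breeding-program simulator that provides data with known architecture for
validation. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## Genotype encoding

Genotyping-by-sequencing (GBS) data from high polyploids resist discrete
dosage calling, so genotypes are encoded as **allele proportions**: at each
biallelic marker, reference reads divided by total reads, a value in
[0, 1]. Calls with fewer than 50 reads (`min_depth`) are set missing;
markers missing in more than 25% of individuals are removed; remaining
missing values are imputed with the per-marker mean, which preserves marker
means exactly. Depth masking is applied *before* the missingness filter (the
order is composable this way: a poorly covered call first becomes missing,
then the marker-level rule decides). Markers left with zero variance are
dropped by default (`drop_zero_variance=False` disables this): they carry no
information and degenerate the RBF bandwidth `theta = 1/(p * var(Z))` and
the Pearson screen. Trait responses (BLUPs or corrected phenotypes) are
min-max normalized to [0, 1].

## Bayesian genomic-prediction models

All models share `y = 1*mu + Z*gamma + e` with Gaussian residuals:

* **BRR** — one effect per marker, common prior `N(0, sigma2_g)`;
* **SM-GK** — a genetic value per individual with prior
  `N(0, sigma2_g K)`, where `K[i,i'] = exp(-(h/p) * d2(i,i'))` is the
  Gaussian kernel on squared Euclidean genotype distances, `h = 1`;
* **RKHS-KA** — kernel averaging: three Gaussian kernels as separate random
  effects. The printed bandwidth family "15M, 5M, 1M" is read as squared
  distances divided by `M` (the median squared Euclidean distance across
  genotypes, so the median pair sits at unit distance) with
  `h in {15, 5, 1}`; taking `h = 15*M` literally collapses the kernel to
  identity for any realistic `M`, so the normalized reading is used.
* Feature-selected markers can enter as a fixed-effect block `X*alpha` with
  a flat prior (the C3F/R3F construction); the kernel is then built from
  the remaining markers by the caller.

Variance components get scaled inverse chi-squared hyperpriors with 5
degrees of freedom and scales chosen so the prior mode splits var(y) evenly
between genetics and residual (`prior_r2 = 0.5`) — the convention of the
standard Bayesian GP packages. Chains default to 20,000 iterations with
2,000 burn-in; cross-validation studies shorten this to 4,000/500, which
moves 10-fold CV accuracies by well under the fold-to-fold noise.

Sampling is performed in a rotated basis: the thin SVD of `Z` for BRR (the
data constrain only the row-space component of `gamma`; the null-space
enters the variance update as a chi-squared draw), and the eigenbasis of
each kernel for the kernel models. One iteration costs O(rank), so chain
length is never the bottleneck. Held-out prediction for kernel models uses
**masked responses**: the kernel covers all individuals and test phenotypes
are treated as missing data, re-imputed from the model each iteration; the
reported prediction is the posterior mean of `mu + u` at the masked
individuals. BRR predicts out-of-sample as `mu + Z_new @ gamma`.

With `fixed_variances=(sigma2_g, sigma2_e)` the sampler freezes the
variance components *and* the intercept at the training mean; its posterior
mean is then exactly the closed-form ridge or BLUP solution on centered
responses, which the oracle tests verify to |error|/sd(y) < 0.02. (With a
sampled intercept the kernel's near-constant leading eigenvector mixes
slowly against `mu`; only the mu/u split is affected, not predictions.)

## Phenotypic intervals

Interval classes are built by clustering the 1-D trait vector with one of
nine strategies (Ward with/without squared dissimilarities — the ward.D2 /
ward.D distinction, implemented by feeding scipy's Ward linkage raw or
square-rooted Euclidean distances — single, complete, UPGMA, WPGMA, WPGMC,
UPGMC, k-means with 10 restarts). The cluster count is a plurality vote
over a fixed panel of eight indices evaluated for k in [2, 10]:
Calinski–Harabasz, silhouette, Davies–Bouldin, Dunn, C-index, Hartigan
(smallest k with H(k) <= 10), Krzanowski–Lai, and the gap statistic (20
uniform reference draws, seeded). Ties go to the smallest k. This replaces
a 30-index consensus from the original R tooling with an implementable,
deterministic panel; the exact per-trait cluster counts of the source
populations are therefore not reproducible and are not used as a test
surface. Classes are renamed 1..k by ascending class mean. On smooth
unimodal traits the panel often favors large k (many thin slices) — the
downstream FS only needs a stratification, not a "true" k.

## Feature-selection ensemble

Classification trio (target = interval labels): (i) L1-penalized linear
SVC (`C = 1`; a marker votes if any class-wise coefficient is non-zero),
(ii) per-marker one-way ANOVA F-test at p < 0.05, (iii) gradient tree
boosting (100 trees) with importance above the mean importance.
Regression trio (target = the normalized trait): (i) L1-penalized linear
epsilon-insensitive regression — an L1 linear SVR, implemented as
`SGDRegressor(loss="epsilon_insensitive", penalty="l1", alpha=1/(C*n))` —
(ii) the Pearson correlation test (t transform, n−2 d.f.) at p < 0.05,
(iii) gradient tree boosting for regression. No multiple-testing correction
is applied: the p < 0.05 screens are votes inside a 2-of-3 / 3-of-3
consensus, not inference.

Marker sets: C2/R2 (≥2 votes), C3/R3 (3 votes), ICR2 = C2 ∩ R2,
CR2 = C2 ∪ R2, CR3 = C3 ∪ R3; C3F/R3F reuse C3/R3 as fixed-effect blocks.
The subset relations (C3 ⊆ C2, CR3 ⊆ CR2, ...) hold by construction and
are asserted on every simulated run.

**Scalability choice.** Exact all-feature boosting splits cost minutes per
fit at 21,000 markers (measured: 623 s for a 3-class fit at n = 500 on one
CPU). The boosting technique therefore defaults to random feature
subsampling per split (`max_features="sqrt"`), which preserves the
importance-above-mean thresholding semantics and cuts the cost ~145-fold;
`gtb_max_features=None` restores exact splits for small panels (the unit
tests use it).

**FS scope.** The default protocol runs FS once on the full dataset and
then cross-validates on the reduced matrix — reproducing the reference
procedure, which leaks test phenotypes into selection and inflates
accuracy. `run_cv_joint(..., nested=True)` refits FS inside every training
fold for leakage-free estimates; a test asserts that on pure noise the
non-nested estimate exceeds the nested one (the selection-bias effect).

## Evaluation

10-fold CV repeated 50 times (stratified by interval labels for
classification) plus leave-one-out. Metrics: MSE per fold and Pearson R per
repeat over the concatenated held-out predictions (per-fold R is undefined
for LOO and noisy at small folds). Undefined R (zero-variance predictions)
is recorded as NaN and excluded from comparisons, with a count. Models are
compared by one-way ANOVA over per-repeat metrics, Tukey HSD at alpha=0.05,
and a greedy compact-letter display consistent with the pairwise
significance matrix.

## Breeding-program simulator

A line-breeding program stands in for a full stochastic simulator: 70
inbred founders; each year 100 biparental crosses produce 100 doubled
haploids (DH) each; a head-row nursery (h² = 0.1) keeps 10 per family; the
1000 PYT entries (h² = 0.2) feed 100 AYT lines (h² = 0.5) and 10 EYT lines
(h² = 0.67); next year's 70 parents are the EYT plus the best AYT lines.
After 10 burn-in and 10 recorded years the 10,000 recorded PYT lines (with
genotypes, true breeding values, PYT phenotypes and year) form the study
pool. DHs are produced as single recombinant gametes doubled, so no
heterozygote ever appears — genotype codes are {0, 2}, rescaled to allele
proportions {0, 1} for the pipeline.

Genome: 21 chromosomes × 1000 SNPs, 1 Morgan each, uniform spacing,
Poisson(1) crossovers without interference. Founder haplotypes draw
derived-allele frequencies from a discretized neutral 1/i spectrum with
independent sites. This is the simulator's main fidelity gap: real (or
coalescent-simulated) founders carry linkage disequilibrium and deep
ancestral structure, whereas here every marker tracks the same
pedigree/year structure. Consequently the all-marker Gaussian kernel
baseline is *stronger* than on coalescent-founder data, and the relative
advantage of feature selection at large n is smaller than the reference
simulation reports — the marker-reduction fractions reproduce well
(>99% at n = 100, ≈98% at 500, ≈96% at 1000), while the accuracy-gain
ratios at n ≥ 500 undershoot. A green marker-reduction test therefore
establishes the FS machinery; the accuracy-ratio tests document the
fidelity gap rather than a defect in the prediction models.

QTLs (default 100 per chromosome) are sampled among the SNPs and are also
observed markers. Additive effects are drawn zero-mean and the founder
genetic values standardized (nominal founder mean 4, variance 0.1 kept in
`SimConfig.trait_mean/trait_var`): this follows the stochastic-simulation
convention in which trait mean/variance, not per-locus effects, are
specified. `directional_effects=True` instead draws every effect from
N(4, 0.1) — a strongly directional allele-count architecture retained for
sensitivity checks. Stage noise is scaled against the standardized founder
genetic variance: noise variance = (1−h²)/h² − 0.2, with the GxE variance
0.2 realized as an i.i.d. deviation inside each phenotyping event, clamped
at zero where the stated heritability leaves no room (the printed
environmental/GxE variances and stage heritabilities are not jointly
satisfiable at a single scale; the stage heritabilities win).

## Numerical notes

* Kernel eigenvalues below `1e-10 * max` are truncated; kernels are
  validated symmetric PSD (tolerance `-1e-8`) unless validation is
  explicitly skipped inside CV loops where the kernel was built in-house.
* 1-D k-means matches the brute-force optimal contiguous partition on
  small fixtures (asserted); hierarchical labels come from
  `fcluster(..., criterion="maxclust")`.
* All stochastic components (samplers, simulator, k-means restarts, gap
  references, CV shuffles, FS seeds) are driven by explicit integer seeds;
  results are bit-for-bit reproducible given the seed.
* Everything runs single-threaded within ~8 GiB; the full breeding program
  takes ~25 s by sampling crossover plans first and materializing complete
  genomes only for nursery-selected lines.

## Known limitations

* No MCMC convergence diagnostics beyond chain means; no non-Gaussian
  likelihoods; single trait, single environment.
* The simulator omits dominance/epistasis, genomic-selection-driven parent
  choice, multi-trait selection and coalescent founders.
* The interval consensus panel is a stand-in for the original 30-index
  consensus; per-dataset cluster counts may differ.
* Accuracy ratios between feature-selected and all-marker models at large
  sample sizes are conservative relative to coalescent-founder simulations
  (see above).
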