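# Methods

This note documents the statistical models implemented in `popqtl`, the
synthetic-cohort generator that the validation studies run on, the
numerical choices made where the design was genuinely open, and the
limitations of what the passing tests demonstrate.

## Synthetic cohort generator

### Genotypes

Allele frequencies follow a two-level Balding–Nichols hierarchy. Each
variant has an ancestral frequency p0; a continental group's frequency is
drawn from Beta(p0(1−F_G)/F_G, (1−p0)(1−F_G)/F_G) and a population's
frequency is drawn the same way around its group frequency with parameter
F_P. Defaults F_G = 0.10 and F_P = 0.02 reflect typical human
continental-scale and within-continent differentiation. The default cohort
shape is 5 continental groups × 5 populations × 27–30 diploid individuals
(~725 samples), mirroring a 1000 Genomes-style design; every dimension
scales down for tests.

Genotypes are Hardy–Weinberg draws per population. Linkage disequilibrium
is induced per haplotype by latent Gaussians with compound-symmetric
correlation ρ within blocks of 10 variants, thresholded at the
frequency-matched quantile, so each site keeps its exact marginal
frequency. Two couplings matter:

* **Frequency coupling within blocks** (`block_freq_coupling`, default
  on): ancestral frequencies are anchored per block (jitter sd 0.05) and
  the Beta drift draws are comonotone within a block (drawn through the
  Beta quantile function at a shared uniform). Without this, independently
  drifting frequencies dilute the realized dosage correlation far below
  what the latent ρ suggests; with it, ρ = 0.95 yields mean adjacent
  dosage |r| ≈ 0.76, as in a real haplotype block.
* Turning the coupling **off** makes within-block LD differ between
  groups (each group's frequencies drift independently), which is the
  classic mechanism producing apparent effect-size heterogeneity of a tag
  variant. The heterogeneity studies use this mode deliberately.

### Expression

Expression is multiplicative in the allelic fold change: for causal
variant k with log2 aFC δ_k and dosage d, expected expression scales by
((2−d) + d·2^δ_k)/2, and independent signals multiply. Causal counts per
gene are truncated-Poisson on {0..5} (mean 1), effects are
Normal(0, 0.5²) capped at ±log2(100), and residual noise is lognormal with
sd 0.5 on the log2 scale — chosen so that most simulated effects are small
(sub-twofold), as molecular QTL studies consistently observe. Batch
(17 levels, log2 shifts sd 0.25), sex (log2 shift 0.2) and optional
group-level shifts act log-additively. When an exact between-group
variance fraction is requested (`group_var_frac`), the five group shifts
are centered and rescaled against the noise variance so the expected
one-way-ANOVA fraction equals the target. Optional per-group noise
multipliers emulate a serial-founder diversity gradient.

### Splicing

Intron-excision ratios come from a logistic-normal model per cluster
(2–3 introns): baseline logits Normal(0,1), an optional causal dosage
effect on one intron's logit (sd 1), per-sample logit noise sd 0.5,
softmax to ratios that sum to one within the cluster.

### What the generator does not emulate

Read-level count noise (expression is continuous, not negative-binomial),
realistic gene annotation and window overlap (each gene's cis block is
disjoint), coalescent LD (blocks are exchangeable, no distance decay
within a block), admixture, sex chromosomes, and missing genotypes.
Passing tests therefore demonstrate the statistical machinery under its
own modelling assumptions, not robustness to quantification artifacts of
real RNA-seq.

## Normalization

Features are kept when ≥ 20% of samples reach a value of 1 (count/TPM
unit); splicing additionally drops zero-variance introns and clusters
reduced below two introns. Each surviving feature is inverse-normal
transformed with rank offset 0.5 (Φ⁻¹((rank−0.5)/n), average ranks for
ties), giving bounded quantiles and exact invariance to monotone
transforms. Covariates are genotype PCs (from LD-pruned r² < 0.2
standardized dosages; default 5), phenotype PCs (default 15), one-hot
batch (reference dropped) and sex; collinear columns are dropped by
pivoted QR. Residualization is OLS per feature via a QR projection,
exactly idempotent. The calibration studies use only the known simulated
covariates (batch, sex, genotype PCs) rather than phenotype PCs, so that
the recovery being measured is not confounded by PCs absorbing the
planted signal.

## Variance partitioning

Per-feature one-way ANOVA R² on the residualized phenotype at the
continental-group or population level. The cohort-level null permutes
labels jointly across samples — the *same* permutation for every feature —
preserving inter-feature correlation in the null of the cohort mean;
p = (1 + #{perm mean ≥ observed})/(n_perm + 1), with floor 1/(n_perm+1)
(999 permutations → smallest reportable p of 10⁻³). The within-group
variance comparison pools per-feature per-group sample variances
(N = features × groups observations) into a gamma GLM with log link on
the group factor and reports the scaled analysis-of-deviance chi-square
with groups−1 df; a feature-level term is deliberately omitted to keep
the model identical across cohort sizes (the pooled and feature-adjusted
versions agree in direction on all simulated checks).

## Cis mapping

Nominal pass: simple regression per (feature, cis variant) with cohort
MAF ≥ 0.01 (missing dosages mean-imputed), two-sided t p-values.
Permutation pass: phenotypes are permuted (1,000 by default, one shared
set of permutation vectors across features within a call, as in the
FastQTL lineage), the per-permutation minimum p is collected, and
Beta(α̂, β̂) is fit by maximum likelihood; the gene-level effective p is
the Beta CDF at the observed minimum, with the raw empirical p retained
for auditing. Grouped (sQTL) mode takes minima over a gene's introns
inside each permutation. eGene calls are BH at 5% FDR on effective p; the
per-gene nominal pair threshold is the Beta quantile at the
q-boundary effective p (midpoint between the last significant and first
non-significant value). Pair selection tolerates a 10⁻⁹ relative slack
because the nominal and permutation passes compute the same p through
different floating-point routes.

## Fine-mapping

Sum-of-single-effects regression with L = 10 effects, fit on standardized
dosages and centered residualized phenotypes by iterative Bayesian
stepwise selection: each effect is refit against the residual left by the
others using the closed-form single-effect regression (per-variant Bayes
factors under a normal prior, uniform prior over variants, softmax to
inclusion weights). The per-effect prior variance is optimized by bounded
1-D maximization of the single-effect marginal likelihood, with the
previous value and zero always offered as candidates so every step is a
true coordinate ascent and the ELBO is monotone (asserted to 10⁻⁸).
Residual variance is updated as expected RSS / n. Convergence: ELBO
change < 10⁻³ (default), max 100 iterations, non-convergence returned
with a flag rather than raised.

Credible sets: per effect with prior variance above 10⁻⁹, the smallest
variant set by descending inclusion reaching 95% cumulative mass;
discarded when purity (minimum |r| among members) < 0.5; identical
memberships deduplicated. Lead selection: highest inclusion, ties broken
by higher MAF, then lower genomic position — fully deterministic.
Intron-level sets merge into gene-level sets by union-find over shared
variants (transitive closure); the merged score is the maximum inclusion
across sources and the lead is re-selected. The merge is provably
independent of input order (tested over all permutations of a chain).
Merging is by nonempty intersection rather than LD similarity — the
minimal reproducible rule; an LD-based merge would need an arbitrary
similarity cutoff.

## Allelic fold change

Joint bounded nonlinear least squares of log2 expression on
c + Σ_k log2(((2−d_k) + d_k·2^δ_k)/2) over all leads of a gene
(|δ| ≤ log2 100; trust-region reflective, xtol/ftol 10⁻¹²; δ initialized
at twice the marginal OLS slope). Standard errors by nonparametric
bootstrap over samples (default 100 resamples). Monomorphic leads are
flagged NaN and excluded from the fit. Estimation is dosage-based:
phasing adds nothing under the multiplicative model the generator and
estimator share. The pseudocount before the log transform defaults to 0
because the pipeline's expression scale is strictly positive; for
zero-inflated count data a pseudocount of 1 is the recommended setting
(`pseudocount=1`). Covariate adjustment for the aFC stage happens on the
log2 scale with the per-gene mean restored, so the fit sees a positive
scale with genetic effects intact.

## Population characterization

* **F_ST**: Weir & Cockerham (1984) variance components a, b, c per
  (focal group, other group) pair; θ̂ = a/(a+b+c). Pairs monomorphic in
  both groups are NaN, not zero; negative estimates are retained so means
  stay unbiased around zero under the null. "Mean F_ST against all other
  groups" is the arithmetic mean of the pairwise estimates (focal versus
  each other group), not focal-versus-pooled — the pooled version is a
  different estimand that shrinks with the number of groups.
* **Frequency classes**, evaluated in precedence order absent-EUR+AFR →
  absent-EUR → globally common (AF > 5% in every group) → other.
* **Differential expression**: equal-variance two-sample contrast of the
  focal group versus the rest per gene, BH q-values, p-ranked deciles
  (decile 10 = strongest DE). The F_ST–DE coupling reports decile means,
  a Mann–Whitney test of F_ST for DE (q ≤ 0.05) versus non-DE genes, and
  the rank-biserial effect size with a bootstrap percentile interval.
* **Interaction tests**: omnibus F-test of y ~ g + group versus
  y ~ g + group + g×group (single mode); joint mode adds additive dosage
  terms for every other lead of the gene to both models. Group main
  effects are always present. A lead is tested when its MAF is ≥ 0.05 in
  at least two groups; groups below 10 samples are excluded from the test
  rather than vetoing it. Bonferroni significance is α over the number of
  leads actually tested.
* **Constraint**: Mann–Whitney of the constraint score for eGenes versus
  non-eGenes; quasi-Poisson GLM (Pearson-χ² scale; the point estimate
  equals the Poisson MLE, dispersion only widens the SE) of credible-set
  counts on a top-decile-constraint indicator; Mann–Whitney of |log2 aFC|
  for top-decile versus other genes.
* **Replication**: a study-A credible set replicates iff it intersects
  the union of study B's credible sets for the same gene; genes with no
  sets in B are reported separately.

## Enrichment

Annotations are BED intervals (4th column = name), converted to 1-based
closed internally. The background is sampled from non-lead cis variants
matched to the leads on MAF decile and log10 |TSS distance| bin at 10:1,
relaxing to MAF-only when a joint bin is exhausted (warned, counted) —
matching removes the two confounders (frequency and promoter proximity)
that dominate naive backgrounds. Significance is a two-sided Fisher exact
test per annotation with Bonferroni over annotations (× deciles in decile
mode, where leads are binned by |log2 aFC| with decile 10 = largest).
Decile counts sum exactly to the marginal analysis.

## Validation studies (`popqtl.benchmarks`)

Study sizes were set so Monte-Carlo error is well inside each decision
margin on a single CPU in minutes: 100 random toys for estimator-oracle
agreement (tolerance 10⁻¹²); 1,000 Balding–Nichols variants × 2 groups ×
200 diploids for F_ST calibration; 200 single-causal genes (ρ = 0.9,
n ≈ 725) for credible-set coverage and 50 two-causal genes (|δ| = 0.5,
separated blocks, causal MAF ≥ 0.05 — a floor chosen because a detection
study is only meaningful for detectable variants; without it failures are
dominated by causals near MAF 0.005 that no method could find at this n)
for signal separation; a 3 × 4 MAF-by-effect grid at n ≈ 731 for aFC
error; 10 null cohorts of 50 genes for effective-p uniformity and 10
mixed cohorts (30 causal at |δ| = 1, MAF ≈ 0.3, n = 500; 70 null) for
empirical FDR; 1,000 single-causal genes for interaction type-I error and
200 two-causal same-block genes (F_G = 0.15, uncoupled block frequencies)
for the joint-model rescue; 200 genes at a 10% planted between-group
variance fraction; and 25 replicates of a 5:1 planted promoter preference
with a proportionally-straddling decoy whose expected fold is exactly 1.

## Known limitations

* The beta-approximated permutation p assumes the minimum-p null is well
  described by a Beta distribution; with very few cis variants or very
  strong LD the approximation is coarser (the empirical p is always
  reported alongside).
* Fine-mapping inherits the single-effect model's assumptions: purely
  additive effects, one variant per signal, Gaussian residuals after
  residualization.
* The quasi-Poisson dispersion estimate, bootstrap SEs, and the
  rank-biserial interval are all frequentist large-sample devices; at very
  small gene counts they are noisy.
* The pipeline is desk-scale by design: genotypes and phenotypes are held
  in memory, and no chunked or out-of-core path exists for biobank-scale
  inputs.
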