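# Methods

This note documents the statistical models implemented in `ccfrisk`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Cancer cell fraction inference

A somatic mutation observed with `alt` of `depth` reads in a specimen of
tumor purity ρ, at a locus of tumor total copy number `CN_t` (the normal
complement is assumed diploid, `CN_n = 2`), with `m` mutant copies per
mutated cell, has expected variant allele frequency

    v(c) = c · m · ρ / (ρ · CN_t + (1 − ρ) · 2)

where `c` is the cancer cell fraction. Multiplicity is point-estimated as
`m = clamp(round(vaf · D / ρ), 1, round(CN_t))` with
`D = ρ·CN_t + (1−ρ)·2`; this is the standard heuristic that treats the
mutation as present in either one copy or, when the VAF demands it, more.
It cannot distinguish a subclonal multi-copy mutation from a clonal
single-copy one — an identifiability limit of single-sample data, not of
the implementation.

The posterior over `c` is discrete: a uniform prior on the grid 0.01,
0.02, …, 1.00 and a `Binomial(alt | depth, v(c))` likelihood, with `v`
clipped to `(1e-6, 1−1e-6)`. The point estimate is the posterior mode
(ties broken toward the smaller grid value), `P(CCF > 0.9)` is the
posterior mass strictly above 0.9, and a mutation is called **clonal**
when that probability exceeds 0.5. If the supplied multiplicity implies
`v(1) > 1`, `m` is reduced to the largest consistent value and the case is
counted in a warning. The grid form was chosen over a conjugate
approximation because the clonality probability is then an exact finite
sum, directly testable against a brute-force evaluation.

Accuracy is information-limited at low purity: at ρ = 0.3 and 1000x depth
the CCF standard error near `c = 1` is ≈ 0.075, so a true clonal mutation
is called subclonal a few percent of the time no matter the estimator. At
ρ ≥ 0.7 (the stratum on which subclone structure is interpreted) call
accuracy exceeds 99% at 1000x.

### Subclone counting

Per sample, a 1-D Gaussian mixture is fitted to logit(CCF) by EM for
K = 1…6 components, K chosen by BIC (fixed random state; three
initializations). A variance floor (`reg_covar = 0.05`) prevents the
grid's point masses — e.g. the clonal peak at exactly 1.0 — from being
resolved as spurious components, and clusters whose back-transformed
centers lie within 0.1 CCF are merged, since the logit scale stretches
near 1 and can split one clone in two. Components with center below the
clonal boundary 0.9 count as subclones (the boundary deliberately reuses
the clonality rule's threshold). Samples with fewer than 5 mutations
return a flagged single-cluster model. This is a deliberately simple
stand-in for Dirichlet-process clone reconstruction: adequate for counting
well-separated clones (recovery ≥ 90% of seeds for centers ≥ 0.25 apart
with ≥ 30 mutations each), not for resolving overlapping ones.

### Clonality preference

For each gene, the number of subclonal mutations out of its total is
tested against `Binomial(n, f)` with `f` the cohort-wide subclonal
fraction, two-sided exact, BH-adjusted across genes. The null is the
cohort-wide fraction because no per-gene expectation is available from a
single panel; a gene mutated in unusually small (or large) clones then
stands out.

## Gene-level CCF matrix

Entry (sample, gene) is the **maximum** `ccf_point` over the sample's
mutations in that gene, 0 for wildtype, capped at 1. The maximum
represents the largest affected clone; mean or sum would conflate
recurrent mutation with clone size. Binarizing the matrix (> 0) yields
the mutation-status design used by the comparison screens.

## CCF-effect patterns

Genes mutated in ≥ 5% of samples are classified by a fixed cascade, most
specific pattern first:

1. **dose_dependent** — continuous-CCF Cox among carriers is significant
   (Wald, α = 0.05): the log-hazard scales with clone size.
2. **dominant** — otherwise, if the maximally selected rank statistic over
   candidate cutoffs (midpoints of observed CCFs within the inner 10–90%
   quantiles; ≥ 10 carriers required) has permutation p < α. The
   permutation of CCFs against outcomes accounts for the cutoff search.
3. **independent** — otherwise, if the mutant-vs-wildtype log-rank test
   has p < α.
4. **none** — otherwise.

The constituent tests are not multiplicity-corrected (they answer one
ordered question per gene); the flat univariable screens, by contrast,
report BH-adjusted FDR. The continuous-CCF Cox is fitted among carriers
only, so dose-dependence is not a restatement of the status effect. Note
the cutoff *location* from a maximally selected statistic is
high-variance: at a hazard ratio of 2 with 150 carriers, the estimated
threshold lands within ±0.1 of the truth in only about two-thirds of
replicates; detection (the permutation p) is much better powered than
localization.

## Survival-modeling core

All Cox machinery uses the **Efron** tie approximation, more accurate
than Breslow at panel-scale tie rates. Unpenalized fits use Newton–
Raphson with step-halving on the exact gradient and Hessian, converging
to gradient sup-norm < 1e-8; constant covariates are dropped with a
warning and monotone-likelihood separation is detected (runaway
standardized coefficient) and flagged rather than silently reported.

### SCAD-penalized selection

The SCAD penalty (shape a = 3.7, the canonical recommendation) is

    p_λ(β) = λ|β|                              |β| ≤ λ
           = (2aλ|β| − β² − λ²) / (2(a−1))     λ < |β| ≤ aλ
           = (a+1)λ²/2                          |β| > aλ

— lasso-like near zero, flat beyond `aλ`, giving sparse yet nearly
unbiased estimates. Fitting uses a local linear approximation: the SCAD
derivative at the current estimate supplies per-coefficient lasso weights,
and each weighted-lasso Cox problem is solved by IRLS (diagonal curvature
of the Efron log-PL) around glmnet-style coordinate descent (active-set
iteration with vectorized KKT checks, lazily computed Gram columns). LLA
iterates to coefficient convergence (max change < 1e-6, at most 10
rounds); a step-halving safeguard engages if the penalized objective ever
rises. Covariates are standardized internally; coefficients are returned
on the original scale.

The λ grid has 50 log-spaced values from λ_max (the smallest λ zeroing
all coefficients) down to 0.01·λ_max. λ is chosen by 10-fold
cross-validation, folds stratified by the event indicator, minimizing the
Verweij–van Houwelingen partial-likelihood deviance
−2·(ℓ_full(β₋k) − ℓ₋k(β₋k)). As a numerical safeguard the path stops
refining once a solution exceeds events/3 nonzero coefficients — a Cox
model denser than that is saturated at these sample sizes and never wins
the cross-validation — carrying the last solution forward so the deviance
curve stays finite on the whole grid.

### Stepwise BIC and stability

The SCAD-selected set is then filtered by backward–forward stepwise Cox
minimizing `BIC = −2·logPL + q·log(d)` with `d` the **event count** (the
standard effective sample size for Cox models); BIC ties break toward the
smaller model. Stability selection reruns the full two-step on seeded
70% subsamples and reports per-gene selection frequencies.

### Risk score, stratification, evaluation

The deployable model is the plain inner product of the final Cox
coefficients with the gene CCFs (no intercept). Recursive partitioning
splits the 1-D score greedily: at each step the leaf whose best
admissible split (≥ 15 samples per side) maximizes the standardized
two-group log-rank statistic is split, until three leaves. Groups are
labelled low/intermediate/high in ascending score order.

Discrimination is measured by the cumulative/dynamic time-dependent AUC
at a 36-month horizon with inverse-probability-of-censoring weights from
the reverse Kaplan–Meier (the scikit-survival estimator), with a seeded
200-resample bootstrap SE. Two AUCs on the same cohort are compared by a
paired-bootstrap Z-test — the difference of point estimates over the
standard deviation of paired replicate differences; exactly identical
scores return z = 0, p = 1, while zero variance with unequal AUCs is an
error. Kaplan–Meier curves (log-log 95% CIs), the k-group log-rank test
and the reverse-KM median follow-up are delegated to lifelines behind the
module's interface. The proportional-hazards diagnostic is the
Grambsch–Therneau scaled-Schoenfeld correlation test with KM-transformed
time, cross-checked against lifelines.

## Synthetic cohorts

The generator draws, per patient: purity ~ U(0.3, 0.95); 1–4 subclones
(weights 0.12/0.30/0.33/0.25, so 88% of patients carry ≥ 2) with CCFs
~ U(0.05, 0.85) beside a major clone at CCF 1; per-gene mutation
indicators (background probability 0.08; 0.15 for the eight planted model
genes; one mutation per mutated gene), each assigned to the major clone
with probability 0.3; locus copy number 2 except a 15% altered fraction
drawn from {1, 3, 4}; multiplicity 2 only for clonal mutations at
amplified loci (amplified mutations are typically truncal, and planting
subclonal multi-copy mutations would test the estimator against the
identifiability limit noted above rather than against noise); depth ~
negative binomial with mean 1000 and shape 25 (sd ≈ 200, floor 50); alt
reads ~ Binomial(depth, v). Mutations with fewer than 3 alt reads are
recorded in the truth but omitted from the emitted cohort, emulating
caller detection limits.

Disease-free survival is exponential with hazard
`0.022 · exp(βᵀ·CCF + 0.85·[pN = N2–3])` per month, the planted β being
the published eight-gene coefficients; censoring is the minimum of an
84-month administrative horizon and an Exp(mean 150) dropout time; overall
survival adds an Exp(mean 14) post-recurrence term. These defaults target
the source cohort's descriptors — 201 patients, 548 genes, ≈ 44 mutations
per patient, ≈ 70% subclonal mutations, ≈ 65% three-year recurrence, and
a nodal-stage hazard ratio ≈ 2.3. The low-depth preset changes only the
mean depth (55x, exome-like) to demonstrate the loss of subclonal
sensitivity.

What the simulator does **not** emulate: mutational spectra and hotspot
structure, phylogenetic constraints among subclones, purity estimation
error, copy-number segmentation error, matched-normal contamination, and
correlated censoring. Recovery results on these cohorts therefore show
that the estimators work when their assumptions hold; they do not
validate the biological model on real tumors.

## Problem sizes used by the test suite

The recovery checks run 20 simulated cohorts of 300 patients at the full
548-gene panel through the complete pipeline (CCF inference, CV-SCAD,
stepwise BIC, partitioning); calibration checks use 200–400 null
replicates at smaller n with 499 permutations per maximally-selected-rank
test. These sizes give stable Monte-Carlo estimates of the tested
proportions while keeping a full suite run on one CPU in the tens of
minutes.

## Known limitations

- Purity is taken as given; the bundled heuristic (2x top-decile VAF on
  diploid loci) is a flagged fallback, not an estimator.
- Multiplicity is a point choice; no minor-copy-number input, hence no
  LOH-aware inference.
- The pattern cascade assigns exactly one label; a gene with both a
  threshold and a dose component is labelled dose_dependent.
- The paired-bootstrap AUC Z-test is one concrete form of "compare two
  AUCs"; analytic alternatives exist and can differ in small samples.
- Single-sample, single-region data: no phylogeny, no multi-region
  consistency checks.
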