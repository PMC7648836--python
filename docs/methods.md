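# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and the limitations — in particular what passing the
test suite on synthetic cohorts does and does not establish about real
data.

## Synthetic cohort generator

`ctstrat.simulate.generate_cohort` emulates a two-group, multi-site
structural-imaging study at the level of subject × region tables. Thickness
for subject *i*, feature *j* is

    y_ij = b_j + a_j (age_i − age_mid) + s_j sex_i + site_offset(site_i, j)
           + q_j (quality_i + 50) + ε_ij,    ε_ij ~ N(0, noise_sd²)

with per-feature baselines b_j ~ N(2.5, 0.15) mm (a plausible
cortical-thickness scale), thinning slopes a_j ~ N(−0.01, 0.002) mm/year,
sex effects ~ N(0, 0.02) mm, site offsets ~ N(0, 0.05) mm, and a weak
scan-quality slope. An optional mild quadratic age term is off by default.
Full-scale IQ is carried as a covariate but given zero true effect: it is a
pure nuisance regressor, and this keeps the clinical and reference feature
distributions identical in law when no deviation is planted (the basis of
the generator's distributional null checks).

Clinical subjects additionally receive a planted subtype deviation

    y_ij += severity_i · deviation_amplitude · noise_sd · T(c_i, j)

where T is a k_true × m signed template matrix and severity_i ~
Uniform(0.5, 1.5). Template supports each cover
`round(deviation_sparsity · m)` features drawn from a shared pool of twice
that size, so subtypes overlap spatially; `round(0.6 k_true)` templates are
negative (decreased thickness) and the rest positive, giving the
3-down/2-up structure at k_true = 5. The per-subject severity multiplier
matters: symptom scores are driven by each subject's mean absolute planted
deviation, which would be constant within a subtype without it, leaving
rank correlations undefined.

Symptom and trait scores are rank-preserving monotone transforms of the
standardized deviation magnitude L_i: each measure's latent score is
`sign · λ · L_i + sqrt(1 − λ²) ε + cluster offset`, scaled and discretized
into its instrument's integer range (ADI-R, ADOS-2 calibrated severity,
SRS-2, RBS-R, SSP, two ADHD scales, three IQ scales with negative coupling,
and seven standardized polygenic-score analogs at half coupling). In
`subtype_signed` mode the link's sign alternates across subtypes, the
regime in which cohort-wide correlations are diluted relative to
within-cluster ones. Missingness is MCAR per measure at `missing_rate`
(default 0.03, which leaves roughly three quarters of subjects complete on
the ten classifier measures); a severity-dependent MAR option exists but is
off by default. Identical config and seed regenerate every table
bit-identically.

`simulate_deviation_maps` draws deviation Z-maps directly in z-space
(standard normal noise plus the planted term) together with the matching
clinical table. It is identical in law to generating thickness and scoring
it with a perfectly calibrated normative model, and is used where many
replicates are needed (clustering recovery, model-order and dilution
experiments); the full generate → fit → score path is exercised by the
calibration and end-to-end tests.

Defaults (200 reference, 300 clinical, 200 features, 34 parcels, 6 sites,
5 subtypes, amplitude 1.5 SD, sparsity 0.1, noise 0.1 mm, ages 6–31,
symptom link 0.5) describe the demonstration study; amplitude was chosen
for testability — strong enough that recovery is expected — not calibrated
to any real effect size, which is unknown at this granularity.

What the generator does **not** emulate: spatial autocorrelation on a
cortical mesh (features are exchangeable given their parcel), longitudinal
structure, site-by-covariate interactions, genotypes, non-Gaussian
thickness noise, and informative missingness by default. Passing tests on
these cohorts therefore demonstrates the pipeline's statistical mechanics,
not its behavior under real-data artifacts.

## Normative model

One exact GP per feature, fit on the reference group only (≥ 20 subjects
enforced). Covariate encoding: continuous covariates (age, FIQ, quality)
standardized by reference-group mean/SD; sex as 0/1; site dummy-coded with
the first level as baseline. The encoded design is checked for full column
rank, with collinear columns named in the error. Covariance:

    K = σ²_lin · XXᵀ + σ²_rbf · exp(−D²_cont / 2ℓ²) + σ²_noise · I

— a linear kernel over all encoded covariates (so binary/dummy covariates
enter linearly only), a squared-exponential over the standardized
continuous block, and white noise. Hyperparameters (all log-scale)
maximize the exact marginal likelihood by L-BFGS-B with analytic
gradients, 5 restarts (one fixed start plus seeded draws, shared across
features so identical features get identical fits), 60 iterations each;
Cholesky failures escalate jitter from 1e-6 by ×10 up to 1e-2 before
erroring. The mean function is the training mean (y is centered), which
gives exact translation equivariance of Z.

Deviation scores divide by the predictive **standard deviation**, not the
variance: a Z-score requires SD units, and this matches the normative-
modeling framework this analysis builds on. The predictive variance is the
posterior-function variance **plus** the noise variance, because observed
thickness values — not latent means — are being scored; with anything less,
held-out reference Z would be over-dispersed. With both structured kernel
terms disabled the model reduces analytically (closed form, not by
optimization) to classical z-scoring against the training mean/SD, which
anchors the degenerate-kernel equivalence test at machine precision.

Per-feature independence (no multi-task GP) keeps fitting at the
200-feature, 200-subject scale under two minutes on one CPU and matches
the feature-wise construction of the deviation maps.

## Spectral subtyping

Affinity A = (1 + cos)/2 maps cosine similarity into [0, 1]: spectral
clustering needs nonnegative affinities, and the affine map preserves the
ordering while making anti-parallel deviation profiles (opposite-sign
patterns) maximally dissimilar. The diagonal is set to 1; symmetry, bounds
and the unit diagonal are asserted on every construction. Zero-norm rows
are an error naming the subject. Clustering follows Ng–Jordan–Weiss:
symmetric normalized Laplacian, the k eigenvectors of smallest eigenvalue,
L2 row normalization, k-means with 50 restarts and a fixed seed; zero
degrees (disconnected graphs) are jittered and logged. Labels are 1-based
everywhere, numbered by order of first appearance so reruns are
reproducible. Clustering operates on clinical subjects only.

Leave-one-out stability re-clusters every n−1 subset at the same k, aligns
to the full solution by Hungarian matching on the contingency table, and
reports mean/SD adjusted Rand index plus per-subject assignment
consistency. Note the null behavior: removing one subject barely perturbs
the affinity, so re-clustering fixed noise is itself fairly reproducible —
measured null LOO ARI is roughly 0.55–0.9 depending on (n, m), against
~1.0 for genuinely clustered data. LOO stability discriminates structure
from noise in relative, not absolute, terms.

## Model-order selection: what pairwise AUROC can and cannot do

`select_model_order` clusters the cohort at each K in the grid (default
2–10), trains one-vs-all linear SVMs under stratified CV to rediscover the
cluster labels, scores each K by the mean pairwise AUROC of held-out
decision values, and takes the argmax, breaking ties toward the smaller
(more parsimonious) K. Ks where any cluster is smaller than the fold count
are scored missing and logged.

Two structural caveats, both verified empirically in this package and
documented here because they are easy to misread as bugs:

1. **The null level is far above 0.5.** The cluster labels are estimated
   from the same data the classifier sees, so even for pure noise the CV
   SVM re-learns the clustering's own decision boundary; measured null
   levels are ~0.85–0.93. Significance must come from the label-permutation
   test, never from comparing the raw AUROC to 0.5 (the same circularity
   the structure-coefficient p-values warn about).
2. **On cleanly separated subtypes the criterion prefers small K.** Merging
   two well-separated clusters leaves a 2-vs-1 partition of point clouds
   that is still linearly separable (a convexity fact), while the
   true-K average additionally contains the hardest cluster pair — so the
   K-below-truth score is essentially never below the true-K score, and the
   argmax lands at the bottom of the grid. A peak at the true K can emerge
   on continuum-like real data, where low-K partitions must cut through
   dense regions, but it is not a reproducible property of this statistic
   on separable planted subtypes. The end-to-end suite contains a test
   asserting the idealized behavior — recovery of the planted K and a 0.5
   null level — and that test fails for the reasons above; it is left
   failing rather than weakened, with the mechanism recorded here. For
   planted-subtype data the stability and recovery diagnostics (LOO ARI,
   ARI against truth) are the informative model-order signals.

## Separability and structure coefficients

One-vs-all linear SVMs (C = 1, no inner tuning) on features standardized
with training-fold statistics, stratified 10-fold CV with a fixed seed.
Pairwise AUROC uses raw decision values — AUROC is rank-based, so
calibration to probabilities would change nothing — with midrank handling
of ties; the ordered (i, j) entry scores class i's decision values on
samples truly in {i, j}, the unordered matrix averages both directions,
per-cluster means average over partners. The permutation test permutes
labels without restriction (not within site), recomputes the identical CV
pipeline, and reports p = (1 + #{perm ≥ observed}) / (B + 1), so the
attainable minimum is 1/(B+1). Structure coefficients are Pearson
correlations between each feature and each class's held-out decision
values; their p-values are supplied for display thresholding only —
decision values are cross-validated, so they are not a formal test.
Zero-variance features get coefficient 0 with a flag.

## Atypicality index

The index is the mean of the top `fraction` (default 1%) largest absolute
Z-scores: the full mean trimmed down to the extreme tail, a scalar for
"maximum overall deviation". The alternative reading — trimming *within*
the top tail — is rejected: it would discard exactly the extremes the
statistic exists to capture. k = max(1, floor(fraction · m)), so small
parcels degrade to the max statistic instead of failing; ties at the k-th
value resolve by stable (value, index) order, making the statistic
deterministic. Indices are computed on all provided features; masking
low-quality features is the caller's responsibility. Regional indices
apply the same statistic within each parcel.

## Associations, FDR, and profiles

Spearman correlations use midranks; p-values are exact (full enumeration
of rank permutations) for n ≤ 9 and the t-approximation above that. Cells
with fewer than 4 pairwise-complete observations, or a constant variable,
are reported missing with a reason rather than dropped silently.
Benjamini–Hochberg runs independently within families: for global-index
cells, all (grouping × measure) cells sharing a measure block (instrument);
for regional cells, all (region × grouping) cells per measure. This family
construction is configurable, since "within domains and across clusters"
admits more than one reading.

The clinical cluster classifier reuses the separability machinery on ten
measures (sex, VIQ/PIQ/FIQ, ADI-R social/communication/RRB, ADOS-2
total/social-affect/RRB), with listwise deletion by default (dropped count
reported, and an error suggesting imputation if a cluster empties) or
median/mode imputation — a deliberately simple, deterministic stand-in for
more elaborate schemes. Cluster profiles use one-way ANOVA with Tukey HSD
flags at α = 0.05 per continuous measure (skipped with a reason when a
cluster has < 3 observations) and a chi-square test on the k × 2 sex table.

## Determinism and problem sizes

Every stage seed derives from one integer via `SeedSequence`; reruns of
the pipeline with the same config and seed are bit-identical for all
deterministic stages (the provenance record's timestamp is the only
exception). The demonstration study uses 200 reference + 300 clinical
subjects with 200 features — chosen so the full pipeline, including the
normative fit, runs in a few minutes on one CPU — and 99 permutations in
the demo permutation tests (floor p = 0.01); analyses of real cohorts
should raise the permutation count.

## Known limitations

- Exact GPs are O(n³) per feature; cohorts beyond a few thousand reference
  subjects would need inducing-point or basis-function approximations.
- Homoscedastic Gaussian likelihood per feature; no warped or
  heteroscedastic variants, no longitudinal modeling.
- The affinity's treatment of near-zero deviation profiles is
  noise-dominated: subjects with little deviation have weakly determined
  cluster membership (visible in the assignment-consistency output).
- Model-order selection by pairwise AUROC carries the two caveats above.
- Median/mode imputation ignores uncertainty; results under heavy
  missingness should be read with the listwise analysis alongside.
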