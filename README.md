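# ctstrat

Normative-model based stratification of heterogeneous clinical cohorts from
regional cortical-thickness (CT) tables.

Case–control comparisons assume a homogeneous clinical group; in conditions
such as autism this assumption fails, and opposing individual-level
alterations (some individuals thinner than the normative pattern, some
thicker) cancel out in group means. `ctstrat` implements the alternative:
score every individual against a normative model of CT, cluster the
individual deviation patterns into putative subtypes, and test whether
clinical associations that are diluted across the cohort sharpen within
subtypes. It is aimed at researchers working with subject × region
morphometry tables (e.g. FreeSurfer exports) plus demographic and clinical
measures.

## Method

1. **Normative model.** For each feature *j*, an exact Gaussian-process
   regression of thickness on covariates *x* = (age, sex, site, FIQ, scan
   quality) is fit on the reference group, with kernel
   *k(x, x′) = σ²ₗ xᵀx′ + σ²f exp(−‖x_c − x_c′‖²/2ℓ²) + σ²ₙδ*.
   Each subject–feature observation is converted into a deviation Z-score
   (a normative probability map, NPM):

   *Z*ᵢⱼ = (*y*ᵢⱼ − *μ̂*ⱼ(*x*ᵢ)) / *σ̂*ⱼ(*x*ᵢ),

   where *σ̂*² combines posterior and noise variance.
2. **Subtyping.** Clinical subjects' NPMs are compared by cosine
   similarity, mapped to affinities *A*ᵢⱼ = (1 + cos(zᵢ, zⱼ))/2, and
   partitioned by spectral clustering (normalized Laplacian, k-means on the
   row-normalized eigenvector embedding).
3. **Validation.** Cluster separability is quantified by the pairwise AUROC
   of cross-validated one-vs-all linear-SVM decision values, with a
   label-permutation test and cross-validated structure coefficients;
   stability by a leave-one-out re-clustering procedure (Hungarian-aligned
   adjusted Rand index).
4. **Atypicality and associations.** Each NPM is summarized by an
   atypicality index — the mean of its top 1% absolute Z-scores — globally
   and per parcel; Spearman correlations with symptom/trait measures are
   computed cohort-wide and per cluster, with Benjamini–Hochberg FDR within
   measure blocks.

A seeded synthetic-cohort generator (`ctstrat.simulate`) emulates the data
structure this analysis assumes — normative age/sex trends, site offsets, a
quality covariate, planted opposing-sign subtypes, and symptom scores
monotonically linked to deviation magnitude — so the whole pipeline is
testable without access-restricted data.

## Worked example

The numbered drivers under `analysis/` run the full study on the
demonstration cohort (200 reference + 300 clinical subjects, 200 features,
five planted subtypes at 1.5 SD on 10% of features):

```sh
python analysis/01_simulate_cohort.py        # cohort tables
python analysis/02_fit_normative.py          # per-feature GPs + NPMs
python analysis/03_cluster_subtypes.py       # spectral subtyping, stability
python analysis/04_separability.py           # pairwise AUROC, permutation test
python analysis/05_atypicality_associations.py
python analysis/06_clinical_profile.py
```

Printed output (abridged):

```
planted subtype sizes: [60, 60, 60, 60, 60]
k=5 cluster sizes: [60, 61, 64, 60, 55]
ARI against planted subtypes: 0.951
leave-one-out stability: mean ARI 0.999 (sd 0.004)
per-cluster mean pairwise AUROC: 1: 0.994, 2: 0.988, 3: 0.980, 4: 0.995, 5: 0.985
grand mean AUROC 0.988, CV accuracy 0.940, permutation p = 0.01 (99 permutations)
global atypicality index: median 3.37, IQR (3.06, 3.78)
fraction of measures whose strongest within-cluster |rho| exceeds the
cohort-wide |rho|: 100% (dilution of clinical associations across the cohort)
clinical classifier (listwise): n = 232 of 300 after missing-data handling
  accuracy = 0.37 (chance = 0.20), mean AUROC = 0.67, permutation p = 0.01
```

Reading this: the clustering recovers the planted subtypes almost exactly
(ARI 0.95) and is stable under leave-one-out; every subtype is
discriminable from every other from its deviation map alone (all
per-cluster mean pairwise AUROCs ≥ 0.98, above chance by permutation test);
symptom correlations are stronger within subtypes than cohort-wide; and the
anatomically defined subtypes carry a clinical signature (accuracy 0.37
against a 0.20 chance level from ten demographic/clinical measures alone).

The same pipeline runs on real data from TSV tables
(`ctstrat run --config cfg.yaml --out run/`, or stage-by-stage via the
`ctstrat` subcommands — see `ctstrat --help`).

## Layout

- `src/ctstrat/` — library: `simulate`, `normative`, `clustering`,
  `separability`, `metrics` (atypicality), `association`, `io`,
  `pipeline`, `cli`.
- `analysis/` — the numbered study drivers shown above.
- `docs/methods.md` — modeling assumptions, parameter choices, and known
  limitations (including an honest account of what model-order selection
  by pairwise AUROC can and cannot do on cleanly separable subtypes).
- `tests/` — unit, property, and acceptance suites.
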