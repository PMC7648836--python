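"""Synthetic cohort generator.

Emulates the statistical structure of a multi-site cortical-thickness
stratification study: a reference (neurotypical) group and a clinical group
measured on the same morphometric features, with normative age/sex trends,
site batch offsets, a scan-quality covariate, planted subtype deviation
patterns of opposing signs, and symptom/trait scores monotonically linked to
each subject's deviation magnitude.

All outputs are plain pandas DataFrames; identical config (including its
seed) regenerates bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

COVARIATE_COLUMNS = ["subject_id", "group", "age", "sex", "site", "fiq",
                     "quality"]

# measure -> (mean, sd, lo, hi, integer, block, coupling sign, link scale)
# Coupling sign: +1 if higher deviation magnitude worsens (raises) the score,
# -1 if it lowers it (IQ, sensory profile). Link scale multiplies the global
# symptom_link_strength.
MEASURE_SPECS: dict[str, tuple] = {
    "viq": (100, 18, 40, 160, True, "iq", -1.0, 0.5),
    "piq": (100, 18, 40, 160, True, "iq", -1.0, 0.5),
    "fiq": (100, 18, 40, 160, True, "iq", -1.0, 0.5),
    "adi_social": (16.2, 6.7, 0, 30, True, "adi", 1.0, 1.0),
    "adi_communication": (13.2, 5.7, 0, 26, True, "adi", 1.0, 1.0),
    "adi_rrb": (4.3, 2.7, 0, 12, True, "adi", 1.0, 1.0),
    "ados_total": (5.2, 2.8, 1, 10, True, "ados", 1.0, 1.0),
    "ados_social_affect": (5.8, 2.6, 1, 10, True, "ados", 1.0, 1.0),
    "ados_rrb": (4.7, 2.7, 1, 10, True, "ados", 1.0, 1.0),
    "srs_total": (70.9, 11.9, 30, 90, True, "srs", 1.0, 1.0),
    "rbs_total": (15.4, 13.0, 0, 97, True, "rbs", 1.0, 1.0),
    "ssp_total": (140.0, 26.2, 38, 190, True, "ssp", -1.0, 1.0),
    "adhd_inattention": (4.2, 3.1, 0, 9, True, "adhd", 1.0, 1.0),
    "adhd_hyperimpulsivity": (2.5, 2.7, 0, 9, True, "adhd", 1.0, 1.0),
    "ps_autism": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
    "ps_adhd": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
    "ps_epilepsy": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
    "ps_fiq": (0, 1, None, None, False, "polygenic", -1.0, 0.5),
    "ps_neuroticism": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
    "ps_schizophrenia": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
    "ps_cross_disorder": (0, 1, None, None, False, "polygenic", 1.0, 0.5),
}

MEASURE_BLOCKS = {m: spec[5] for m, spec in MEASURE_SPECS.items()}
MEASURE_BLOCKS["sex"] = "demographic"

#: The ten demographic/clinical measures used by the cluster classifier.
CLASSIFIER_MEASURES = [
    "sex", "viq", "piq", "fiq",
    "adi_social", "adi_communication", "adi_rrb",
    "ados_total", "ados_social_affect", "ados_rrb",
]


@dataclass
class SubtypeTruth:
    """Ground-truth planted structure for a simulated cohort.

    ``true_subtype`` holds 1-based subtype labels for clinical subjects only;
    ``pattern_matrix`` is the k_true x n_features signed deviation template in
    SD units (entries in {-1, 0, +1}); ``severity`` is the per-subject
    multiplicative factor applied to the template.
    """

    subject_id: np.ndarray
    true_subtype: np.ndarray
    pattern_matrix: np.ndarray
    severity: np.ndarray


def make_parcellation(n_features: int, n_parcels: int,
                      seed: int = 0) -> np.ndarray:
    """Assign each feature a 1-based parcel label in contiguous blocks.

    Mimics aggregating vertex-wise features into atlas regions. Every parcel
    is non-empty; block sizes differ by at most one.
    """
    if not (1 <= n_parcels <= n_features):
        raise ValueError(
            f"n_parcels must be in [1, n_features]; got {n_parcels} parcels "
            f"for {n_features} features")
    labels = np.empty(n_features, dtype=int)
    for parcel, idx in enumerate(
            np.array_split(np.arange(n_features), n_parcels), start=1):
        labels[idx] = parcel
    return labels


def _subtype_counts(config: SimulationConfig) -> np.ndarray:
    """Largest-remainder apportionment of clinical subjects to subtypes."""
    target = np.asarray(config.subtype_proportions) * config.n_clinical
    counts = np.floor(target).astype(int)
    remainder = config.n_clinical - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _pattern_matrix(config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Signed subtype templates: sparse supports, one sign per subtype.

    round(0.6 * k_true) subtypes get decreased-thickness (negative)
    templates, the rest increased, mirroring the 3-down/2-up structure at
    k_true=5. Supports are drawn from a shared pool twice the template size,
    so subtypes overlap spatially — decreased- and increased-thickness
    subtypes are anti-correlated over shared anatomy rather than occupying
    disjoint feature sets, as in real cortical-thickness subtype maps.
    """
    m = config.n_features
    n_active = max(1, round(config.deviation_sparsity * m))
    n_negative = int(round(0.6 * config.k_true))
    pool = rng.choice(m, size=min(m, 2 * n_active), replace=False)
    patterns = np.zeros((config.k_true, m))
    for k in range(config.k_true):
        support = rng.choice(pool, size=n_active, replace=False)
        sign = -1.0 if k < n_negative else 1.0
        patterns[k, support] = sign
    return patterns


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SubtypeTruth]:
    """Generate a full synthetic cohort.

    Returns
    -------
    covariates : DataFrame with COVARIATE_COLUMNS, reference rows first.
    features : DataFrame with subject_id + one column per feature (mm).
    clinical : DataFrame for clinical subjects: subject_id, sex, and all
        measures in MEASURE_SPECS, with "NA"-style missing values as NaN.
    truth : SubtypeTruth for the clinical subjects.
    """
    rng = np.random.default_rng(config.seed)
    n_ref, n_clin = config.n_reference, config.n_clinical
    n = n_ref + n_clin
    m = config.n_features

    subject_id = np.array([f"sub-{i:04d}" for i in range(1, n + 1)])
    group = np.array(["reference"] * n_ref + ["clinical"] * n_clin)
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.binomial(1, 0.7, size=n)  # 1 = male
    site = rng.integers(1, config.n_sites + 1, size=n)
    fiq = rng.normal(100.0, 15.0, size=n)
    quality = rng.normal(-50.0, 30.0, size=n)  # Euler-number analog

    # Per-feature normative structure.
    baseline = 2.5 + rng.normal(0.0, 0.15, size=m)
    age_slope = -0.01 + rng.normal(0.0, 0.002, size=m)
    sex_effect = rng.normal(0.0, 0.02, size=m)
    site_offsets = rng.normal(0.0, 0.05, size=(config.n_sites, m))
    quality_slope = rng.normal(0.0, 5e-4, size=m)

    age_c = age - (lo + hi) / 2.0
    values = (baseline[None, :]
              + np.outer(age_c, age_slope)
              + np.outer(sex, sex_effect)
              + site_offsets[site - 1]
              + np.outer(quality + 50.0, quality_slope))
    if config.quadratic_age:
        values = values - 2e-4 * np.outer(age_c ** 2, np.ones(m))
    values = values + rng.normal(0.0, config.noise_sd, size=(n, m))

    # Planted subtype deviations on clinical subjects.
    counts = _subtype_counts(config)
    labels = np.repeat(np.arange(1, config.k_true + 1), counts)
    rng.shuffle(labels)
    patterns = _pattern_matrix(config, rng)
    severity = rng.uniform(0.5, 1.5, size=n_clin)
    planted = (severity[:, None] * config.deviation_amplitude
               * config.noise_sd * patterns[labels - 1])
    values[n_ref:] += planted

    covariates = pd.DataFrame({
        "subject_id": subject_id, "group": group, "age": age, "sex": sex,
        "site": site, "fiq": fiq, "quality": quality,
    })
    feature_cols = [f"f{j:04d}" for j in range(m)]
    features = pd.DataFrame(values, columns=feature_cols)
    features.insert(0, "subject_id", subject_id)

    clinical, latent = _clinical_scores(config, rng, labels, severity,
                                        sex[n_ref:])
    clinical.insert(0, "subject_id", subject_id[n_ref:])
    # Keep the covariate-table FIQ consistent with the clinical-table FIQ
    # (the normative model uses it as a pure nuisance covariate).
    observed_fiq = clinical["fiq"].to_numpy(dtype=float)
    filled = np.where(np.isnan(observed_fiq),
                      fiq[n_ref:], observed_fiq)
    covariates.loc[n_ref:, "fiq"] = filled

    truth = SubtypeTruth(subject_id=subject_id[n_ref:], true_subtype=labels,
                         pattern_matrix=patterns, severity=severity)
    return covariates, features, clinical, truth


def _latent_severity(config: SimulationConfig, labels: np.ndarray,
                     severity: np.ndarray) -> np.ndarray:
    """Standardized per-subject mean absolute planted deviation."""
    n_active = max(1, round(config.deviation_sparsity * config.n_features))
    mean_abs = (severity * config.deviation_amplitude
                * n_active / config.n_features)
    sd = mean_abs.std()
    if sd == 0.0:
        return np.zeros_like(mean_abs)
    return (mean_abs - mean_abs.mean()) / sd


def _clinical_scores(config: SimulationConfig, rng: np.random.Generator,
                     labels: np.ndarray, severity: np.ndarray,
                     sex: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Instrument-like symptom and trait scores linked to deviation size.

    Each measure's latent score is ``sign * lam * L + sqrt(1-lam^2) * eps``
    on a standardized scale (L = standardized mean absolute planted
    deviation), shifted by a per-(cluster, measure) offset and discretized
    into the instrument's integer range, so the link is rank-preserving
    monotone. In ``subtype_signed`` mode the link's sign alternates across
    subtypes, which dilutes cohort-wide correlations.
    """
    n = len(labels)
    latent = _latent_severity(config, labels, severity)
    n_negative = int(round(0.6 * config.k_true))
    subtype_sign = np.where(labels <= n_negative, -1.0, 1.0)

    data: dict[str, np.ndarray] = {"sex": sex.astype(float)}
    for name, (mean, sd, lo, hi, integer, _block, coup,
               scale) in MEASURE_SPECS.items():
        lam = np.clip(config.symptom_link_strength * scale, 0.0, 1.0)
        direction = coup * np.ones(n)
        if config.symptom_link_mode == "subtype_signed" and not (
                name.startswith("ps_") or name in ("viq", "piq", "fiq")):
            direction = coup * subtype_sign
        offsets = config.symptom_cluster_offset * rng.normal(
            size=config.k_true)
        u = (direction * lam * latent
             + np.sqrt(max(0.0, 1.0 - lam ** 2)) * rng.normal(size=n)
             + offsets[labels - 1])
        score = mean + sd * u
        if lo is not None:
            score = np.clip(score, lo, hi)
        if integer:
            score = np.round(score)
        data[name] = score

    df = pd.DataFrame(data)
    if config.missing_rate > 0:
        for name in MEASURE_SPECS:
            if config.missing_mechanism == "mar":
                p = np.clip(config.missing_rate
                            * (1.0 + 0.8 * np.tanh(latent)), 0.0, 0.95)
            else:
                p = np.full(n, config.missing_rate)
            mask = rng.random(n) < p
            df.loc[mask, name] = np.nan
    return df, latent


def simulate_deviation_maps(
        config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame, SubtypeTruth]:
    """Simulate clinical deviation Z-maps directly in z-space.

    Equivalent in law to generating a cohort, fitting a perfectly calibrated
    normative model, and scoring the clinical group: standard-normal noise
    plus ``severity * amplitude * pattern``. The matching clinical score
    table is generated from the same planted structure. Used for clustering,
    model-order, and association experiments where repeated replicates are
    needed.
    """
    rng = np.random.default_rng(config.seed)
    n_clin, m = config.n_clinical, config.n_features
    counts = _subtype_counts(config)
    labels = np.repeat(np.arange(1, config.k_true + 1), counts)
    rng.shuffle(labels)
    patterns = _pattern_matrix(config, rng)
    severity = rng.uniform(0.5, 1.5, size=n_clin)
    z = rng.standard_normal((n_clin, m))
    z += (severity[:, None] * config.deviation_amplitude
          * patterns[labels - 1])
    subject_id = np.array([f"sub-{i:04d}" for i in range(1, n_clin + 1)])
    sex = rng.binomial(1, 0.7, size=n_clin)
    clinical, _ = _clinical_scores(config, rng, labels, severity, sex)
    clinical.insert(0, "subject_id", subject_id)
    truth = SubtypeTruth(subject_id=subject_id, true_subtype=labels,
                         pattern_matrix=patterns, severity=severity)
    return z, clinical, truth
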