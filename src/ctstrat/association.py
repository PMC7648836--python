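"""Clinical and trait associations of atypicality indices.

Spearman correlations between atypicality indices and symptom/trait
measures are computed both cohort-wide and within each cluster, corrected by
Benjamini-Hochberg FDR within measure-domain blocks. The module also
re-uses the separability machinery to classify clusters from clinical
measures alone, and profiles cluster demographics (ANOVA + Tukey HSD,
chi-square for sex).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .config import CVConfig
from .separability import (SeparabilityReport,
                           permutation_test_separability)

MIN_PAIRS = 4


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean())
    ry = (ry - ry.mean())
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 1.0
    count = 0
    total = 0
    for perm in permutations(range(len(y))):
        rho = float(rx @ ry[list(perm)]) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midrank ties; exact p for n <= 9, else t-approx."""
    n = len(x)
    rho, p = stats.spearmanr(x, y)
    if n <= 9:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def spearman_associations(indices: pd.DataFrame, clinical: pd.DataFrame,
                          labels: np.ndarray,
                          measures: list[str] | None = None,
                          blocks: dict[str, str] | None = None,
                          scope: str = "global") -> pd.DataFrame:
    """Spearman correlations of atypicality indices with clinical measures.

    Computed for the whole cohort and within each cluster, for the global
    index (scope="global") or additionally every parcel (scope="regional"),
    with pairwise-complete deletion. Cells with fewer than 4 complete pairs
    or a constant measure are reported as missing with a reason.

    ``indices`` and ``clinical`` must be row-aligned to ``labels`` (clinical
    subjects only).
    """
    if scope not in ("global", "regional"):
        raise ValueError("scope must be 'global' or 'regional'")
    if measures is None:
        measures = [c for c in clinical.columns
                    if c not in ("subject_id", "sex")]
    blocks = blocks or {}
    regions = ["global"]
    if scope == "regional":
        regions += [c for c in indices.columns if c.startswith("parcel_")]
    labels = np.asarray(labels)
    groupings = ["whole-cohort"] + [f"cluster {c}"
                                    for c in np.unique(labels)]
    rows = []
    for grouping in groupings:
        if grouping == "whole-cohort":
            mask = np.ones(len(labels), dtype=bool)
        else:
            mask = labels == int(grouping.split()[-1])
        for measure in measures:
            y_all = clinical[measure].to_numpy(dtype=float)[mask]
            for region in regions:
                x_all = indices[region].to_numpy(dtype=float)[mask]
                ok = ~(np.isnan(x_all) | np.isnan(y_all))
                n_used = int(ok.sum())
                rho = p = np.nan
                reason = ""
                if n_used < MIN_PAIRS:
                    reason = f"fewer than {MIN_PAIRS} complete pairs"
                elif np.unique(y_all[ok]).size < 2:
                    reason = "constant measure within grouping"
                elif np.unique(x_all[ok]).size < 2:
                    reason = "constant index within grouping"
                else:
                    rho, p = _spearman(x_all[ok], y_all[ok])
                rows.append({
                    "grouping": grouping, "measure": measure,
                    "region": region,
                    "block": blocks.get(measure, "unblocked"),
                    "rho": rho, "p_raw": p, "n_used": n_used,
                    "missing_reason": reason,
                })
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray, families: np.ndarray,
           q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up applied independently within families.

    NaN p-values (missing cells) are passed through as NaN and never
    rejected. Returns (q_values, significant flags).
    """
    p = np.asarray(p_values, dtype=float)
    fam = np.asarray(families)
    finite = ~np.isnan(p)
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    for family in np.unique(fam):
        idx = np.where((fam == family) & finite)[0]
        if idx.size == 0:
            continue
        reject, q_fam, _, _ = multipletests(p[idx], alpha=q_level,
                                            method="fdr_bh")
        q[idx] = q_fam
        flags[idx] = reject
    return q, flags


def annotate_fdr(associations: pd.DataFrame,
                 q_level: float = 0.05) -> pd.DataFrame:
    """Attach block-FDR q-values and significance flags to an association
    table.

    Family construction: for global-index cells, all (grouping x measure)
    cells sharing a measure block are corrected together; for regional
    cells, all (region x grouping) cells per measure form one family.
    """
    df = associations.copy()
    is_global = df["region"] == "global"
    family = np.where(is_global,
                      "blk:" + df["block"].astype(str),
                      "msr:" + df["measure"].astype(str))
    q, flags = bh_fdr(df["p_raw"].to_numpy(), family, q_level)
    df["q_fdr"] = q
    df["significant"] = flags
    return df


def impute_median(clinical: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing measure values (mode for binary measures)."""
    out = clinical.copy()
    for col in out.columns:
        if col == "subject_id":
            continue
        values = out[col]
        observed = values.dropna()
        if observed.empty:
            raise ValueError(f"measure {col!r} is fully missing")
        if set(observed.unique()) <= {0, 1}:  # binary: impute the mode
            fill = observed.mode().iloc[0]
        else:
            fill = observed.median()
        out[col] = values.fillna(fill)
    return out


def clinical_cluster_classifier(clinical: pd.DataFrame,
                                labels: np.ndarray,
                                measures: list[str],
                                cv_config: CVConfig | None = None,
                                seed: int = 0,
                                impute: str = "listwise",
                                n_permutations: int = 99,
                                ) -> tuple[SeparabilityReport, dict]:
    """Discriminate clusters from demographic/clinical measures alone.

    ``impute="listwise"`` drops subjects with any missing measure (the count
    is reported); ``"median"`` imputes first. Returns the separability
    report (accuracy, pairwise AUROC, permutation p) and an info dict with
    the chance level 1/k and sample sizes.
    """
    missing = [m for m in measures if m not in clinical.columns]
    if missing:
        raise ValueError(f"configured measures absent from table: {missing}")
    labels = np.asarray(labels)
    table = clinical[measures].copy()
    if impute == "median":
        table = impute_median(table)
        keep = np.ones(len(table), dtype=bool)
    elif impute == "listwise":
        keep = ~table.isna().any(axis=1).to_numpy()
    else:
        raise ValueError("impute must be 'listwise' or 'median'")
    kept_labels = labels[keep]
    classes = np.unique(labels)
    emptied = [int(c) for c in classes if (kept_labels == c).sum() == 0]
    if emptied:
        raise ValueError(
            f"cluster(s) {emptied} emptied by listwise deletion; consider "
            "impute='median'")
    X = table.loc[keep].to_numpy(dtype=float)
    report = permutation_test_separability(X, kept_labels, cv_config,
                                           n_permutations=n_permutations,
                                           seed=seed)
    info = {"n_total": int(len(labels)), "n_used": int(keep.sum()),
            "n_dropped": int((~keep).sum()),
            "chance_accuracy": 1.0 / len(classes)}
    return report, info


def cluster_demographics(covariates: pd.DataFrame, clinical: pd.DataFrame,
                         labels: np.ndarray,
                         measures: list[str] | None = None) -> pd.DataFrame:
    """Cluster profile table: per-cluster mean +- sd with omnibus tests.

    Continuous measures get a one-way ANOVA with Tukey HSD post-hoc flags at
    alpha=0.05; the sex distribution gets a chi-square test on the k x 2
    table. ``covariates`` and ``clinical`` must be row-aligned to
    ``labels``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters")
    if measures is None:
        measures = ["age"] + [c for c in clinical.columns
                              if c not in ("subject_id", "sex")]
    rows = []
    for measure in measures:
        source = covariates if measure in covariates.columns else clinical
        values = source[measure].to_numpy(dtype=float)
        row: dict = {"measure": measure, "test": "anova"}
        groups = []
        skip_reason = ""
        for c in classes:
            v = values[labels == c]
            v = v[~np.isnan(v)]
            groups.append(v)
            row[f"cluster_{c}"] = (f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
                                   if v.size >= 2 else "NA")
            if v.size < 3:
                skip_reason = f"cluster {c} has < 3 observations"
        if skip_reason:
            row.update({"statistic": np.nan, "p_value": np.nan,
                        "post_hoc": f"skipped: {skip_reason}"})
            rows.append(row)
            continue
        f_stat, p = stats.f_oneway(*groups)
        flat = np.concatenate(groups)
        glab = np.concatenate([[c] * len(g) for c, g in zip(classes, groups)])
        tukey = pairwise_tukeyhsd(flat, glab, alpha=0.05)
        sig_pairs = []
        idx = 0
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if tukey.reject[idx]:
                    sig_pairs.append(f"{classes[i]}-{classes[j]}")
                idx += 1
        row.update({"statistic": float(f_stat), "p_value": float(p),
                    "post_hoc": ";".join(sig_pairs)})
        rows.append(row)
    # Sex distribution: chi-square on the k x 2 contingency table.
    sex = covariates["sex"].to_numpy()
    table = np.array([[np.sum((labels == c) & (sex == s)) for s in (0, 1)]
                      for c in classes])
    chi2, p, _, _ = stats.chi2_contingency(table)
    sex_row: dict = {"measure": "sex", "test": "chi-square",
                     "statistic": float(chi2), "p_value": float(p),
                     "post_hoc": ""}
    for ci, c in enumerate(classes):
        total = table[ci].sum()
        pct = 100.0 * table[ci, 0] / total if total else np.nan
        sex_row[f"cluster_{c}"] = f"{total} [{pct:.0f}% F]"
    rows.append(sex_row)
    return pd.DataFrame(rows)
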