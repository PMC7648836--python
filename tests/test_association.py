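"""Associations: Spearman oracle, block FDR, imputation, clinical
classifier, and cluster demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctstrat.association import (_exact_spearman_p, _spearman, annotate_fdr,
                                 bh_fdr, clinical_cluster_classifier,
                                 cluster_demographics, impute_median,
                                 spearman_associations)
from ctstrat.config import CVConfig, SimulationConfig
from ctstrat.simulate import CLASSIFIER_MEASURES, generate_cohort


def manual_spearman(x, y):
    """Midrank-based oracle: Pearson correlation of rank vectors."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10, dtype=float)
        assert _spearman(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert _spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_case(self):
        # ranks differ by d = (1,-1,1,-1,0): rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = _spearman(np.array([1, 2, 3, 4, 5]),
                           np.array([2, 1, 4, 3, 5]))
        assert rho == pytest.approx(0.8)

    def test_matches_midrank_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 13)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, _ = _spearman(x, y)
            assert rho == pytest.approx(manual_spearman(x, y), abs=1e-12)

    def test_exact_p_small_n(self):
        # perfectly monotone n=5: only identity and reversal reach |rho|=1
        x = np.array([1.0, 2, 3, 4, 5])
        p = _exact_spearman_p(x, x, 1.0)
        assert p == pytest.approx(2 / 120)


class TestBhFdr:
    def test_single_p(self):
        q, flags = bh_fdr(np.array([0.04]), np.array(["a"]))
        assert q[0] == pytest.approx(0.04)
        assert flags[0]

    def test_step_up_hand_case(self):
        q, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]),
                      np.array(["a"] * 4))
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        q, flags = bh_fdr(np.ones(5), np.array(["a"] * 5))
        assert np.all(q == 1.0)
        assert not flags.any()

    def test_families_independent(self):
        p = np.array([0.01, 0.5, 0.01, 0.5])
        fam = np.array(["a", "a", "b", "b"])
        q, _ = bh_fdr(p, fam)
        q_single, _ = bh_fdr(p[:2], fam[:2])
        assert np.allclose(q[:2], q_single)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0]), np.array(["a"]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.5]), np.array(["a"]))

    def test_nan_passthrough(self):
        q, flags = bh_fdr(np.array([0.01, np.nan]), np.array(["a", "a"]))
        assert np.isnan(q[1]) and not flags[1]


class TestAssociationTable:
    def _inputs(self, rng, n=40):
        indices = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "global": rng.uniform(1, 3, n),
            "parcel_1": rng.uniform(1, 3, n),
        })
        clinical = pd.DataFrame({
            "subject_id": indices["subject_id"],
            "m1": indices["global"] + rng.normal(0, 0.1, n),
            "m2": rng.normal(0, 1, n),
        })
        labels = np.repeat([1, 2], n // 2)
        return indices, clinical, labels

    def test_monotone_measure_detected(self, rng):
        indices, clinical, labels = self._inputs(rng)
        out = spearman_associations(indices, clinical, labels,
                                    blocks={"m1": "core", "m2": "core"})
        cell = out[(out.grouping == "whole-cohort") & (out.measure == "m1")]
        assert cell["rho"].iloc[0] > 0.9
        annotated = annotate_fdr(out)
        assert {"q_fdr", "significant"} <= set(annotated.columns)

    def test_sparse_cell_reported_missing(self, rng):
        indices, clinical, labels = self._inputs(rng)
        clinical.loc[labels == 2, "m1"] = np.nan
        out = spearman_associations(indices, clinical, labels)
        cell = out[(out.grouping == "cluster 2") & (out.measure == "m1")]
        assert np.isnan(cell["rho"].iloc[0])
        assert "pairs" in cell["missing_reason"].iloc[0]

    def test_constant_measure_reported(self, rng):
        indices, clinical, labels = self._inputs(rng)
        clinical["m2"] = 1.0
        out = spearman_associations(indices, clinical, labels)
        cell = out[(out.grouping == "whole-cohort") & (out.measure == "m2")]
        assert "constant" in cell["missing_reason"].iloc[0]

    def test_regional_scope_adds_parcels(self, rng):
        indices, clinical, labels = self._inputs(rng)
        out = spearman_associations(indices, clinical, labels,
                                    scope="regional")
        assert set(out["region"]) == {"global", "parcel_1"}


class TestImputation:
    def test_median_fill(self):
        df = pd.DataFrame({"subject_id": list("abc"),
                           "m": [1.0, np.nan, 3.0]})
        assert impute_median(df)["m"].tolist() == [1.0, 2.0, 3.0]

    def test_binary_mode_fill(self):
        df = pd.DataFrame({"subject_id": list("abcd"),
                           "sex": [1.0, 1.0, 0.0, np.nan]})
        assert impute_median(df)["sex"].tolist() == [1.0, 1.0, 0.0, 1.0]

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"subject_id": list("ab"), "m": [1.0, 2.0]})
        pd.testing.assert_frame_equal(impute_median(df), df)

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"subject_id": list("ab"),
                           "m": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_median(df)


class TestClinicalClassifier:
    def test_linked_scores_separate_clusters(self):
        config = SimulationConfig(n_reference=20, n_clinical=150,
                                  n_features=20, n_parcels=2, k_true=3,
                                  symptom_link_strength=0.8,
                                  symptom_cluster_offset=1.0,
                                  missing_rate=0.0, seed=13)
        *_, clinical, truth = generate_cohort(config)
        report, info = clinical_cluster_classifier(
            clinical, truth.true_subtype, CLASSIFIER_MEASURES,
            CVConfig(n_splits=5), seed=0, n_permutations=49)
        assert report.accuracy > info["chance_accuracy"] + 0.1
        assert report.p_value < 0.05

    def test_listwise_emptying_cluster_suggests_imputation(self):
        clinical = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(30)],
            **{m: np.random.default_rng(0).normal(size=30)
               for m in CLASSIFIER_MEASURES},
        })
        labels = np.repeat([1, 2], 15)
        clinical.loc[labels == 2, "viq"] = np.nan
        with pytest.raises(ValueError, match="median"):
            clinical_cluster_classifier(clinical, labels,
                                        CLASSIFIER_MEASURES,
                                        CVConfig(n_splits=5), seed=0)

    def test_median_mode_keeps_all_subjects(self):
        config = SimulationConfig(n_reference=20, n_clinical=100,
                                  n_features=10, n_parcels=2, k_true=2,
                                  missing_rate=0.1, seed=14)
        *_, clinical, truth = generate_cohort(config)
        report, info = clinical_cluster_classifier(
            clinical, truth.true_subtype, CLASSIFIER_MEASURES,
            CVConfig(n_splits=5), seed=0, impute="median",
            n_permutations=19)
        assert info["n_used"] == 100


class TestDemographics:
    def test_shifted_cluster_flagged_by_tukey(self, rng):
        n = 120
        labels = np.repeat([1, 2, 3], n // 3)
        value = rng.standard_normal(n)
        value[labels == 2] += 3.0  # three-SD shift for cluster 2
        covariates = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(6, 31, n),
            "sex": rng.binomial(1, 0.7, n),
        })
        clinical = pd.DataFrame({"subject_id": covariates["subject_id"],
                                 "m": value})
        profile = cluster_demographics(covariates, clinical, labels,
                                       measures=["m"])
        row = profile[profile.measure == "m"].iloc[0]
        assert row["p_value"] < 1e-6
        assert set(row["post_hoc"].split(";")) == {"1-2", "2-3"}
        sex_row = profile[profile.measure == "sex"].iloc[0]
        assert sex_row["test"] == "chi-square"
        assert 0 <= sex_row["p_value"] <= 1

    def test_single_cluster_rejected(self, rng):
        covariates = pd.DataFrame({"subject_id": ["a", "b"],
                                   "age": [10.0, 12.0], "sex": [0, 1]})
        clinical = pd.DataFrame({"subject_id": ["a", "b"], "m": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cluster_demographics(covariates, clinical, np.array([1, 1]))

    def test_tiny_cluster_measure_skipped(self, rng):
        n = 22
        labels = np.array([1] * 20 + [2] * 2)
        covariates = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(6, 31, n),
            "sex": rng.binomial(1, 0.5, n),
        })
        clinical = pd.DataFrame({"subject_id": covariates["subject_id"],
                                 "m": rng.standard_normal(n)})
        profile = cluster_demographics(covariates, clinical, labels,
                                       measures=["m"])
        assert "skipped" in profile[profile.measure == "m"
                                    ]["post_hoc"].iloc[0]
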