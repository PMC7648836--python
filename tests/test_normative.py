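"""Normative GP: degenerate equivalences, invariances, calibration, and a
cross-check of the posterior algebra against sklearn's GP regression."""

import numpy as np
import pandas as pd
import pytest

from ctstrat.config import KernelConfig, SimulationConfig
from ctstrat.normative import (CovariateSchemaError, NormativeModel,
                               calibration_report, compute_deviations,
                               fit_normative)
from ctstrat.simulate import generate_cohort

WHITE_NOISE = KernelConfig(use_linear=False, use_rbf=False)


def _split_reference(config):
    covariates, features, _, _ = generate_cohort(config)
    ref = covariates["group"].to_numpy() == "reference"
    cov = covariates[ref].reset_index(drop=True)
    feat = features[ref].reset_index(drop=True)
    half = len(cov) // 2
    return (cov.iloc[:half].reset_index(drop=True),
            feat.iloc[:half].reset_index(drop=True),
            cov.iloc[half:].reset_index(drop=True),
            feat.iloc[half:].reset_index(drop=True))


@pytest.fixture(scope="module")
def reference_split():
    config = SimulationConfig(n_reference=120, n_clinical=10, n_features=6,
                              n_parcels=2, n_sites=3, k_true=2, seed=21)
    return _split_reference(config)


def test_constant_feature_predicts_constant(reference_split):
    train_c, train_f, test_c, test_f = reference_split
    train_f = train_f.copy()
    test_f = test_f.copy()
    train_f["f0000"] = 2.5
    test_f["f0000"] = 2.5
    model = fit_normative(train_c, train_f, KernelConfig(n_restarts=2))
    dev = compute_deviations(model, test_c, test_f)
    j = model.feature_ids.index("f0000")
    assert np.allclose(dev.predictive_mean[:, j], 2.5, atol=1e-6)
    assert np.all(dev.predictive_sd[:, j] < 1e-3)  # noise floor


def test_white_noise_kernel_equals_classical_zscore(reference_split):
    """With structured covariance disabled, Z must equal z-scoring against
    the training mean/SD to machine precision."""
    train_c, train_f, test_c, test_f = reference_split
    model = fit_normative(train_c, train_f, WHITE_NOISE)
    dev = compute_deviations(model, test_c, test_f)
    Y_train = train_f[model.feature_ids].to_numpy(dtype=float)
    Y_test = test_f[model.feature_ids].to_numpy(dtype=float)
    expected = (Y_test - Y_train.mean(axis=0)) / Y_train.std(axis=0)
    assert np.max(np.abs(dev.z - expected)) <= 1e-8


def test_identical_features_identical_hyperparameters(reference_split):
    train_c, train_f, *_ = reference_split
    train_f = train_f.copy()
    train_f["f0001"] = train_f["f0000"]
    model = fit_normative(train_c, train_f, KernelConfig(n_restarts=3))
    f0 = model.features_[model.feature_ids.index("f0000")]
    f1 = model.features_[model.feature_ids.index("f0001")]
    assert np.array_equal(f0.theta, f1.theta)


def test_translation_equivariance(reference_split):
    train_c, train_f, test_c, test_f = reference_split
    model = fit_normative(train_c, train_f, KernelConfig(n_restarts=2))
    dev = compute_deviations(model, test_c, test_f)
    shifted_train = train_f.copy()
    shifted_test = test_f.copy()
    shifted_train["f0002"] = shifted_train["f0002"] + 3.7
    shifted_test["f0002"] = shifted_test["f0002"] + 3.7
    model2 = fit_normative(train_c, shifted_train, KernelConfig(n_restarts=2))
    dev2 = compute_deviations(model2, test_c, shifted_test)
    j = model.feature_ids.index("f0002")
    assert np.max(np.abs(dev.z[:, j] - dev2.z[:, j])) <= 1e-6


def test_z_is_zero_at_mean_and_one_at_one_sd(reference_split):
    train_c, train_f, test_c, test_f = reference_split
    model = fit_normative(train_c, train_f, KernelConfig(n_restarts=2))
    dev = compute_deviations(model, test_c, test_f)
    at_mean = test_f.copy()
    at_mean.loc[:, model.feature_ids] = dev.predictive_mean
    assert np.allclose(compute_deviations(model, test_c, at_mean).z, 0.0,
                       atol=1e-12)
    plus_one = test_f.copy()
    plus_one.loc[:, model.feature_ids] = (dev.predictive_mean
                                          + dev.predictive_sd)
    assert np.allclose(compute_deviations(model, test_c, plus_one).z, 1.0,
                       atol=1e-12)


@pytest.mark.parametrize("kernel,columns", [
    (KernelConfig(use_linear=True, use_rbf=False, n_restarts=2), slice(None)),
    (KernelConfig(use_linear=False, use_rbf=True, n_restarts=2), slice(0, 3)),
])
def test_posterior_matches_sklearn_gpr(reference_split, kernel, columns):
    """Independent oracle: with the fitted hyperparameters held fixed,
    sklearn's GaussianProcessRegressor on the encoded design must reproduce
    our predictive mean and SD."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import (RBF, ConstantKernel,
                                                  DotProduct, WhiteKernel)

    train_c, train_f, test_c, test_f = reference_split
    model = fit_normative(train_c, train_f, kernel)
    dev = compute_deviations(model, test_c, test_f)
    X_train = model.X_train[:, columns]
    X_test = model.encoding.encode(test_c)[:, columns]
    for j in (0, 3):
        f = model.features_[j]
        v_lin, v_rbf = np.exp(f.theta[0]), np.exp(f.theta[1])
        ell, v_noise = np.exp(f.theta[2]), np.exp(f.theta[3])
        if kernel.use_linear:
            sk_kernel = (ConstantKernel(v_lin, "fixed")
                         * DotProduct(sigma_0=1e-10, sigma_0_bounds="fixed")
                         + WhiteKernel(v_noise, "fixed"))
        else:
            sk_kernel = (ConstantKernel(v_rbf, "fixed")
                         * RBF(ell, "fixed")
                         + WhiteKernel(v_noise, "fixed"))
        y = train_f[model.feature_ids[j]].to_numpy(dtype=float)
        gpr = GaussianProcessRegressor(kernel=sk_kernel, optimizer=None,
                                       alpha=0.0, normalize_y=False)
        gpr.fit(X_train, y - f.y_mean)
        mean, sd = gpr.predict(X_test, return_std=True)
        assert np.allclose(mean + f.y_mean, dev.predictive_mean[:, j],
                           atol=1e-6)
        assert np.allclose(sd, dev.predictive_sd[:, j], rtol=1e-5)


def test_heldout_reference_calibration():
    """Held-out reference subjects score approximately standard normal."""
    config = SimulationConfig(n_reference=160, n_clinical=10, n_features=8,
                              n_parcels=2, n_sites=3, k_true=2, seed=31)
    train_c, train_f, test_c, test_f = _split_reference(config)
    model = fit_normative(train_c, train_f)
    dev = compute_deviations(model, test_c, test_f)
    report = calibration_report(dev)
    assert abs(report["mean"].mean()) < 0.15
    assert 0.7 < report["variance"].mean() < 1.3


class TestCalibrationReport:
    def test_standard_normal_extreme_fraction(self, rng):
        from ctstrat.normative import DeviationMap
        z = rng.standard_normal((10000, 1))
        dev = DeviationMap(subject_id=np.arange(10000).astype(str),
                           feature_ids=["f0"], z=z,
                           predictive_mean=np.zeros_like(z),
                           predictive_sd=np.ones_like(z))
        report = calibration_report(dev)
        assert abs(report.attrs["fraction_extreme"] - 0.05) < 0.01

    def test_zero_deviations(self):
        from ctstrat.normative import DeviationMap
        z = np.zeros((5, 2))
        dev = DeviationMap(subject_id=np.arange(5).astype(str),
                           feature_ids=["a", "b"], z=z,
                           predictive_mean=z, predictive_sd=np.ones_like(z))
        report = calibration_report(dev)
        assert (report["mean"] == 0).all()
        assert (report["variance"] == 0).all()
        assert report.attrs["fraction_extreme"] == 0.0

    def test_single_subject_mask_errors(self):
        from ctstrat.normative import DeviationMap
        z = np.zeros((5, 2))
        dev = DeviationMap(subject_id=np.arange(5).astype(str),
                           feature_ids=["a", "b"], z=z,
                           predictive_mean=z, predictive_sd=np.ones_like(z))
        with pytest.raises(ValueError):
            calibration_report(dev, mask=np.array([True] + [False] * 4))


class TestErrors:
    def test_collinear_covariates_named(self, reference_split):
        train_c, train_f, *_ = reference_split
        bad = train_c.copy()
        bad["fiq"] = bad["age"]  # perfectly collinear after standardization
        with pytest.raises(CovariateSchemaError, match="collinear"):
            fit_normative(bad, train_f, WHITE_NOISE)

    def test_unseen_site_level(self, reference_split):
        train_c, train_f, test_c, test_f = reference_split
        model = fit_normative(train_c, train_f, WHITE_NOISE)
        moved = test_c.copy()
        moved.loc[0, "site"] = 99
        with pytest.raises(CovariateSchemaError, match="site"):
            compute_deviations(model, moved, test_f)

    def test_missing_covariates_fail_fast(self, reference_split):
        train_c, train_f, *_ = reference_split
        bad = train_c.copy()
        bad.loc[3, "fiq"] = np.nan
        with pytest.raises(CovariateSchemaError, match="missing"):
            fit_normative(bad, train_f, WHITE_NOISE)

    def test_too_few_reference_subjects(self, reference_split):
        train_c, train_f, *_ = reference_split
        with pytest.raises(ValueError, match="20"):
            fit_normative(train_c.iloc[:10], train_f.iloc[:10], WHITE_NOISE)


def test_model_json_roundtrip(tmp_path, reference_split):
    train_c, train_f, test_c, test_f = reference_split
    model = fit_normative(train_c, train_f, KernelConfig(n_restarts=2))
    path = tmp_path / "model.json"
    model.to_json(path)
    restored = NormativeModel.from_json(path)
    dev = compute_deviations(model, test_c, test_f)
    dev2 = compute_deviations(restored, test_c, test_f)
    assert np.array_equal(dev.z, dev2.z)
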