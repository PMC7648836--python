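"""Per-feature normative models and deviation (Z) maps.

Each morphometric feature is modeled independently by an exact Gaussian
process regression of thickness on demographic and nuisance covariates (age,
sex, site, full-scale IQ, scan quality), fit on the reference group only.
Any subject is then scored as a normative deviation

    Z = (observed - predictive_mean) / predictive_sd,

where the predictive SD combines posterior-function variance and fitted
noise variance, since observations (not latent means) are being scored. The
subjects x features matrix of Z-scores is the subject's normative
probability map.

Kernel: linear (over all encoded covariates) + squared-exponential (over
standardized continuous covariates) + white noise, with hyperparameters
optimized by multi-restart L-BFGS-B on the exact log marginal likelihood.
With both structured terms disabled the model reduces analytically to
classical z-scoring against the training mean/SD.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import kurtosis, skew

from .config import KernelConfig

CONTINUOUS_COVARIATES = ["age", "fiq", "quality"]
BINARY_COVARIATES = ["sex"]

_LOG2PI = np.log(2.0 * np.pi)


class CovariateSchemaError(ValueError):
    pass


@dataclass
class CovariateEncoding:
    """Standardization statistics and site levels frozen at fit time."""

    continuous_mean: np.ndarray
    continuous_sd: np.ndarray
    site_levels: list

    def encode(self, covariates: pd.DataFrame) -> np.ndarray:
        """Encode to the design matrix: standardized continuous columns,
        binary columns, then drop-first site dummies."""
        missing = [c for c in CONTINUOUS_COVARIATES + BINARY_COVARIATES
                   + ["site"] if c not in covariates.columns]
        if missing:
            raise CovariateSchemaError(f"missing covariate columns: {missing}")
        sub = covariates[CONTINUOUS_COVARIATES + BINARY_COVARIATES]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise CovariateSchemaError(
                f"missing values in covariates {bad}; normative fitting "
                "requires complete covariates")
        cont = covariates[CONTINUOUS_COVARIATES].to_numpy(dtype=float)
        cont = (cont - self.continuous_mean) / self.continuous_sd
        binary = covariates[BINARY_COVARIATES].to_numpy(dtype=float)
        sites = covariates["site"].tolist()
        unseen = sorted({s for s in sites if s not in self.site_levels})
        if unseen:
            raise CovariateSchemaError(
                f"unseen site level(s) {unseen}: refit the normative model "
                "including these sites, or map them to a pooled site")
        dummies = np.zeros((len(sites), len(self.site_levels) - 1))
        index = {s: i for i, s in enumerate(self.site_levels)}
        for row, s in enumerate(sites):
            i = index[s]
            if i > 0:  # first level is the baseline
                dummies[row, i - 1] = 1.0
        return np.hstack([cont, binary, dummies])

    @property
    def column_names(self) -> list[str]:
        return (CONTINUOUS_COVARIATES + BINARY_COVARIATES
                + [f"site_{s}" for s in self.site_levels[1:]])

    @classmethod
    def fit(cls, covariates: pd.DataFrame) -> "CovariateEncoding":
        cont = covariates[CONTINUOUS_COVARIATES].to_numpy(dtype=float)
        sd = cont.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(continuous_mean=cont.mean(axis=0), continuous_sd=sd,
                   site_levels=sorted(pd.unique(covariates["site"]).tolist()))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns via pivoted QR: the trailing pivots
        # beyond the numerical rank are the (nearly) collinear ones.
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise CovariateSchemaError(
            f"covariate encoding is rank-deficient; collinear columns: {bad}")


@dataclass
class _FeatureGP:
    """Fitted state for one feature's GP (all in encoded-covariate space)."""

    theta: np.ndarray  # log [linear var, rbf var, lengthscale, noise var]
    y_mean: float
    alpha: np.ndarray
    jitter_used: float


@dataclass
class NormativeModel:
    encoding: CovariateEncoding
    kernel_config: KernelConfig
    X_train: np.ndarray
    feature_ids: list[str]
    features_: list[_FeatureGP] = field(default_factory=list)
    training_hash: str = ""

    @property
    def noise_variances(self) -> np.ndarray:
        return np.array([np.exp(f.theta[3]) for f in self.features_])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "encoding": {
                "continuous_mean": self.encoding.continuous_mean.tolist(),
                "continuous_sd": self.encoding.continuous_sd.tolist(),
                "site_levels": self.encoding.site_levels,
            },
            "kernel_config": {
                "use_linear": self.kernel_config.use_linear,
                "use_rbf": self.kernel_config.use_rbf,
                "n_restarts": self.kernel_config.n_restarts,
                "max_iter": self.kernel_config.max_iter,
                "jitter": self.kernel_config.jitter,
                "max_jitter": self.kernel_config.max_jitter,
                "seed": self.kernel_config.seed,
            },
            "X_train": self.X_train.tolist(),
            "feature_ids": self.feature_ids,
            "features": [
                {"theta": f.theta.tolist(), "y_mean": f.y_mean,
                 "alpha": f.alpha.tolist(), "jitter_used": f.jitter_used}
                for f in self.features_
            ],
            "training_hash": self.training_hash,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        payload = json.loads(Path(path).read_text())
        enc = payload["encoding"]
        model = cls(
            encoding=CovariateEncoding(
                continuous_mean=np.array(enc["continuous_mean"]),
                continuous_sd=np.array(enc["continuous_sd"]),
                site_levels=enc["site_levels"]),
            kernel_config=KernelConfig(**payload["kernel_config"]),
            X_train=np.array(payload["X_train"]),
            feature_ids=payload["feature_ids"],
            features_=[_FeatureGP(theta=np.array(f["theta"]),
                                  y_mean=f["y_mean"],
                                  alpha=np.array(f["alpha"]),
                                  jitter_used=f["jitter_used"])
                       for f in payload["features"]],
            training_hash=payload["training_hash"])
        return model


@dataclass
class DeviationMap:
    """Subjects x features Z-scores with their predictive moments."""

    subject_id: np.ndarray
    feature_ids: list[str]
    z: np.ndarray
    predictive_mean: np.ndarray
    predictive_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=self.feature_ids)
        df.insert(0, "subject_id", self.subject_id)
        return df


def _kernel_parts(X: np.ndarray, n_cont: int):
    """Precompute the Gram matrix and continuous squared distances."""
    gram = X @ X.T
    C = X[:, :n_cont]
    sq = np.sum(C ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (C @ C.T)
    np.maximum(d2, 0.0, out=d2)
    return gram, d2


def _build_K(theta, gram, d2, use_linear, use_rbf):
    v_lin, v_rbf, ell2 = np.exp(theta[0]), np.exp(theta[1]), np.exp(
        2.0 * theta[2])
    K = np.zeros_like(gram)
    E = None
    if use_linear:
        K += v_lin * gram
    if use_rbf:
        E = np.exp(-0.5 * d2 / ell2)
        K += v_rbf * E
    return K, E


def _nll_and_grad(theta, y, gram, d2, use_linear, use_rbf, jitter):
    n = y.shape[0]
    K, E = _build_K(theta, gram, d2, use_linear, use_rbf)
    v_noise = np.exp(theta[3])
    K[np.diag_indices_from(K)] += v_noise + jitter
    L = cholesky(K, lower=True, check_finite=False)
    alpha = cho_solve((L, True), y, check_finite=False)
    nll = (0.5 * y @ alpha + np.sum(np.log(np.diag(L)))
           + 0.5 * n * _LOG2PI)
    Kinv = cho_solve((L, True), np.eye(n), check_finite=False)
    W = Kinv - np.outer(alpha, alpha)  # d(nll)/dK = W / 2
    grad = np.zeros(4)
    if use_linear:
        grad[0] = 0.5 * np.exp(theta[0]) * np.sum(W * gram)
    if use_rbf:
        v_rbf, ell2 = np.exp(theta[1]), np.exp(2.0 * theta[2])
        grad[1] = 0.5 * v_rbf * np.sum(W * E)
        grad[2] = 0.5 * v_rbf * np.sum(W * E * (d2 / ell2))
    grad[3] = 0.5 * v_noise * np.trace(W)
    return nll, grad


def _fit_feature(y: np.ndarray, gram: np.ndarray, d2: np.ndarray,
                 cfg: KernelConfig, starts: list[np.ndarray]) -> _FeatureGP:
    y_mean = float(y.mean())
    yc = y - y_mean
    var_y = float(yc.var())
    if var_y == 0.0:
        var_y = 1e-12
    if not (cfg.use_linear or cfg.use_rbf):
        # Pure white noise: the ML noise variance is the training variance
        # (closed form), and Z reduces to classical z-scoring.
        theta = np.log(np.array([1e-12, 1e-12, 1.0, var_y]))
        return _FeatureGP(theta=theta, y_mean=y_mean,
                          alpha=yc / var_y, jitter_used=0.0)

    scale = np.log(var_y)
    best = None
    jitter_used = 0.0
    for start in starts:
        theta0 = start.copy()
        theta0[[0, 1, 3]] += scale  # variance params scale with the data
        jitter = 0.0
        while True:
            try:
                res = minimize(
                    _nll_and_grad, theta0, jac=True,
                    args=(yc, gram, d2, cfg.use_linear, cfg.use_rbf, jitter),
                    method="L-BFGS-B",
                    bounds=[(scale - 20, scale + 6)] * 2
                           + [(-4, 6), (scale - 12, scale + 6)],
                    options={"maxiter": cfg.max_iter})
                break
            except np.linalg.LinAlgError:
                jitter = cfg.jitter if jitter == 0.0 else jitter * 10.0
                if jitter > cfg.max_jitter:
                    raise
        if best is None or res.fun < best.fun:
            best = res
            jitter_used = jitter
    theta = best.x
    if not cfg.use_linear:
        theta[0] = -np.inf
    if not cfg.use_rbf:
        theta[1] = -np.inf
    K, _ = _build_K(theta, gram, d2, cfg.use_linear, cfg.use_rbf)
    K[np.diag_indices_from(K)] += np.exp(theta[3]) + jitter_used
    L = cholesky(K, lower=True, check_finite=False)
    alpha = cho_solve((L, True), yc, check_finite=False)
    return _FeatureGP(theta=theta, y_mean=y_mean, alpha=alpha,
                      jitter_used=jitter_used)


def _restart_starts(cfg: KernelConfig) -> list[np.ndarray]:
    """Shared restart points (relative to the data scale) for every feature,
    so identical features yield identical fits."""
    rng = np.random.default_rng(cfg.seed)
    starts = [np.array([np.log(0.1), np.log(0.5), 0.0, np.log(0.5)])]
    for _ in range(max(0, cfg.n_restarts - 1)):
        starts.append(np.array([
            rng.uniform(-5, 0), rng.uniform(-3, 1),
            rng.uniform(-1, 2), rng.uniform(-3, 0.5)]))
    return starts


def _table_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def fit_normative(covariates: pd.DataFrame, features: pd.DataFrame,
                  kernel_config: KernelConfig | None = None) -> NormativeModel:
    """Fit independent per-feature GPs on the reference group.

    ``covariates`` must contain reference subjects only (rows aligned with
    ``features`` by position) with no missing values; at least 20 subjects
    are required.
    """
    kernel_config = kernel_config or KernelConfig()
    if "group" in covariates.columns:
        keep = covariates["group"].to_numpy() == "reference"
        covariates = covariates.loc[keep].reset_index(drop=True)
        features = features.loc[keep].reset_index(drop=True)
    if len(covariates) < 20:
        raise ValueError(
            f"need >= 20 reference subjects, got {len(covariates)}")
    if not covariates["subject_id"].equals(features["subject_id"]):
        raise ValueError("covariates and features are not aligned by "
                         "subject_id")
    encoding = CovariateEncoding.fit(covariates)
    X = encoding.encode(covariates)
    _check_full_rank(X, encoding.column_names)

    feature_ids = [c for c in features.columns if c != "subject_id"]
    Y = features[feature_ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("feature matrix contains non-finite values")
    gram, d2 = _kernel_parts(X, len(CONTINUOUS_COVARIATES))
    starts = _restart_starts(kernel_config)
    fitted = [_fit_feature(Y[:, j], gram, d2, kernel_config, starts)
              for j in range(Y.shape[1])]
    return NormativeModel(
        encoding=encoding, kernel_config=kernel_config, X_train=X,
        feature_ids=feature_ids, features_=fitted,
        training_hash=_table_hash(X, Y))


def compute_deviations(model: NormativeModel, covariates: pd.DataFrame,
                       features: pd.DataFrame) -> DeviationMap:
    """Score subjects (reference or clinical) against the normative model."""
    X_new = model.encoding.encode(covariates)
    feature_ids = model.feature_ids
    missing = [f for f in feature_ids if f not in features.columns]
    if missing:
        raise ValueError(f"feature matrix lacks modeled features: {missing}")
    Y = features[feature_ids].to_numpy(dtype=float)
    cfg = model.kernel_config
    n_cont = len(CONTINUOUS_COVARIATES)
    Xt = model.X_train
    gram_x = X_new @ Xt.T
    Cn, Ct = X_new[:, :n_cont], Xt[:, :n_cont]
    d2x = (np.sum(Cn ** 2, axis=1)[:, None]
           + np.sum(Ct ** 2, axis=1)[None, :] - 2.0 * Cn @ Ct.T)
    np.maximum(d2x, 0.0, out=d2x)
    gram_t, d2_t = _kernel_parts(Xt, n_cont)
    self_gram = np.sum(X_new ** 2, axis=1)

    mean = np.empty_like(Y)
    var = np.empty_like(Y)
    for j, f in enumerate(model.features_):
        v_lin, v_rbf = np.exp(f.theta[0]), np.exp(f.theta[1])
        ell2 = np.exp(2.0 * f.theta[2])
        v_noise = np.exp(f.theta[3])
        Kx = np.zeros_like(gram_x)
        prior = np.zeros(X_new.shape[0])
        if cfg.use_linear:
            Kx += v_lin * gram_x
            prior += v_lin * self_gram
        if cfg.use_rbf:
            Kx += v_rbf * np.exp(-0.5 * d2x / ell2)
            prior += v_rbf
        mean[:, j] = f.y_mean + Kx @ f.alpha
        if cfg.use_linear or cfg.use_rbf:
            Kt, _ = _build_K(f.theta, gram_t, d2_t, cfg.use_linear,
                             cfg.use_rbf)
            Kt[np.diag_indices_from(Kt)] += v_noise + f.jitter_used
            L = cholesky(Kt, lower=True, check_finite=False)
            V = solve_triangular(L, Kx.T, lower=True, check_finite=False)
            post = prior - np.sum(V ** 2, axis=0)
            np.maximum(post, 0.0, out=post)
        else:
            post = prior
        var[:, j] = post + v_noise

    sd = np.sqrt(var)
    z = (Y - mean) / sd
    return DeviationMap(
        subject_id=covariates["subject_id"].to_numpy(),
        feature_ids=feature_ids, z=z, predictive_mean=mean,
        predictive_sd=sd)


def calibration_report(deviations: DeviationMap,
                       mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-feature moments of Z plus the overall extreme-deviation rate.

    For a well-calibrated normative model on held-out reference subjects, Z
    is approximately standard normal per feature and about 5% of entries
    exceed |Z| > 1.96.
    """
    z = deviations.z if mask is None else deviations.z[np.asarray(mask)]
    if z.shape[0] < 2:
        raise ValueError("calibration requires >= 2 subjects in the mask")
    report = pd.DataFrame({
        "feature_id": deviations.feature_ids,
        "mean": z.mean(axis=0),
        "variance": z.var(axis=0),
        "skew": skew(z, axis=0),
        "excess_kurtosis": kurtosis(z, axis=0),
    })
    report.attrs["fraction_extreme"] = float(np.mean(np.abs(z) > 1.96))
    return report
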