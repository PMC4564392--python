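"""Kernel Gaussian-process prediction of lesion load from grey matter.

Subjects' smoothed modulated GM maps (or warped-weighted thickness maps)
are reduced to an N x N linear kernel over in-mask voxels — the natural
representation when voxels vastly outnumber subjects — optionally
residualised for confounds (age, sex, TIV, LIV) by projecting the implied
feature space onto the orthogonal complement of the confound columns.
A Gaussian process with covariance theta_s * K + theta_n * I is fitted by
maximising the log marginal likelihood (the two hyperparameters are found
by profiling out the overall scale and searching the noise-to-signal ratio),
prediction quality is assessed by leave-one-out cross-validation (Pearson r,
r^2, RMSE in mm^3 of WMH volume) with the confound projection and the
hyperparameters re-estimated inside every fold, and significance by
permuting the targets.  The dual weights can be mapped back to a voxelwise
weight image; individual voxel weights are not interpretable in isolation
(only the full pattern defines the predictor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumes import Volume

__all__ = [
    "KernelMatrix",
    "GPRModel",
    "PredictionReport",
    "build_linear_kernel",
    "residualise_confounds",
    "gpr_fit",
    "loo_cv",
    "permutation_significance",
    "weight_map",
]


@dataclass
class KernelMatrix:
    """N x N subject-similarity matrix (linear kernel, K = F F' / D)."""

    K: np.ndarray
    n_features: int
    centred: bool = True
    features: np.ndarray | None = None  # centred (N, D), kept for weight maps

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.K).min())
        if eigmin < -1e-8 * max(np.trace(self.K), 1.0):
            raise ValueError("kernel is not positive semi-definite within tolerance")

    @property
    def n_subjects(self) -> int:
        return self.K.shape[0]


@dataclass
class GPRModel:
    """Fitted Gaussian-process state."""

    theta_s: float
    theta_n: float
    alpha: np.ndarray  # dual weights, solves (theta_s K + theta_n I) alpha = y - mean
    y_mean: float
    log_marginal_likelihood: float
    log_marginal_likelihood_init: float
    constant_target: bool = False

    def predict(self, k_rows: np.ndarray) -> np.ndarray:
        """Predictive mean from kernel rows against the training subjects."""
        return self.theta_s * np.atleast_2d(k_rows) @ self.alpha + self.y_mean


@dataclass
class PredictionReport:
    """Leave-one-out prediction quality."""

    predictions: np.ndarray
    pearson_r: float
    r_squared: float
    rmse: float
    permutation_p: float | None = None
    flags: list[str] = field(default_factory=list)


def build_linear_kernel(feature_maps: list[Volume], mask: Volume) -> KernelMatrix:
    """Linear kernel over in-mask voxels, features mean-centred across subjects."""
    if len(feature_maps) < 3:
        raise ValueError("need at least 3 subjects")
    ref = feature_maps[0]
    for v in feature_maps[1:]:
        ref.require_same_grid(v, "feature maps")
    ref.require_same_grid(mask, "feature maps and mask")
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty feature mask")
    F = np.stack([np.asarray(v.data, dtype=float)[m] for v in feature_maps])
    F = F - F.mean(axis=0, keepdims=True)
    D = F.shape[1]
    return KernelMatrix(K=F @ F.T / D, n_features=D, centred=True, features=F)


def _confound_matrix(confounds: np.ndarray, n: int) -> np.ndarray:
    C = np.column_stack([np.ones(n), np.asarray(confounds, dtype=float)]) \
        if confounds is not None else np.ones((n, 1))
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("confound matrix is rank deficient")
    return C


def residualise_confounds(kernel: KernelMatrix, confounds: np.ndarray | None) -> KernelMatrix:
    """Project the confound subspace out of the kernel: K' = R K R.

    R = I - C (C'C)^-1 C' with an intercept column appended to C, so the
    implied features are residualised against the confounds (with intercept
    only this is double-centring).  Idempotent.
    """
    n = kernel.n_subjects
    C = _confound_matrix(confounds, n)
    R = np.eye(n) - C @ np.linalg.pinv(C)
    K2 = R @ kernel.K @ R
    K2 = 0.5 * (K2 + K2.T)
    feats = R @ kernel.features if kernel.features is not None else None
    return KernelMatrix(K=K2, n_features=kernel.n_features, centred=True,
                        features=feats)


# ---------------------------------------------------------------------------
# evidence maximisation
# ---------------------------------------------------------------------------

_LOG10_RHO_GRID = np.linspace(-6.0, 6.0, 97)


def _profile_lml(w: np.ndarray, z: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Profiled log marginal likelihood over the noise/signal ratio grid.

    With Sigma = s (K + rho I), the scale s has the closed form
    s* = mean(z_i^2 / (w_i + rho)); substituting gives
    lml(rho) = -N/2 (1 + log 2 pi + log s*) - 1/2 sum log(w_i + rho).
    """
    N = len(w)
    d = w[np.newaxis, :] + rho[:, np.newaxis]  # (G, N)
    s = np.mean(z[np.newaxis, :] ** 2 / d, axis=1)
    s = np.maximum(s, 1e-300)
    lml = -0.5 * N * (1.0 + np.log(2 * np.pi) + np.log(s)) - 0.5 * np.sum(
        np.log(d), axis=1
    )
    return lml, s


def _fit_core(K: np.ndarray, y: np.ndarray) -> GPRModel:
    N = len(y)
    y_mean = float(np.mean(y))
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        return GPRModel(1e-12, 1.0, np.zeros(N), y_mean, 0.0, 0.0, constant_target=True)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    scale = max(float(w.max()), 1e-12)
    z = U.T @ yc
    rho = scale * 10.0**_LOG10_RHO_GRID
    lml, s = _profile_lml(w, z, rho)
    best = int(np.argmax(lml))
    # local refinement around the best grid point
    lo = rho[max(best - 1, 0)]
    hi = rho[min(best + 1, len(rho) - 1)]
    from scipy.optimize import minimize_scalar

    def neg(log_rho):
        l, _ = _profile_lml(w, z, np.array([np.exp(log_rho)]))
        return -l[0]

    res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)), method="bounded")
    rho_opt = float(np.exp(res.x))
    lml_opt, s_opt = _profile_lml(w, z, np.array([rho_opt]))
    theta_s = float(s_opt[0])
    theta_n = float(s_opt[0] * rho_opt)
    alpha = U @ (z / (theta_s * (w + rho_opt)))
    # reference value at the initial (unit-ratio) point of the search
    lml_init, _ = _profile_lml(w, z, np.array([scale]))
    return GPRModel(theta_s, theta_n, alpha, y_mean, float(lml_opt[0]),
                    float(lml_init[0]))


def gpr_fit(kernel: KernelMatrix | np.ndarray, y: np.ndarray,
            fixed: tuple[float, float] | None = None) -> GPRModel:
    """Fit the GP by maximising the log marginal likelihood.

    ``fixed=(theta_s, theta_n)`` skips the evidence maximisation and only
    solves for the dual weights (useful for linearity analyses).
    """
    K = kernel.K if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if fixed is not None:
        theta_s, theta_n = (float(v) for v in fixed)
        y_mean = float(np.mean(y))
        Sigma = theta_s * K + theta_n * np.eye(len(y))
        try:
            alpha = np.linalg.solve(Sigma, y - y_mean)
        except np.linalg.LinAlgError:
            alpha = np.linalg.solve(Sigma + 1e-8 * np.trace(Sigma) * np.eye(len(y)),
                                    y - y_mean)
        sign, logdet = np.linalg.slogdet(Sigma)
        lml = float(-0.5 * (y - y_mean) @ alpha - 0.5 * logdet
                    - 0.5 * len(y) * np.log(2 * np.pi))
        return GPRModel(theta_s, theta_n, alpha, y_mean, lml, lml)
    return _fit_core(K, y)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class _LooFold:
    train: np.ndarray
    w: np.ndarray
    U: np.ndarray
    k_test: np.ndarray
    scale: float


def _make_loo_plan(K: np.ndarray, confounds: np.ndarray | None) -> list[_LooFold]:
    """Per-fold eigendecompositions of the confound-residualised kernel.

    The confound projection is estimated on the training subjects only and
    applied to all rows (the held-out subject's implied features are
    residualised with the training regression coefficients), so no
    information leaks from the held-out target.
    """
    n = K.shape[0]
    C = _confound_matrix(confounds, n) if confounds is not None else None
    folds = []
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        if C is not None:
            A = np.eye(n)
            M = np.zeros((n, n))
            M[:, train] = C @ np.linalg.pinv(C[train])
            A = A - M
            Kt = A @ K @ A.T
            Kt = 0.5 * (Kt + Kt.T)
        else:
            Kt = K
        Ktr = Kt[np.ix_(train, train)]
        w, U = np.linalg.eigh(Ktr)
        w = np.clip(w, 0.0, None)
        folds.append(_LooFold(train, w, U, Kt[i, train],
                              max(float(w.max()), 1e-12)))
    return folds


def _loo_with_plan(folds: list[_LooFold], y: np.ndarray) -> np.ndarray:
    preds = np.empty(len(folds))
    for i, fold in enumerate(folds):
        yt = y[fold.train]
        y_mean = yt.mean()
        z = fold.U.T @ (yt - y_mean)
        rho = fold.scale * 10.0**_LOG10_RHO_GRID
        lml, s = _profile_lml(fold.w, z, rho)
        best = int(np.argmax(lml))
        rho_opt = rho[best]
        theta_s = float(s[best])
        alpha = fold.U @ (z / (theta_s * (fold.w + rho_opt)))
        preds[i] = theta_s * fold.k_test @ alpha + y_mean
    return preds


def _summarise(preds: np.ndarray, y: np.ndarray) -> PredictionReport:
    flags = []
    if np.std(y) == 0 or np.std(preds) == 0:
        r = 0.0
        flags.append("constant target or predictions; r undefined, reported as 0")
    else:
        r = float(stats.pearsonr(preds, y)[0])
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return PredictionReport(predictions=preds, pearson_r=r, r_squared=r**2,
                            rmse=rmse, flags=flags)


def loo_cv(
    kernel: KernelMatrix | np.ndarray,
    y: np.ndarray,
    confounds: np.ndarray | None = None,
) -> PredictionReport:
    """Leave-one-out cross-validated prediction.

    Confound projection and hyperparameters are re-estimated within every
    fold; the held-out subject is predicted from its cross-covariance row.
    r is Pearson's correlation between predicted and true targets, r^2 its
    square, RMSE the root mean squared error in target units.
    """
    K = kernel.K if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    folds = _make_loo_plan(K, confounds)
    preds = _loo_with_plan(folds, y)
    return _summarise(preds, y)


def permutation_significance(
    kernel: KernelMatrix | np.ndarray,
    y: np.ndarray,
    confounds: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation p value of the LOO correlation.

    The targets are permuted, the full LOO procedure re-run, and
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).  Returns (p, null r's).
    """
    if n_perm < 20:
        raise ValueError("too few permutations for a meaningful p value")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse p value")
    K = kernel.K if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _make_loo_plan(K, confounds)
    r_obs = _summarise(_loo_with_plan(folds, y), y).pearson_r
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        null[i] = _summarise(_loo_with_plan(folds, yp), yp).pearson_r
    p = float((1.0 + np.sum(null >= r_obs)) / (n_perm + 1.0))
    return p, null


def weight_map(model: GPRModel, kernel: KernelMatrix, mask: Volume) -> Volume:
    """Primal voxel weights w = F' alpha / D as a volume on the mask.

    Satisfies the dual-primal identity: the training prediction for subject
    i equals theta_s * dot(f_i, w) + offset, with f_i the subject's centred
    feature vector.  The map is a whole pattern; individual voxel weights
    cannot be interpreted in isolation.
    """
    if kernel.features is None:
        raise ValueError("kernel was built without stored features")
    w = kernel.features.T @ model.alpha / kernel.n_features
    m = np.asarray(mask.data, dtype=bool)
    out = np.zeros(m.shape)
    out[m] = w
    return Volume(data=out, affine=mask.affine)
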