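"""Tissue segmentation for lesioned brains.

The centrepiece is a prior-weighted multivariate mixture of Gaussians fitted
by expectation-maximisation: each tissue class has a mean vector and
covariance over the input channels (T1 alone, or T1 + FLAIR), and when
population tissue probability maps are supplied they act as per-voxel mixing
weights, anchoring class identity spatially.  This is the device that lets a
white-matter-hyperintensity class be segmented automatically: WMH is nearly
indistinguishable from grey matter on T1 but far brighter than everything
else on FLAIR, so the two-channel model isolates it while a T1-only model
cannot.

Also here: population-TPM construction (voxelwise average, smoothed and
floored), intensity-bounded region growing for lacune masks, and
probability-threshold skull stripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .tpm import TPMSet
from .volumes import Volume, gaussian_smooth

__all__ = [
    "MixtureModel",
    "MixtureOfGaussians",
    "fit_mixture",
    "posterior_maps",
    "build_population_tpms",
    "grow_lacune",
    "skull_strip",
    "canonical_class_order",
]


@dataclass
class MixtureModel:
    """Fitted mixture: per class, a mean vector and covariance over channels."""

    class_names: list[str]
    means: np.ndarray  # (K, C)
    covariances: np.ndarray  # (K, C, C)
    weights: np.ndarray  # (K,) global mixing weights (uniform priors case)
    channel_names: list[str]
    log_likelihoods: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def _log_gaussians(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log density of each sample under each class Gaussian, shape (N, K)."""
    N, C = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        diff = X - means[k]
        L = np.linalg.cholesky(covs[k])
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (maha + logdet + C * np.log(2 * np.pi))
    return out


class MixtureOfGaussians:
    """Prior-weighted EM mixture of multivariate Gaussians.

    sklearn-style estimator: ``fit(X, priors=None)`` with X of shape
    (n_voxels, n_channels) and optional per-voxel class priors of shape
    (n_voxels, K).  Fitted state lives in ``means_``, ``covariances_``,
    ``weights_`` and ``log_likelihoods_``.

    With priors, the per-voxel prior probabilities replace the global mixing
    weights in both the E-step and the log-likelihood; means are initialised
    from prior-weighted moments with a broad (global data) covariance so the
    priors dominate early responsibilities.  Without priors, k-means
    initialises the classes.  Covariances are regularised by lambda*I with
    lambda = 1e-6 times the mean channel variance.
    """

    def __init__(self, n_classes: int, max_iter: int = 200, tol: float = 1e-6,
                 seed: int = 0):
        self.n_classes = n_classes
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X: np.ndarray, priors: np.ndarray | None = None) -> "MixtureOfGaussians":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n_voxels, n_channels) array")
        K = self.n_classes
        if K < 2:
            raise ValueError("need at least 2 classes")
        N, C = X.shape
        if len(np.unique(X[:, 0])) < K:
            raise ValueError("fewer distinct intensities than classes (degenerate fit)")
        lam = 1e-6 * float(np.mean(np.var(X, axis=0)))
        reg = lam * np.eye(C)

        if priors is not None:
            priors = np.asarray(priors, dtype=float)
            if priors.shape != (N, K):
                raise ValueError("priors must have shape (n_voxels, n_classes)")
            priors = np.clip(priors, 1e-12, None)
            priors = priors / priors.sum(axis=1, keepdims=True)
            # initialise from an intensity-only fit and match its classes to
            # the prior classes by responsibility/prior overlap: a spatially
            # diffuse prior (e.g. population WMH inside WM) cannot seed the
            # class means by itself, but it reliably names the clusters the
            # intensity structure finds
            base = MixtureOfGaussians(
                n_classes=K, max_iter=self.max_iter, tol=self.tol, seed=self.seed
            ).fit(X)
            resp0 = base.predict_proba(X)
            overlap = resp0.T @ priors  # (K_fit, K_prior)
            from scipy.optimize import linear_sum_assignment

            rows, cols = linear_sum_assignment(-overlap)
            perm = np.empty(K, dtype=int)
            perm[cols] = rows
            means = base.means_[perm].copy()
            covs = base.covariances_[perm].copy()
            weights = priors.mean(axis=0)
        else:
            km = KMeans(n_clusters=K, n_init=4, random_state=self.seed).fit(X)
            means = km.cluster_centers_.copy()
            covs = np.empty((K, C, C))
            weights = np.empty(K)
            for k in range(K):
                sel = km.labels_ == k
                weights[k] = sel.mean()
                if sel.sum() > C:
                    covs[k] = np.cov(X[sel].T).reshape(C, C) + reg
                else:
                    covs[k] = np.cov(X.T).reshape(C, C) + reg

        lls: list[float] = []
        prev = -np.inf
        for _ in range(self.max_iter):
            logg = _log_gaussians(X, means, covs)
            if priors is not None:
                logw = np.log(priors)
            else:
                logw = np.log(np.clip(weights, 1e-12, None))[np.newaxis, :]
            joint = logg + logw
            m = joint.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
            ll = float(lse.sum())
            if lls and ll < lls[-1] - 1e-8 * abs(lls[-1]):
                raise AssertionError("EM log-likelihood decreased")
            lls.append(ll)
            resp = np.exp(joint - lse[:, np.newaxis])
            nk = resp.sum(axis=0)
            nk = np.clip(nk, 1e-10, None)
            means = (resp.T @ X) / nk[:, np.newaxis]
            for k in range(K):
                diff = X - means[k]
                covs[k] = (resp[:, k][:, np.newaxis] * diff).T @ diff / nk[k] + reg
            if priors is None:
                weights = nk / N
            if prev > -np.inf and abs(ll - prev) < self.tol * abs(ll):
                break
            prev = ll

        self.means_ = means
        self.covariances_ = covs
        self.weights_ = weights
        self.log_likelihoods_ = lls
        return self

    def predict_proba(self, X: np.ndarray, priors: np.ndarray | None = None) -> np.ndarray:
        logg = _log_gaussians(np.asarray(X, dtype=float), self.means_, self.covariances_)
        if priors is not None:
            priors = np.clip(np.asarray(priors, dtype=float), 1e-12, None)
            priors = priors / priors.sum(axis=1, keepdims=True)
            logw = np.log(priors)
        else:
            logw = np.log(np.clip(self.weights_, 1e-12, None))[np.newaxis, :]
        joint = logg + logw
        joint -= joint.max(axis=1, keepdims=True)
        p = np.exp(joint)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# volume-level wrappers
# ---------------------------------------------------------------------------


def _gather(channels: list[Volume], mask: Volume) -> tuple[np.ndarray, np.ndarray]:
    ref = channels[0]
    for ch in channels[1:]:
        ref.require_same_grid(ch, "channels")
    ref.require_same_grid(mask, "channels and mask")
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    X = np.stack([np.asarray(ch.data, dtype=float)[m] for ch in channels], axis=1)
    return X, m


def _gather_priors(priors: TPMSet, m: np.ndarray) -> tuple[np.ndarray, list[str]]:
    P = np.stack([np.asarray(priors[c].data, dtype=float)[m] for c in priors.classes], axis=1)
    return P, priors.classes


def fit_mixture(
    channels: list[Volume],
    mask: Volume,
    priors: TPMSet | None,
    K: int | None = None,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> MixtureModel:
    """Fit the (prior-weighted) mixture over in-mask voxels.

    With priors, K is the number of prior classes and the fitted classes
    inherit their names; without, classes are anonymous (``class_0`` ...)
    until identified, e.g. with :func:`canonical_class_order`.
    """
    X, m = _gather(channels, mask)
    if priors is not None:
        P, names = _gather_priors(priors, m)
        K = P.shape[1]
    else:
        if K is None:
            raise ValueError("K is required when no priors are given")
        P, names = None, [f"class_{i}" for i in range(K)]
    est = MixtureOfGaussians(n_classes=K, seed=seed).fit(X, priors=P)
    return MixtureModel(
        class_names=list(names),
        means=est.means_,
        covariances=est.covariances_,
        weights=est.weights_,
        channel_names=channel_names or [f"ch{i}" for i in range(X.shape[1])],
        log_likelihoods=est.log_likelihoods_,
    )


def posterior_maps(
    model: MixtureModel,
    channels: list[Volume],
    priors: TPMSet | None,
    mask: Volume,
) -> TPMSet:
    """Per-voxel class responsibilities as a TPM set (sum to 1 in-mask)."""
    if len(channels) != model.means.shape[1]:
        raise ValueError(
            f"model has {model.means.shape[1]} channels, got {len(channels)}"
        )
    X, m = _gather(channels, mask)
    est = MixtureOfGaussians(n_classes=model.n_classes)
    est.means_ = model.means
    est.covariances_ = model.covariances
    est.weights_ = model.weights
    P = None
    if priors is not None:
        if list(priors.classes) != list(model.class_names):
            raise ValueError("prior classes do not match model classes")
        P, _ = _gather_priors(priors, m)
    resp = est.predict_proba(X, priors=P)
    ref = channels[0]
    maps = {}
    for k, name in enumerate(model.class_names):
        data = np.zeros(ref.shape)
        data[m] = resp[:, k]
        maps[name] = ref.with_data(data)
    return TPMSet(maps, validate=False)


def canonical_class_order(model: MixtureModel) -> dict[str, int]:
    """Identify anonymous fitted classes by their intensity signature.

    Single channel (T1), 3 classes: CSF has the lowest T1 mean, WM the
    highest, GM the middle.  Two channels (T1, FLAIR), 4 classes: WMH has
    the largest FLAIR mean; of the rest, CSF has the lowest and WM the
    highest T1 mean; GM is what remains.
    """
    means = model.means
    K, C = means.shape
    if C == 1 and K == 3:
        order = np.argsort(means[:, 0])
        return {"csf": int(order[0]), "gm": int(order[1]), "wm": int(order[2])}
    if C == 2 and K == 4:
        wmh = int(np.argmax(means[:, 1]))
        rest = [k for k in range(K) if k != wmh]
        rest_sorted = sorted(rest, key=lambda k: means[k, 0])
        return {
            "csf": rest_sorted[0],
            "gm": rest_sorted[1],
            "wm": rest_sorted[2],
            "wmh": wmh,
        }
    raise ValueError("no canonical ordering rule for this channel/class count")


def build_population_tpms(
    subject_tpms: list[TPMSet], smooth_fwhm_mm: float = 4.0, floor: float = 1e-3
) -> TPMSet:
    """Population tissue priors: voxelwise class mean, smoothed and floored.

    A small floor is added inside the brain support so no class ever has a
    strictly zero prior; probabilities are renormalised wherever the floored
    sum exceeds 1.
    """
    if len(subject_tpms) < 2:
        raise ValueError("need at least 2 subjects")
    ref = subject_tpms[0]
    classes = ref.classes
    for s in subject_tpms[1:]:
        if list(s.classes) != list(classes):
            raise ValueError("subjects must share the class set")
        ref.reference.require_same_grid(s.reference, "subject TPMs")
    avg = np.mean([s.stack() for s in subject_tpms], axis=0)
    if smooth_fwhm_mm > 0:
        avg = np.stack(
            [
                gaussian_smooth(ref.reference.with_data(a), smooth_fwhm_mm).data
                for a in avg
            ]
        )
    inside = avg.sum(axis=0) > 0
    avg[:, inside] += floor
    total = avg.sum(axis=0)
    over = total > 1.0
    avg[:, over] /= total[over]
    return ref.with_stack(np.clip(avg, 0, 1), validate=False)


def grow_lacune(
    t1: Volume,
    seed_point: tuple[int, int, int],
    lower: float,
    upper: float,
    max_iters: int = 500,
) -> Volume:
    """Intensity-bounded 6-connected region growing from a seed voxel.

    One dilation layer is accepted per iteration; growth stops at closure or
    after ``max_iters`` iterations.  Mirrors the space-filling lacune
    segmentation workflow (intensity window, fixed iteration cap).
    """
    data = np.asarray(t1.data, dtype=float)
    seed_point = tuple(int(i) for i in seed_point)
    val = data[seed_point]
    if not (lower <= val <= upper):
        raise ValueError(
            f"seed intensity {val} outside the [{lower}, {upper}] window"
        )
    in_range = (data >= lower) & (data <= upper)
    mask = np.zeros(data.shape, dtype=bool)
    mask[seed_point] = True
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    for _ in range(max_iters):
        grown = ndimage.binary_dilation(mask, structure=struct) & in_range
        if np.array_equal(grown, mask):
            break
        mask = grown
    return t1.with_data(mask.astype(np.uint8))


def skull_strip(
    vol: Volume, tpms: TPMSet, threshold: float = 0.1
) -> tuple[Volume, Volume]:
    """Zero everything outside the brain.

    The brain mask is the union of tissue probability above ``threshold``
    (summed over GM + WM + CSF), reduced to its largest connected component.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    vol.require_same_grid(tpms.reference, "volume and TPMs")
    names = [c for c in ("gm", "wm", "csf") if c in tpms.classes] or tpms.classes
    total = np.sum([np.asarray(tpms[c].data, dtype=float) for c in names], axis=0)
    mask = total >= threshold
    if not mask.any():
        raise ValueError("empty brain mask at this threshold")
    labels_cc, n_cc = ndimage.label(mask)
    if n_cc > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels_cc), labels_cc, range(1, n_cc + 1))
        mask = labels_cc == (1 + int(np.argmax(sizes)))
    stripped = vol.with_data(np.where(mask, vol.data, 0.0))
    return stripped, vol.with_data(mask.astype(np.uint8))
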