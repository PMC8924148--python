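"""Learning phase: eigenvalue-decomposition discriminant analysis (EDDA).

Class covariances are parameterized through the eigen-decomposition
``Sigma_k = lambda_k D_k A_k D_k'`` (volume, shape, orientation), each factor
either shared across classes, class-specific, or restricted to the identity.
Fitting a family reduces to separate per-class moment estimation plus a
constrained covariance step; the family itself is chosen by BIC on the
labelled training log-likelihood.

Supported families (mclust naming): the diagonal/spherical families
EII, VII, EEI, VEI, EVI, VVI plus the full-covariance EEE and VVV.  VEI is
the one family without a closed form and is fitted by the usual fixed-point
alternation between volumes and the common diagonal shape.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model_core import (
    DamdaError,
    DataMatrix,
    GaussianClass,
    LabelSet,
    LearnedClassifier,
    log_density_batch,
)

SUPPORTED_FAMILIES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "VVV")
DEFAULT_FAMILIES = SUPPORTED_FAMILIES

_VEI_MAX_ITER = 200
_VEI_TOL = 1e-8


class FamilyFitError(DamdaError):
    """Constrained covariance estimation failed for a family."""


def cov_param_count(family: str, K: int, P: int) -> int:
    """Number of free covariance parameters of an EDDA family."""
    full = P * (P + 1) // 2
    return {
        "EII": 1,
        "VII": K,
        "EEI": P,
        "VEI": K + (P - 1),
        "EVI": 1 + K * (P - 1),
        "VVI": K * P,
        "EEE": full,
        "VVV": K * full,
    }[family]


def _class_scatters(X: np.ndarray, ind: np.ndarray):
    """Per-class sizes, means and (uncentered-by-mean) scatter matrices."""
    n_k = ind.sum(axis=0).astype(float)
    means = (ind.T @ X) / n_k[:, None]
    K, P = means.shape
    S = np.empty((K, P, P))
    for k in range(K):
        Xi = X[ind[:, k] == 1] - means[k]
        S[k] = Xi.T @ Xi
    return n_k, means, S


def _det1_normalize(diag: np.ndarray) -> tuple[np.ndarray, float]:
    """Split a positive diagonal into (unit-determinant shape, volume)."""
    logdet = np.sum(np.log(diag))
    vol = np.exp(logdet / diag.size)
    return diag / vol, vol


def _constrained_covs(family: str, S: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """ML covariance estimates under the family constraint.

    ``S`` are within-class scatter matrices, ``n_k`` class counts.  All
    families except VEI have closed-form maximizers of the labelled
    likelihood (equivalently minimizers of
    ``sum_k [n_k log det Sigma_k + tr(Sigma_k^{-1} S_k)]``).
    """
    K, P, _ = S.shape
    M = float(n_k.sum())
    diag_S = np.stack([np.diag(S[k]) for k in range(K)])  # (K, P)

    if family == "VVV":
        return S / n_k[:, None, None]
    if family == "EEE":
        pooled = S.sum(axis=0) / M
        return np.broadcast_to(pooled, (K, P, P)).copy()
    if family == "EII":
        lam = float(np.trace(S.sum(axis=0))) / (M * P)
        return np.broadcast_to(lam * np.eye(P), (K, P, P)).copy()
    if family == "VII":
        lam_k = np.array([np.trace(S[k]) for k in range(K)]) / (n_k * P)
        return lam_k[:, None, None] * np.eye(P)[None]
    if family == "EEI":
        d = diag_S.sum(axis=0) / M
        return np.broadcast_to(np.diag(d), (K, P, P)).copy()
    if family == "VVI":
        return np.stack([np.diag(diag_S[k] / n_k[k]) for k in range(K)])
    if family == "EVI":
        # shared volume, class-specific unit-determinant diagonal shapes
        shapes = np.empty_like(diag_S)
        vols = np.empty(K)
        for k in range(K):
            shapes[k], vols[k] = _det1_normalize(diag_S[k])
        lam = float(vols.sum()) / M  # sum_k det(diag S_k)^{1/P} / M
        return np.stack([np.diag(lam * shapes[k]) for k in range(K)])
    if family == "VEI":
        # shared unit-determinant diagonal shape, class-specific volumes
        lam_k = np.array([np.trace(S[k]) for k in range(K)]) / (n_k * P)
        prev = np.inf
        for _ in range(_VEI_MAX_ITER):
            B = (diag_S / lam_k[:, None]).sum(axis=0)
            B, _ = _det1_normalize(B)
            lam_k = (diag_S / B[None, :]).sum(axis=1) / (n_k * P)
            obj = float(np.sum(n_k * P * np.log(lam_k)) + np.sum(diag_S / (lam_k[:, None] * B[None, :])))
            if abs(prev - obj) <= _VEI_TOL * (1.0 + abs(obj)):
                break
            prev = obj
        else:
            raise FamilyFitError("VEI fixed-point iteration did not converge")
        return np.stack([np.diag(lam_k[k] * B) for k in range(K)])
    raise FamilyFitError(f"unsupported covariance family {family!r}")


def _ridge_repair(covs: np.ndarray) -> np.ndarray:
    """Add a tiny diagonal ridge to covariances with a zero-variance direction."""
    out = covs.copy()
    for k in range(covs.shape[0]):
        ev = np.linalg.eigvalsh(out[k])
        if ev[0] <= 1e-10 * max(ev[-1], 1e-300):
            ridge = 1e-8 * max(np.mean(np.diag(out[k])), 1e-12)
            warnings.warn(
                f"degenerate covariance for class {k}: adding ridge {ridge:.3g}",
                stacklevel=3,
            )
            out[k] = out[k] + ridge * np.eye(covs.shape[1])
    return out


def labelled_loglik(
    X: np.ndarray, ind: np.ndarray, props: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> float:
    """Complete (labelled) log-likelihood of the training data."""
    ll = 0.0
    for k in range(means.shape[0]):
        rows = ind[:, k] == 1
        if rows.any():
            ll += np.sum(log_density_batch(X[rows], means[k], covs[k], str(k)))
            ll += rows.sum() * np.log(props[k])
    return float(ll)


def fit_edda_family(
    train: DataMatrix, labels: LabelSet, family: str
) -> LearnedClassifier:
    """Fit the EDDA classifier for one covariance family.

    Class means are the sample means, mixing proportions the class
    frequencies, and covariances maximize the labelled likelihood under the
    family's structural constraint.  BIC (higher is better) is recorded.
    """
    if family not in SUPPORTED_FAMILIES:
        raise FamilyFitError(f"unknown family {family!r}; supported: {SUPPORTED_FAMILIES}")
    X, ind = train.values, labels.indicators
    if X.shape[0] != ind.shape[0]:
        raise ValueError("train and labels must have the same number of rows")
    counts = ind.sum(axis=0)
    if np.any(counts < 2):
        small = [labels.class_names[k] for k in np.flatnonzero(counts < 2)]
        raise DamdaError(f"classes with fewer than 2 observations: {small}")

    n_k, means, S = _class_scatters(X, ind)
    covs = _ridge_repair(_constrained_covs(family, S, n_k))
    M, P = X.shape
    K = means.shape[0]
    props = n_k / M
    ll = labelled_loglik(X, ind, props, means, covs)
    eta = K * P + (K - 1) + cov_param_count(family, K, P)
    bic = 2.0 * ll - eta * np.log(M)
    classes = [
        GaussianClass(means[k], covs[k], labels.class_names[k]) for k in range(K)
    ]
    return LearnedClassifier(
        classes=classes,
        props=props,
        family=family,
        var_names=train.var_names,
        bic=float(bic),
        loglik=float(ll),
    )


def fit_edda(
    train: DataMatrix,
    labels: LabelSet,
    families: tuple[str, ...] | list[str] = DEFAULT_FAMILIES,
) -> LearnedClassifier:
    """Fit all candidate families and return the one with maximal BIC.

    Ties are broken toward the family with fewer covariance parameters.
    """
    if not families:
        raise ValueError("at least one candidate family is required")
    fits: list[LearnedClassifier] = []
    errors: dict[str, Exception] = {}
    for fam in families:
        try:
            fits.append(fit_edda_family(train, labels, fam))
        except DamdaError as exc:  # keep trying the remaining families
            errors[fam] = exc
    if not fits:
        raise DamdaError(f"all EDDA families failed: {errors}")
    K, P = fits[0].n_classes, len(train.var_names)
    fits.sort(key=lambda f: (-f.bic, cov_param_count(f.family, K, P)))
    return fits[0]
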