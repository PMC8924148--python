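"""Shared domain types, Gaussian densities, MAP classification and model I/O.

The containers here are deliberately thin wrappers around numpy arrays:
:class:`DataMatrix` pairs an observation matrix with ordered variable names
(variables are always matched *by name* across training and test data),
:class:`LabelSet` holds one-hot class indicators, and the two classifier
types record the learning-phase (:class:`LearnedClassifier`) and
discovery-phase (:class:`AugmentedModel`) parameters.  All density work is
done in log space; posterior responsibilities are normalized with
log-sum-exp so that large dimension counts cannot underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "damda-model/1"

#: relative eigenvalue tolerance for positive-definiteness checks
PD_RTOL = 1e-10


class DamdaError(Exception):
    """Base class for all package errors."""


class SingularModelError(DamdaError):
    """A class covariance is numerically singular."""


class ColumnMismatchError(DamdaError):
    """Data columns do not match the model's variable names."""


class ModelParseError(DamdaError):
    """A serialized model document is malformed."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class DataMatrix:
    """Numeric observation matrix with ordered, unique variable names."""

    values: np.ndarray
    var_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.var_names = [str(v) for v in self.var_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.var_names)} names"
            )
        if len(set(self.var_names)) != len(self.var_names):
            raise ValueError("variable names must be unique")
        if self.values.shape[1] < 1:
            raise ValueError("at least one variable required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite values are not supported")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def select(self, names: list[str] | tuple[str, ...]) -> "DataMatrix":
        """Return the sub-matrix with the given columns, in the given order."""
        missing = [n for n in names if n not in self.var_names]
        if missing:
            raise ColumnMismatchError(f"columns not present: {missing}")
        idx = [self.var_names.index(n) for n in names]
        return DataMatrix(self.values[:, idx], list(names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.var_names)


@dataclass
class LabelSet:
    """One-hot class membership indicators."""

    indicators: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.indicators = np.atleast_2d(np.asarray(self.indicators))
        self.class_names = [str(c) for c in self.class_names]
        if self.indicators.shape[1] != len(self.class_names):
            raise ValueError("indicator columns must match class names")
        rowsum = self.indicators.sum(axis=1)
        if not np.all(rowsum == 1):
            raise ValueError("each row must belong to exactly one class")

    @classmethod
    def from_labels(cls, labels, class_names: list[str] | None = None) -> "LabelSet":
        labels = [str(x) for x in labels]
        if class_names is None:
            class_names = sorted(set(labels))
        ind = np.zeros((len(labels), len(class_names)), dtype=int)
        lookup = {c: j for j, c in enumerate(class_names)}
        for i, lab in enumerate(labels):
            if lab not in lookup:
                raise ValueError(f"label {lab!r} not among class names {class_names}")
            ind[i, lookup[lab]] = 1
        return cls(ind, list(class_names))

    @property
    def n_obs(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_classes(self) -> int:
        return self.indicators.shape[1]

    def labels(self) -> list[str]:
        idx = np.argmax(self.indicators, axis=1)
        return [self.class_names[j] for j in idx]


@dataclass
class GaussianClass:
    """A single Gaussian class: mean vector and SPD covariance matrix."""

    mean: np.ndarray
    cov: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8, rtol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.size

    def is_pd(self, rtol: float = PD_RTOL) -> bool:
        ev = np.linalg.eigvalsh(self.cov)
        return bool(ev[0] > rtol * max(ev[-1], 0.0))


@dataclass
class Responsibilities:
    """N x C posterior class-membership probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("responsibility rows must sum to 1")

    @property
    def n_obs(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def hard_assignments(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)


@dataclass
class LearnedClassifier:
    """Learning-phase output: class Gaussians on the P training variables."""

    classes: list[GaussianClass]
    props: np.ndarray
    family: str
    var_names: list[str]
    bic: float | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.props = np.asarray(self.props, dtype=float).ravel()
        if len(self.classes) != self.props.size:
            raise ValueError("one mixing proportion per class required")
        if not np.isclose(self.props.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing proportions must sum to 1")
        dims = {g.dim for g in self.classes}
        if dims != {len(self.var_names)}:
            raise ValueError("class dimension must match variable names")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_names(self) -> list[str]:
        return [g.name or f"class_{k}" for k, g in enumerate(self.classes)]

    def means(self) -> np.ndarray:
        return np.stack([g.mean for g in self.classes])

    def covs(self) -> np.ndarray:
        return np.stack([g.cov for g in self.classes])


@dataclass
class AugmentedModel:
    """Discovery-phase state: C = K + H Gaussians on all R test variables.

    For the K known classes the mean and covariance are stored in blocks so
    that the learning-phase estimates stay bit-identical: the first
    ``p_count`` coordinates of the mean are ``learned_means[k]`` and the
    upper-left block of the covariance is ``learned_covs[k]``; only
    ``mu_q``, ``cross`` (the P x Q cross-covariances C_k) and ``sigma_q``
    are re-estimated on the test data.
    """

    var_names: list[str]
    p_count: int
    learned_means: np.ndarray  # (K, P)
    learned_covs: np.ndarray  # (K, P, P)
    mu_q: np.ndarray  # (K, Q)
    cross: np.ndarray  # (K, P, Q)
    sigma_q: np.ndarray  # (K, Q, Q)
    hidden: list[GaussianClass] = field(default_factory=list)
    props: np.ndarray = None  # length C
    class_names: list[str] | None = None
    learned_props: np.ndarray | None = None  # length K, for re-normalization

    def __post_init__(self) -> None:
        self.learned_means = np.atleast_2d(np.asarray(self.learned_means, float))
        K, P = self.learned_means.shape
        R = len(self.var_names)
        Q = R - P
        if P != self.p_count:
            raise ValueError("learned_means width must equal p_count")
        self.learned_covs = np.asarray(self.learned_covs, float).reshape(K, P, P)
        self.mu_q = np.asarray(self.mu_q, float).reshape(K, Q)
        self.cross = np.asarray(self.cross, float).reshape(K, P, Q)
        self.sigma_q = np.asarray(self.sigma_q, float).reshape(K, Q, Q)
        for h in self.hidden:
            if h.dim != R:
                raise ValueError("hidden classes must live on all R variables")
        self.props = np.asarray(self.props, dtype=float).ravel()
        if self.props.size != K + len(self.hidden):
            raise ValueError("props length must be K + H")
        if not np.isclose(self.props.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing proportions must sum to 1")
        if self.class_names is None:
            self.class_names = [f"known_{k}" for k in range(K)] + [
                f"hidden_{h}" for h in range(len(self.hidden))
            ]
        if self.learned_props is not None:
            self.learned_props = np.asarray(self.learned_props, float).ravel()

    @property
    def n_known(self) -> int:
        return self.learned_means.shape[0]

    @property
    def n_hidden(self) -> int:
        return len(self.hidden)

    @property
    def n_classes(self) -> int:
        return self.n_known + self.n_hidden

    @property
    def q_count(self) -> int:
        return len(self.var_names) - self.p_count

    def known_mean(self, k: int) -> np.ndarray:
        return np.concatenate([self.learned_means[k], self.mu_q[k]])

    def known_cov(self, k: int) -> np.ndarray:
        P, Q = self.p_count, self.q_count
        cov = np.empty((P + Q, P + Q))
        cov[:P, :P] = self.learned_covs[k]
        cov[:P, P:] = self.cross[k]
        cov[P:, :P] = self.cross[k].T
        cov[P:, P:] = self.sigma_q[k]
        return cov

    def all_means(self) -> np.ndarray:
        mk = [self.known_mean(k) for k in range(self.n_known)]
        mh = [h.mean for h in self.hidden]
        return np.stack(mk + mh) if mk or mh else np.empty((0, len(self.var_names)))

    def all_covs(self) -> np.ndarray:
        ck = [self.known_cov(k) for k in range(self.n_known)]
        ch = [h.cov for h in self.hidden]
        return np.stack(ck + ch)

    def gaussians(self) -> list[GaussianClass]:
        out = [
            GaussianClass(self.known_mean(k), self.known_cov(k), self.class_names[k])
            for k in range(self.n_known)
        ]
        for h, g in enumerate(self.hidden):
            out.append(GaussianClass(g.mean, g.cov, self.class_names[self.n_known + h]))
        return out


# ---------------------------------------------------------------------------
# densities and classification


def _chol_logdet(cov: np.ndarray, name: str | None = None) -> tuple[np.ndarray, float]:
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError(
            f"covariance of class {name or '<unnamed>'} is not positive definite"
        ) from exc
    return L, 2.0 * np.sum(np.log(np.diag(L)))


def log_density_batch(
    Y: np.ndarray, mean: np.ndarray, cov: np.ndarray, name: str | None = None
) -> np.ndarray:
    """Log multivariate-normal density of each row of ``Y`` (vectorized)."""
    from scipy.linalg import solve_triangular

    Y = np.atleast_2d(Y)
    d = mean.size
    L, logdet = _chol_logdet(cov, name)
    z = solve_triangular(L, (Y - mean).T, lower=True, check_finite=False)
    maha = np.sum(z * z, axis=0)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def log_density(point: np.ndarray, cls: GaussianClass) -> float:
    """Log Gaussian density ``log phi(point; mu, Sigma)`` of a single point."""
    point = np.asarray(point, dtype=float).ravel()
    if point.size != cls.dim:
        raise ValueError(f"point has length {point.size}, class has dim {cls.dim}")
    return float(log_density_batch(point[None, :], cls.mean, cls.cov, cls.name)[0])


def log_density_model(Y: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """N x C matrix of per-class log densities, batched over classes."""
    N, R = Y.shape
    C = means.shape[0]
    try:
        L = np.linalg.cholesky(covs)  # batched (C, R, R)
    except np.linalg.LinAlgError:
        # redo per class to name the offender
        for c in range(C):
            _chol_logdet(covs[c], str(c))
        raise
    diff = (Y[None, :, :] - means[:, None, :]).transpose(0, 2, 1)  # (C, R, N)
    z = np.linalg.solve(L, diff)  # batched triangular systems
    maha = np.einsum("crn,crn->cn", z, z)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    cst = R * np.log(2.0 * np.pi)
    return (-0.5 * (cst + logdet[:, None] + maha)).T


def posterior_from_logs(log_dens: np.ndarray, props: np.ndarray) -> tuple[np.ndarray, float]:
    """Responsibilities and total log-likelihood from per-class log densities."""
    with np.errstate(divide="ignore"):
        joint = log_dens + np.log(props)[None, :]
    m = np.max(joint, axis=1)
    with np.errstate(invalid="ignore"):
        s = np.exp(joint - m[:, None])
    tot = s.sum(axis=1)
    t = s / tot[:, None]
    return t, float(np.sum(m + np.log(tot)))


def map_classify(model, data: DataMatrix) -> tuple[LabelSet, Responsibilities]:
    """MAP classification of ``data`` under a learned or augmented model.

    Columns are matched to the model's variable names (order-free); hard
    labels are the row-wise argmax of the posterior responsibilities.
    """
    aligned = data.select(model.var_names)
    if isinstance(model, AugmentedModel):
        means, covs = model.all_means(), model.all_covs()
        names = model.class_names
    else:
        means, covs = model.means(), model.covs()
        names = model.class_names
    log_dens = log_density_model(aligned.values, means, covs)
    if not np.all(np.isfinite(log_dens)):
        bad = int(np.argwhere(~np.isfinite(log_dens))[0][0])
        raise DamdaError(f"non-finite density at observation {bad}")
    t, _ = posterior_from_logs(log_dens, model.props)
    hard = np.argmax(t, axis=1)
    ind = np.zeros_like(t, dtype=int)
    ind[np.arange(t.shape[0]), hard] = 1
    return LabelSet(ind, list(names)), Responsibilities(t)


# ---------------------------------------------------------------------------
# serialization


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def serialize_model(model) -> str:
    """Serialize a classifier to a JSON text document (lossless round trip)."""
    if isinstance(model, LearnedClassifier):
        doc = {
            "schema": SCHEMA_VERSION,
            "kind": "learned",
            "family": model.family,
            "var_names": model.var_names,
            "props": _arr(model.props),
            "bic": model.bic,
            "loglik": model.loglik,
            "classes": [
                {"name": g.name, "mean": _arr(g.mean), "cov": _arr(g.cov)}
                for g in model.classes
            ],
        }
    elif isinstance(model, AugmentedModel):
        doc = {
            "schema": SCHEMA_VERSION,
            "kind": "augmented",
            "var_names": model.var_names,
            "p_count": model.p_count,
            "class_names": model.class_names,
            "props": _arr(model.props),
            "learned_means": _arr(model.learned_means),
            "learned_covs": _arr(model.learned_covs),
            "mu_q": _arr(model.mu_q),
            "cross": _arr(model.cross),
            "sigma_q": _arr(model.sigma_q),
            "learned_props": None
            if model.learned_props is None
            else _arr(model.learned_props),
            "hidden": [
                {"name": g.name, "mean": _arr(g.mean), "cov": _arr(g.cov)}
                for g in model.hidden
            ],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return json.dumps(doc, indent=1)


def load_model(text: str):
    """Parse a model document written by :func:`serialize_model`."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"invalid model document: {exc}") from exc
    try:
        if doc["schema"] != SCHEMA_VERSION:
            raise ModelParseError(f"unsupported schema {doc.get('schema')!r}")
        if doc["kind"] == "learned":
            return LearnedClassifier(
                classes=[
                    GaussianClass(np.array(c["mean"]), np.array(c["cov"]), c["name"])
                    for c in doc["classes"]
                ],
                props=np.array(doc["props"]),
                family=doc["family"],
                var_names=list(doc["var_names"]),
                bic=doc["bic"],
                loglik=doc["loglik"],
            )
        if doc["kind"] == "augmented":
            K = len(doc["learned_means"])
            P = doc["p_count"]
            R = len(doc["var_names"])
            return AugmentedModel(
                var_names=list(doc["var_names"]),
                p_count=P,
                learned_means=np.array(doc["learned_means"]).reshape(K, P),
                learned_covs=np.array(doc["learned_covs"]).reshape(K, P, P),
                mu_q=np.array(doc["mu_q"]).reshape(K, R - P),
                cross=np.array(doc["cross"]).reshape(K, P, R - P),
                sigma_q=np.array(doc["sigma_q"]).reshape(K, R - P, R - P),
                hidden=[
                    GaussianClass(np.array(c["mean"]), np.array(c["cov"]), c["name"])
                    for c in doc["hidden"]
                ],
                props=np.array(doc["props"]),
                class_names=list(doc["class_names"]),
                learned_props=None
                if doc.get("learned_props") is None
                else np.array(doc["learned_props"]),
            )
        raise ModelParseError(f"unknown model kind {doc['kind']!r}")
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelParseError):
            raise
        raise ModelParseError(f"malformed model document: {exc}") from exc
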