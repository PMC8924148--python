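"""Shared fixtures and small generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from damda import DataMatrix, LabelSet, fit_edda
from damda.model_core import GaussianClass, LearnedClassifier


def random_spd(rng: np.random.Generator, dim: int, cond: float = 5.0) -> np.ndarray:
    """Random SPD matrix with bounded condition number."""
    half = 0.5 * np.log(cond)
    ev = np.exp(rng.uniform(-half, half, size=dim))
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    return (Q * ev) @ Q.T


def random_mixture(rng, C, R, sep=3.0, cond=5.0):
    """Random C-component Gaussian mixture parameters on R variables."""
    means = sep * rng.standard_normal((C, R))
    covs = np.stack([random_spd(rng, R, cond) for _ in range(C)])
    props = rng.dirichlet(np.full(C, 8.0))
    return means, covs, props


def sample_mixture(rng, n, means, covs, props):
    labels = rng.choice(means.shape[0], size=n, p=props)
    X = np.empty((n, means.shape[1]))
    for c in np.unique(labels):
        rows = labels == c
        X[rows] = rng.multivariate_normal(
            means[c], covs[c], size=int(rows.sum()), method="cholesky"
        )
    return X, labels


def discovery_instance(rng, K, H, P, Q, N, M=150):
    """A random learned-classifier / test-data pair for the discovery phase.

    The test data come from a (K + H)-component mixture on R = P + Q
    variables; the classifier is an EDDA fit on a labelled sample of the
    first K components restricted to the first P variables.
    """
    C, R = K + H, P + Q
    means, covs, _ = random_mixture(rng, C, R)
    var_names = [f"v{j}" for j in range(R)]
    # training sample: known classes only, P variables only
    known_props = np.full(K, 1.0 / K)
    while True:
        Xtr, ltr = sample_mixture(rng, M, means[:K, :P], covs[:K, :P, :P], known_props)
        if np.all(np.bincount(ltr, minlength=K) >= max(2, P + 1)):
            break
    train = DataMatrix(Xtr, var_names[:P])
    labels = LabelSet.from_labels([f"c{c}" for c in ltr], [f"c{c}" for c in range(K)])
    learned = fit_edda(train, labels)
    # test sample: all classes, all variables, mildly unbalanced
    props = rng.dirichlet(np.full(C, 10.0))
    Yte, lte = sample_mixture(rng, N, means, covs, props)
    test = DataMatrix(Yte, var_names)
    return learned, test, lte


def toy_classifier(means, covs, props, names=None) -> LearnedClassifier:
    means = np.atleast_2d(np.asarray(means, float))
    classes = [
        GaussianClass(means[k], np.atleast_2d(covs[k]), f"c{k}")
        for k in range(means.shape[0])
    ]
    names = names or [f"v{j}" for j in range(means.shape[1])]
    return LearnedClassifier(classes, np.asarray(props, float), "VVV", names)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
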