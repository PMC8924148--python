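"""Initialization of the discovery EM.

A hierarchical (Ward) partition of the test data into C = K + H clusters
seeds the mixture.  Each known class is matched one-to-one to the cluster
minimizing a Kullback-Leibler-type divergence computed on the training
variables; matched clusters inherit the fixed learning-phase parameters on
those variables and their own moments on the extras, the unmatched clusters
seed the hidden classes with their full moments.  Matching is solved as an
exact assignment problem (minimum total divergence over injections), so the
result does not depend on cluster enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .model_core import (
    AugmentedModel,
    DamdaError,
    DataMatrix,
    GaussianClass,
    LearnedClassifier,
)

#: eigenvalue floor for positive-definiteness repair, relative to trace/R
_PD_FLOOR = 1e-8


@dataclass
class ClusterMoments:
    """Per-cluster weighted moments split into P/Q blocks."""

    mu_p: np.ndarray  # (C, P)
    sigma_p: np.ndarray  # (C, P, P)
    mu_q: np.ndarray  # (C, Q)
    sigma_q: np.ndarray  # (C, Q, Q)
    cross: np.ndarray  # (C, P, Q)
    sizes: np.ndarray  # (C,)

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def full_mean(self, g: int) -> np.ndarray:
        return np.concatenate([self.mu_p[g], self.mu_q[g]])

    def full_cov(self, g: int) -> np.ndarray:
        P, Q = self.mu_p.shape[1], self.mu_q.shape[1]
        cov = np.empty((P + Q, P + Q))
        cov[:P, :P] = self.sigma_p[g]
        cov[:P, P:] = self.cross[g]
        cov[P:, :P] = self.cross[g].T
        cov[P:, P:] = self.sigma_q[g]
        return cov


def pd_repair(cov: np.ndarray) -> np.ndarray:
    """Raise eigenvalues below the relative floor; returns an SPD matrix."""
    cov = 0.5 * (cov + cov.T)
    R = cov.shape[0]
    floor = _PD_FLOOR * max(np.trace(cov) / max(R, 1), 1e-12)
    ev, vec = np.linalg.eigh(cov)
    if ev[0] >= floor:
        return cov
    ev = np.maximum(ev, floor)
    return (vec * ev) @ vec.T


def hierarchical_partition(
    test: DataMatrix | np.ndarray, C: int, linkage_cache: dict | None = None
) -> np.ndarray:
    """Deterministic Ward partition of the test data into C clusters.

    Columns are standardized first so the agglomeration is scale-free.
    Returns 0-based cluster labels.
    """
    Y = test.values if isinstance(test, DataMatrix) else np.asarray(test, float)
    N = Y.shape[0]
    if C > N:
        raise DamdaError(f"cannot form {C} clusters from {N} observations")
    if C == N:
        return np.arange(N)
    key = "linkage"
    if linkage_cache is not None and key in linkage_cache:
        Z = linkage_cache[key]
    else:
        sd = Y.std(axis=0)
        sd[sd < 1e-12] = 1.0
        Z = linkage((Y - Y.mean(axis=0)) / sd, method="ward")
        if linkage_cache is not None:
            linkage_cache[key] = Z
    return fcluster(Z, t=C, criterion="maxclust") - 1


def random_partition(N: int, C: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition with every cluster non-empty (used for EM restarts)."""
    if C > N:
        raise DamdaError(f"cannot form {C} clusters from {N} observations")
    part = rng.integers(0, C, size=N)
    # guarantee non-empty clusters
    missing = np.setdiff1d(np.arange(C), np.unique(part))
    if missing.size:
        idx = rng.choice(N, size=missing.size, replace=False)
        part[idx] = missing
    return part


def cluster_moments(
    test: DataMatrix | np.ndarray, partition: np.ndarray, p_count: int
) -> ClusterMoments:
    """Within-cluster means and covariance blocks, with small-cluster shrinkage.

    Clusters with fewer than R + 2 members have their covariance shrunk
    toward the pooled covariance, with weight proportional to the deficiency;
    every covariance is PD-repaired.
    """
    Y = test.values if isinstance(test, DataMatrix) else np.asarray(test, float)
    part = np.asarray(partition)
    C = int(part.max()) + 1
    N, R = Y.shape
    P, Q = p_count, R - p_count
    pooled = np.cov(Y, rowvar=False, bias=True).reshape(R, R)
    pooled = pd_repair(pooled)

    mu = np.empty((C, R))
    cov = np.empty((C, R, R))
    sizes = np.empty(C)
    for g in range(C):
        rows = Y[part == g]
        n_g = rows.shape[0]
        if n_g == 0:
            raise DamdaError(f"cluster {g} is empty")
        sizes[g] = n_g
        mu[g] = rows.mean(axis=0)
        own = np.zeros((R, R))
        if n_g > 1:
            rc = rows - mu[g]
            own = rc.T @ rc / n_g
        w = min(1.0, max(n_g - 1.0, 0.0) / (R + 2.0))
        cov[g] = pd_repair(w * own + (1.0 - w) * pooled)
    return ClusterMoments(
        mu_p=mu[:, :P],
        sigma_p=cov[:, :P, :P],
        mu_q=mu[:, P:],
        sigma_q=cov[:, P:, P:],
        cross=cov[:, :P, P:],
        sizes=sizes,
    )


def kl_divergence(
    mu_g: np.ndarray, sigma_g: np.ndarray, mu_k: np.ndarray, sigma_k: np.ndarray
) -> float:
    """Divergence used for cluster-to-class matching.

    tr(Sigma_g^-1 Sigma_k) + (mu_g - mu_k)' Sigma_g^-1 (mu_g - mu_k)
    + log(det Sigma_g / det Sigma_k); equals 2*KL + P when both are Gaussian,
    and is used only for ranking.
    """
    sigma_g = np.atleast_2d(np.asarray(sigma_g, float))
    sigma_k = np.atleast_2d(np.asarray(sigma_k, float))
    delta = np.asarray(mu_g, float).ravel() - np.asarray(mu_k, float).ravel()
    try:
        cf = sla.cho_factor(sigma_g, lower=True)
    except sla.LinAlgError as exc:
        raise DamdaError("cluster covariance is singular in KL matching") from exc
    trace_term = float(np.trace(sla.cho_solve(cf, sigma_k)))
    quad = float(delta @ sla.cho_solve(cf, delta))
    logdet_g = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sign, logdet_k = np.linalg.slogdet(sigma_k)
    if sign <= 0:
        raise DamdaError("class covariance has non-positive determinant")
    return trace_term + quad + logdet_g - logdet_k


def match_clusters(div: np.ndarray, K: int) -> tuple[np.ndarray, list[int]]:
    """Injective cluster-to-class matching minimizing total divergence.

    ``div`` is C x K (rows clusters, columns known classes).  Returns the
    array ``cluster_of_class`` (length K) and the sorted list of unmatched
    clusters, which seed the hidden classes.
    """
    div = np.atleast_2d(np.asarray(div, float))
    C = div.shape[0]
    if div.shape[1] != K or C < K:
        raise ValueError(f"divergence matrix must be CxK with C >= K, got {div.shape}")
    rows, cols = linear_sum_assignment(div)
    cluster_of_class = np.empty(K, dtype=int)
    cluster_of_class[cols] = rows
    hidden = sorted(set(range(C)) - set(rows.tolist()))
    return cluster_of_class, hidden


def init_parameters(
    learned: LearnedClassifier,
    moments: ClusterMoments,
    mapping: tuple[np.ndarray, list[int]],
    var_names: list[str],
) -> AugmentedModel:
    """Build the initial augmented model from matched cluster moments.

    Matched clusters take the fixed learning-phase parameters on the P
    block, their own moments on the extras; cross blocks are shrunk toward
    zero if needed so every assembled covariance is positive definite.
    """
    cluster_of_class, hidden_clusters = mapping
    K = learned.n_classes
    P = len(learned.var_names)
    Q = moments.mu_q.shape[1]
    mu_q = np.empty((K, Q))
    cross = np.empty((K, P, Q))
    sigma_q = np.empty((K, Q, Q))
    lc = learned.covs()
    for k in range(K):
        g = cluster_of_class[k]
        mu_q[k] = moments.mu_q[g]
        sq = pd_repair(moments.sigma_q[g]) if Q else moments.sigma_q[g]
        cr = moments.cross[g]
        # shrink the cross block until the Schur complement is PD
        for _ in range(12):
            schur = sq - cr.T @ np.linalg.solve(lc[k], cr)
            try:
                np.linalg.cholesky(0.5 * (schur + schur.T) + 1e-300 * np.eye(Q))
                break
            except np.linalg.LinAlgError:
                cr = 0.5 * cr
        else:
            cr = np.zeros_like(cr)
        cross[k], sigma_q[k] = cr, sq

    hidden = [
        GaussianClass(moments.full_mean(g), pd_repair(moments.full_cov(g)))
        for g in hidden_clusters
    ]
    order = list(cluster_of_class) + list(hidden_clusters)
    props = moments.sizes[order] / moments.sizes.sum()
    class_names = list(learned.class_names) + [
        f"hidden_{h}" for h in range(len(hidden_clusters))
    ]
    return AugmentedModel(
        var_names=list(var_names),
        p_count=P,
        learned_means=learned.means(),
        learned_covs=learned.covs(),
        mu_q=mu_q,
        cross=cross,
        sigma_q=sigma_q,
        hidden=hidden,
        props=props,
        class_names=class_names,
        learned_props=learned.props.copy(),
    )


def initialize(
    aligned_test: DataMatrix,
    learned: LearnedClassifier,
    H: int,
    partition: np.ndarray | None = None,
    linkage_cache: dict | None = None,
) -> AugmentedModel:
    """Full initialization pipeline for the discovery EM.

    ``aligned_test`` must have the learned variables first (see
    :func:`damda.discovery.align_test`).  Deterministic given the data and
    H unless an explicit ``partition`` is supplied.
    """
    K = learned.n_classes
    C = K + H
    if partition is None:
        partition = hierarchical_partition(aligned_test, C, linkage_cache)
    moments = cluster_moments(aligned_test, partition, len(learned.var_names))
    if moments.n_clusters < C:
        raise DamdaError(
            f"partition produced {moments.n_clusters} clusters, expected {C}"
        )
    div = np.empty((C, K))
    for g in range(C):
        for k in range(K):
            div[g, k] = kl_divergence(
                moments.mu_p[g],
                moments.sigma_p[g],
                learned.classes[k].mean,
                learned.classes[k].cov,
            )
    mapping = match_clusters(div, K)
    return init_parameters(learned, moments, mapping, aligned_test.var_names)
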