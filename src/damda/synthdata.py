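"""Synthetic-data generator for the adaptive-classification study designs.

Test observations carry three kinds of variables: *Gen* (class-generative,
distributed as a C-component Gaussian mixture), *Cor* (each a noisy linear
combination of two randomly chosen Gen variables — informative about the
classes only through Gen), and *Noi* (independent Gaussian noise).  Only a
random subset of classes and a policy-chosen subset of variables are
observed in the training set; the test set contains all classes and all
variables.  Evaluation helpers compute the adjusted Rand index and the
classification error after optimal class matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .model_core import DataMatrix, LabelSet


@dataclass
class SimSpec:
    """Configuration of one simulated classification problem.

    Defaults reproduce the 100-variable design (10 Gen, 30 Cor, 60 Noi,
    C = 4 classes of which 2 observed in training, 20 observed variables).
    ``separation`` is the minimum pairwise distance between class means in
    units of the average within-class standard deviation.
    """

    n_gen: int = 10
    n_cor: int = 30
    n_noi: int = 60
    C: int = 4
    K_obs: int = 2
    separation: float = 3.0
    cor_link_count: int = 2
    cor_noise_frac: float = 0.35  # Cor noise variance / linked-signal variance
    noise_var: float = 1.0  # Noi variance
    cov_cond_max: float = 10.0  # condition-number cap of class covariances
    M: int = 400
    N: int = 400
    observed_var_policy: str = "all-gen+random"
    observed_total: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_obs > self.C:
            raise ValueError("K_obs cannot exceed C")
        if min(self.n_gen, self.C) < 1 or min(self.n_cor, self.n_noi) < 0:
            raise ValueError("variable counts must be non-negative, n_gen >= 1")
        if self.n_gen < self.C - 1:
            raise ValueError("need n_gen >= C - 1 to separate C classes")
        if self.cor_link_count > self.n_gen:
            raise ValueError("cor_link_count cannot exceed n_gen")


@dataclass
class SimData:
    """One generated problem instance."""

    train: DataMatrix
    train_labels: LabelSet
    test: DataMatrix
    truth: LabelSet
    observed_vars: list[str]
    observed_classes: list[str]
    hidden_classes: list[str]
    gen_names: list[str]
    cor_names: list[str]
    noi_names: list[str]
    class_means: np.ndarray  # (C, n_gen)
    class_covs: np.ndarray  # (C, n_gen, n_gen)
    cor_links: dict[str, list[str]] = field(default_factory=dict)
    cor_weights: np.ndarray | None = None  # (n_gen, n_cor)
    cor_noise_sd: np.ndarray | None = None  # (n_cor,)
    noi_var: float = 1.0

    def population_moments(self, class_index: int) -> tuple[np.ndarray, np.ndarray]:
        """True within-class mean and covariance on all R variables.

        Gen block has the class parameters; Cor columns are W'Gen plus
        independent noise; Noi columns are independent of everything.
        """
        mu_g = self.class_means[class_index]
        S_g = self.class_covs[class_index]
        W = self.cor_weights if self.cor_weights is not None else np.zeros((mu_g.size, 0))
        n_noi = len(self.noi_names)
        mean = np.concatenate([mu_g, W.T @ mu_g, np.zeros(n_noi)])
        d = mean.size
        cov = np.zeros((d, d))
        g, c = mu_g.size, W.shape[1]
        cov[:g, :g] = S_g
        cov[:g, g : g + c] = S_g @ W
        cov[g : g + c, :g] = W.T @ S_g
        cov[g : g + c, g : g + c] = W.T @ S_g @ W + np.diag(self.cor_noise_sd**2)
        if n_noi:
            cov[g + c :, g + c :] = self.noi_var * np.eye(n_noi)
        return mean, cov


def _random_spd(dim: int, cond_max: float, rng: np.random.Generator) -> np.ndarray:
    """Random SPD matrix with unit geometric-mean eigenvalue, bounded condition."""
    half = 0.5 * np.log(cond_max)
    logev = rng.uniform(-half, half, size=dim)
    logev -= logev.mean()  # geometric mean 1
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    return (Q * np.exp(logev)) @ Q.T


def _simplex_means(spec: SimSpec, covs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Class means at the vertices of a randomly rotated regular simplex.

    ``separation`` is the per-coordinate scale of the classic simplex
    layout (mean vectors ``separation * e_c``), so pairwise mean distances
    equal ``sqrt(2) * separation`` within-class standard deviations.  The
    scaling is applied in Mahalanobis units — the *minimum* pairwise
    Mahalanobis distance (with respect to the average covariance of each
    pair) is ``sqrt(2) * separation`` — so anisotropic class covariances
    cannot silently shrink the effective separation.
    """
    C, d = spec.C, spec.n_gen
    # regular simplex in C-1 dimensions with unit pairwise distances
    V = np.eye(C)[:, : C - 1]
    centroid = V.mean(axis=0)
    V = (V - centroid) / np.sqrt(2.0)
    basis, _ = np.linalg.qr(rng.standard_normal((d, C - 1)))
    U = V @ basis.T  # unit-distance vertices in d dimensions
    min_maha = np.inf
    for a in range(C):
        for b in range(a + 1, C):
            diff = U[a] - U[b]
            pair_cov = 0.5 * (covs[a] + covs[b])
            min_maha = min(min_maha, float(np.sqrt(diff @ np.linalg.solve(pair_cov, diff))))
    return (np.sqrt(2.0) * spec.separation / min_maha) * U


def generate(spec: SimSpec) -> SimData:
    """Generate one training/test pair following the Gen/Cor/Noi design."""
    rng = np.random.default_rng(spec.seed)
    gen_names = [f"Gen{j+1:02d}" for j in range(spec.n_gen)]
    cor_names = [f"Cor{j+1:02d}" for j in range(spec.n_cor)]
    noi_names = [f"Noi{j+1:02d}" for j in range(spec.n_noi)]
    class_names = [f"class_{c+1}" for c in range(spec.C)]

    covs = np.stack([_random_spd(spec.n_gen, spec.cov_cond_max, rng) for _ in range(spec.C)])
    means = _simplex_means(spec, covs, rng)

    # population (test-mixture) moments of the Gen block, uniform class weights
    mix_mean = means.mean(axis=0)
    mix_cov = covs.mean(axis=0) + np.einsum(
        "ci,cj->ij", means - mix_mean, means - mix_mean
    ) / spec.C

    links = []
    weights = []
    noise_sd = []
    for _ in range(spec.n_cor):
        pick = rng.choice(spec.n_gen, size=spec.cor_link_count, replace=False)
        w = rng.uniform(0.7, 1.3, size=spec.cor_link_count) * rng.choice(
            [-1.0, 1.0], size=spec.cor_link_count
        )
        wvec = np.zeros(spec.n_gen)
        wvec[pick] = w
        var_signal = float(wvec @ mix_cov @ wvec)
        links.append(pick)
        weights.append(wvec)
        noise_sd.append(np.sqrt(spec.cor_noise_frac * var_signal))

    observed_classes_idx = np.sort(rng.choice(spec.C, size=spec.K_obs, replace=False))
    hidden_classes_idx = [c for c in range(spec.C) if c not in observed_classes_idx]

    def _sample(n: int, class_pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        labs = rng.choice(class_pool, size=n)
        X_gen = np.empty((n, spec.n_gen))
        for c in np.unique(labs):
            rows = labs == c
            X_gen[rows] = rng.multivariate_normal(
                means[c], covs[c], size=int(rows.sum()), method="cholesky"
            )
        cols = [X_gen]
        if spec.n_cor:
            cor = np.column_stack(
                [
                    X_gen @ weights[j] + noise_sd[j] * rng.standard_normal(n)
                    for j in range(spec.n_cor)
                ]
            )
            cols.append(cor)
        if spec.n_noi:
            cols.append(np.sqrt(spec.noise_var) * rng.standard_normal((n, spec.n_noi)))
        return np.column_stack(cols), labs

    all_names = gen_names + cor_names + noi_names
    X_train_full, train_labs = _sample(spec.M, observed_classes_idx)
    X_test, test_labs = _sample(spec.N, np.arange(spec.C))

    observed_vars = _observed_variables(spec, gen_names, cor_names, noi_names, rng)
    obs_idx = [all_names.index(v) for v in observed_vars]

    train = DataMatrix(X_train_full[:, obs_idx], observed_vars)
    train_labels = LabelSet.from_labels(
        [class_names[c] for c in train_labs],
        [class_names[c] for c in observed_classes_idx],
    )
    test = DataMatrix(X_test, all_names)
    truth = LabelSet.from_labels([class_names[c] for c in test_labs], class_names)

    return SimData(
        train=train,
        train_labels=train_labels,
        test=test,
        truth=truth,
        observed_vars=observed_vars,
        observed_classes=[class_names[c] for c in observed_classes_idx],
        hidden_classes=[class_names[c] for c in hidden_classes_idx],
        gen_names=gen_names,
        cor_names=cor_names,
        noi_names=noi_names,
        class_means=means,
        class_covs=covs,
        cor_links={cor_names[j]: [gen_names[g] for g in links[j]] for j in range(spec.n_cor)},
        cor_weights=np.column_stack(weights) if weights else np.zeros((spec.n_gen, 0)),
        cor_noise_sd=np.asarray(noise_sd, float),
        noi_var=spec.noise_var,
    )


def _observed_variables(
    spec: SimSpec,
    gen_names: list[str],
    cor_names: list[str],
    noi_names: list[str],
    rng: np.random.Generator,
) -> list[str]:
    """Choose the training variables according to the scenario policy."""
    pool_cn = cor_names + noi_names
    total = spec.observed_total
    if spec.observed_var_policy == "all-gen+random":
        n_extra = total - spec.n_gen
        if n_extra < 0:
            raise ValueError("observed_total smaller than the number of Gen variables")
        extra = rng.choice(len(pool_cn), size=n_extra, replace=False)
        chosen = gen_names + [pool_cn[i] for i in extra]
    elif spec.observed_var_policy == "half-gen":
        g = spec.n_gen // 2
        gen_pick = rng.choice(spec.n_gen, size=g, replace=False)
        cor_pick = rng.choice(spec.n_cor, size=min(g, spec.n_cor), replace=False)
        chosen = [gen_names[i] for i in gen_pick] + [cor_names[i] for i in cor_pick]
        rest_pool = [v for v in pool_cn if v not in chosen]
        n_rest = total - len(chosen)
        rest = rng.choice(len(rest_pool), size=n_rest, replace=False)
        chosen = chosen + [rest_pool[i] for i in rest]
    elif spec.observed_var_policy == "few-gen":
        g = max(2, spec.n_gen // 5)
        gen_pick = rng.choice(spec.n_gen, size=g, replace=False)
        chosen = [gen_names[i] for i in gen_pick]
        rest = rng.choice(len(pool_cn), size=total - g, replace=False)
        chosen = chosen + [pool_cn[i] for i in rest]
    else:
        raise ValueError(f"unknown observed_var_policy {spec.observed_var_policy!r}")
    if len(chosen) != total:
        raise ValueError("observed-variable policy produced the wrong count")
    return chosen


# ---------------------------------------------------------------------------
# evaluation metrics


def _as_codes(x) -> np.ndarray:
    if isinstance(x, LabelSet):
        return np.argmax(x.indicators, axis=1)
    return np.asarray(x)


def ari(a, b) -> float:
    """Adjusted (Hubert-Arabie) Rand index between two partitions."""
    a, b = _as_codes(a), _as_codes(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("partitions must have the same length")
    return float(adjusted_rand_score(a, b))


def matched_error(truth, pred) -> float:
    """Misclassification rate after optimal one-to-one class matching.

    Predicted classes are matched to true classes by maximizing agreement on
    the confusion matrix (rectangular assignments allowed); unmatched
    predictions count as errors.
    """
    t, p = _as_codes(truth), _as_codes(pred)
    if t.shape[0] != p.shape[0]:
        raise ValueError("partitions must have the same length")
    tc = np.unique(t)
    pc = np.unique(p)
    conf = np.zeros((tc.size, pc.size))
    for i, a in enumerate(tc):
        for j, b in enumerate(pc):
            conf[i, j] = np.sum((t == a) & (p == b))
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(1.0 - conf[rows, cols].sum() / t.shape[0])
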