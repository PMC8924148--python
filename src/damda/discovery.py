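"""Discovery phase: EM on the test data with learning-phase parameters fixed.

The test data carry R = P + Q variables (the P training variables first,
extras after) and possibly H classes never seen in training.  The EM
maximizes the observed-data mixture log-likelihood while holding the
learned per-class means and covariances on the P training variables
bit-identical to the learning phase.  The M-step for the known classes is
the *inductive conditional estimation* procedure: the P-marginal is fixed,
the conditional distribution of the extras given the training variables is
estimated in closed form from the blocks of the weighted scattering matrix,
and the augmented covariance is assembled so that positive definiteness is
certified by the Schur complement.

Closed forms (W, V, U are the blocks of the weighted scatter O_k):

    C_k      = (Sbar^-1 W Sbar^-1)^-1 (Sbar^-1 V)  =  Sbar W^-1 V
    E_k      = [C_k' Sbar^-1 W Sbar^-1 C_k - 2 V' Sbar^-1 C_k + U] / N_k
             = (U - V' W^-1 V) / N_k
    mu_Q     = [sum_i t_ik y_i^Q - C_k' Sbar^-1 sum_i t_ik (y_i^P - mubar)] / N_k
    Sigma_Q  = E_k + C_k' Sbar^-1 C_k

The simplified right-hand sides are algebraically identical to the printed
expressions and numerically better behaved; the test-suite checks both
routes against each other and against a direct numerical maximizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import linalg as sla

from . import init as init_mod
from .model_core import (
    AugmentedModel,
    DamdaError,
    DataMatrix,
    GaussianClass,
    LearnedClassifier,
    Responsibilities,
    log_density_model,
    posterior_from_logs,
)


class EmptyClassError(DamdaError):
    """A mixture component received (numerically) zero test mass."""


class SingularScatterError(DamdaError):
    """The W block of a class scatter is numerically singular."""


class AssemblyError(DamdaError):
    """The assembled augmented covariance is not positive definite."""


@dataclass
class EMControl:
    """Tuning knobs of the discovery EM.

    regularize: ``"off"`` fails loudly on singular scatters, ``"on"`` always
    adds the inverse-Wishart-style prior scatter ``nu * Psi``, ``"auto"``
    adds it only for classes whose effective size falls below the total
    variable count R (the point where the class scatter must be singular).
    """

    tol: float = 1e-5
    max_iter: int = 500
    h_range: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    seed: int = 0
    regularize: str = "off"
    #: "reestimate" (default): tau_c = N_c/N for all classes on the test data.
    #: "renormalize": keep the learned known-class proportions, scaled by the
    #: mass left over from the hidden classes.  Biased when class balance
    #: shifts; provided for comparison only.
    prop_update: str = "reestimate"
    reg_nu: float | None = None  # default R + 2
    reg_psi: np.ndarray | None = None  # default diag of pooled test variances
    restarts: int = 5
    cond_threshold: float = 1e12

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.regularize not in ("off", "auto", "on"):
            raise ValueError("regularize must be 'off', 'auto' or 'on'")
        if self.prop_update not in ("reestimate", "renormalize"):
            raise ValueError("prop_update must be 'reestimate' or 'renormalize'")
        if self.reg_nu is not None and self.reg_nu < 0:
            raise ValueError("reg_nu must be non-negative")
        self.h_range = tuple(sorted(set(int(h) for h in self.h_range)))
        if any(h < 0 for h in self.h_range):
            raise ValueError("h_range entries must be >= 0")


@dataclass
class ScatterPartition:
    """Blocks of the weighted class scatter O_k = [[W, V], [V', U]].

    ``n_k`` is the raw effective class size sum_i t_ik; ``n_eff`` is the
    divisor used downstream (inflated to n_k + nu under regularization);
    ``ybar`` is the weighted mean on all R variables.
    """

    W: np.ndarray
    V: np.ndarray
    U: np.ndarray
    n_k: float
    ybar: np.ndarray
    n_eff: float | None = None

    def __post_init__(self) -> None:
        if self.n_eff is None:
            self.n_eff = self.n_k

    def assembled(self) -> np.ndarray:
        P, Q = self.W.shape[0], self.U.shape[0]
        O = np.empty((P + Q, P + Q))
        O[:P, :P] = self.W
        O[:P, P:] = self.V
        O[P:, :P] = self.V.T
        O[P:, P:] = self.U
        return O


@dataclass
class DiscoveryFit:
    model: AugmentedModel
    responsibilities: Responsibilities
    loglik_trace: list[float]
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass
class SelectionResult:
    model: AugmentedModel
    h_star: int
    bic_table: dict[int, float | None]
    fit: DiscoveryFit

    @property
    def bic(self) -> float:
        return self.bic_table[self.h_star]


# ---------------------------------------------------------------------------
# building blocks


def align_test(test: DataMatrix, learned: LearnedClassifier) -> tuple[DataMatrix, int]:
    """Reorder test columns: learned variables first (learned order), extras after."""
    extras = [v for v in test.var_names if v not in set(learned.var_names)]
    aligned = test.select(list(learned.var_names) + extras)
    return aligned, len(learned.var_names)


def e_step(model: AugmentedModel, test: DataMatrix) -> Responsibilities:
    """Posterior responsibilities t_ic under the current augmented model."""
    aligned = test.select(model.var_names)
    t, _ = _e_step_arrays(aligned.values, model)
    return Responsibilities(t)


def _e_step_arrays(Y: np.ndarray, model: AugmentedModel) -> tuple[np.ndarray, float]:
    log_dens = log_density_model(Y, model.all_means(), model.all_covs())
    if not np.all(np.isfinite(log_dens)):
        bad = int(np.argwhere(~np.isfinite(log_dens))[0][0])
        raise DamdaError(f"non-finite class density at observation {bad}")
    return posterior_from_logs(log_dens, model.props)


def update_props(t: np.ndarray | Responsibilities) -> np.ndarray:
    """Mixing-proportion update: tau_c = N_c / N for known and hidden classes."""
    probs = t.probs if isinstance(t, Responsibilities) else np.asarray(t, float)
    return probs.sum(axis=0) / probs.shape[0]


def update_hidden(
    test: DataMatrix | np.ndarray, t: np.ndarray | Responsibilities, h_index: int
) -> GaussianClass:
    """Weighted mean/covariance update of one hidden class."""
    Y = test.values if isinstance(test, DataMatrix) else np.asarray(test, float)
    probs = t.probs if isinstance(t, Responsibilities) else np.asarray(t, float)
    w = probs[:, h_index]
    n_h = float(w.sum())
    if n_h <= 1e-8:
        raise EmptyClassError(f"hidden class {h_index} has effective size {n_h:.3g}")
    mean = (w @ Y) / n_h
    Yc = Y - mean
    cov = (Yc.T * w) @ Yc / n_h
    return GaussianClass(mean, 0.5 * (cov + cov.T))


def scatter_partition(
    test: DataMatrix | np.ndarray, t_col: np.ndarray, p_count: int
) -> ScatterPartition:
    """Weighted scatter O_k about the weighted mean, split into W, V, U blocks."""
    Y = test.values if isinstance(test, DataMatrix) else np.asarray(test, float)
    w = np.asarray(t_col, float)
    n_k = float(w.sum())
    ybar = (w @ Y) / n_k if n_k > 0 else np.zeros(Y.shape[1])
    Yc = Y - ybar
    O = (Yc.T * w) @ Yc
    O = 0.5 * (O + O.T)
    return ScatterPartition(
        W=O[:p_count, :p_count],
        V=O[:p_count, p_count:],
        U=O[p_count:, p_count:],
        n_k=n_k,
        ybar=ybar,
    )


def regularize_scatter(
    sp: ScatterPartition, psi: np.ndarray, nu: float
) -> ScatterPartition:
    """Bayesian regularization: O_k <- O_k + nu * Psi, divisor <- N_k + nu."""
    if nu < 0:
        raise ValueError("prior weight nu must be non-negative")
    if nu == 0:
        return sp
    P = sp.W.shape[0]
    psi = np.atleast_2d(np.asarray(psi, float))
    R = P + sp.U.shape[0]
    if psi.shape != (R, R):
        raise ValueError(f"prior scale matrix must be {R}x{R}")
    return ScatterPartition(
        W=sp.W + nu * psi[:P, :P],
        V=sp.V + nu * psi[:P, P:],
        U=sp.U + nu * psi[P:, P:],
        n_k=sp.n_k,
        ybar=sp.ybar,
        n_eff=sp.n_k + nu,
    )


def conditional_estimates(
    sp: ScatterPartition, sigma_bar: np.ndarray, cond_threshold: float = 1e12
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (C_k, E_k) of the conditional distribution of extras.

    Requires the W block to be invertible; beyond ``cond_threshold`` the
    computation refuses to proceed and advises regularization.
    """
    W, V, U = sp.W, sp.V, sp.U
    ev = np.linalg.eigvalsh(W)
    if ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > cond_threshold:
        raise SingularScatterError(
            "scatter block W is singular or ill-conditioned; enable the "
            "regularization option (EMControl.regularize)"
        )
    B = sla.solve(W, V, assume_a="pos")  # W^-1 V
    C_k = sigma_bar @ B
    E_k = (U - V.T @ B) / sp.n_eff
    return C_k, 0.5 * (E_k + E_k.T)


def marginal_extras(
    sp: ScatterPartition,
    sigma_bar: np.ndarray,
    mu_bar: np.ndarray,
    C_k: np.ndarray,
    E_k: np.ndarray,
    test_extras: np.ndarray | None = None,
    t_col: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal mean and covariance of the extra variables for a known class.

    The weighted sums in the printed expressions equal ``N_k`` times the
    weighted means stored in the scatter partition, so ``test_extras`` and
    ``t_col`` are accepted for interface compatibility but not required.
    """
    P = sigma_bar.shape[0]
    ybar_p, ybar_q = sp.ybar[:P], sp.ybar[P:]
    adj = sla.solve(sigma_bar, C_k, assume_a="pos")  # Sbar^-1 C_k
    mu_q = ybar_q - adj.T @ (ybar_p - mu_bar)
    sigma_q = E_k + C_k.T @ adj
    return mu_q, 0.5 * (sigma_q + sigma_q.T)


def assemble_known(
    mu_bar: np.ndarray,
    sigma_bar: np.ndarray,
    mu_q: np.ndarray,
    C_k: np.ndarray,
    sigma_q: np.ndarray,
) -> GaussianClass:
    """Assemble the augmented Gaussian of a known class and certify SPD.

    Positive definiteness holds iff the Schur complement
    ``sigma_q - C_k' sigma_bar^-1 C_k`` (the conditional covariance E_k)
    is positive definite.
    """
    mu_bar = np.asarray(mu_bar, float).ravel()
    mu_q = np.asarray(mu_q, float).ravel()
    P, Q = mu_bar.size, mu_q.size
    if C_k.shape != (P, Q) or sigma_q.shape != (Q, Q):
        raise ValueError("inconsistent block dimensions")
    mean = np.concatenate([mu_bar, mu_q])
    cov = np.empty((P + Q, P + Q))
    cov[:P, :P] = sigma_bar
    cov[:P, P:] = C_k
    cov[P:, :P] = C_k.T
    cov[P:, P:] = sigma_q
    if Q > 0:
        schur = sigma_q - C_k.T @ sla.solve(sigma_bar, C_k, assume_a="pos")
        try:
            np.linalg.cholesky(0.5 * (schur + schur.T))
        except np.linalg.LinAlgError as exc:
            raise AssemblyError(
                "Schur complement of the assembled covariance is not positive "
                "definite (singular or ill-conditioned class scatter upstream)"
            ) from exc
    return GaussianClass(mean, cov)


def count_params(K: int, H: int, P: int, Q: int) -> int:
    """Free-parameter count eta_H of the discovery phase.

    eta_H = (H + K - 1) + 2HR + H*C(R,2) + 2KQ + KPQ + K*C(Q,2), R = P + Q.
    """
    if min(K, H + 1, P, Q + 1) < 1 or K < 1:
        raise ValueError("need K >= 1 and H, Q >= 0, P >= 1")
    R = P + Q
    return (
        (H + K - 1)
        + 2 * H * R
        + H * comb(R, 2)
        + 2 * K * Q
        + K * P * Q
        + K * comb(Q, 2)
    )


# ---------------------------------------------------------------------------
# EM driver


def _default_prior(Y: np.ndarray, ctrl: EMControl) -> tuple[np.ndarray, float]:
    R = Y.shape[1]
    psi = ctrl.reg_psi
    if psi is None:
        psi = np.diag(np.var(Y, axis=0))
    psi = np.atleast_2d(np.asarray(psi, float))
    nu = float(ctrl.reg_nu) if ctrl.reg_nu is not None else float(R + 2)
    return psi, nu


def _reg_active(mode: str, n_k: float, R: float) -> bool:
    if mode == "on":
        return True
    if mode == "auto":
        return n_k < R
    return False


def _m_step(
    Y: np.ndarray,
    t: np.ndarray,
    model: AugmentedModel,
    ctrl: EMControl,
    psi: np.ndarray,
    nu: float,
) -> AugmentedModel:
    N, R = Y.shape
    K, H, P = model.n_known, model.n_hidden, model.p_count
    Q = R - P
    n_c = t.sum(axis=0)
    if np.any(n_c < 1e-8):
        empty = int(np.argmin(n_c))
        raise EmptyClassError(
            f"class {model.class_names[empty]} collapsed (N_c = {n_c[empty]:.3g})"
        )
    props = n_c / N
    if ctrl.prop_update == "renormalize" and model.learned_props is not None:
        hidden_mass = float(props[K:].sum())
        props = np.concatenate(
            [model.learned_props * (1.0 - hidden_mass), props[K:]]
        )

    mu_q = model.mu_q
    cross = model.cross
    sigma_q = model.sigma_q
    if Q > 0:
        mu_q = np.empty((K, Q))
        cross = np.empty((K, P, Q))
        sigma_q = np.empty((K, Q, Q))
        for k in range(K):
            sp = scatter_partition(Y, t[:, k], P)
            if _reg_active(ctrl.regularize, sp.n_k, R):
                sp = regularize_scatter(sp, psi, nu)
            C_k, E_k = conditional_estimates(sp, model.learned_covs[k], ctrl.cond_threshold)
            mq, sq = marginal_extras(
                sp, model.learned_covs[k], model.learned_means[k], C_k, E_k
            )
            # Schur complement equals E_k by construction; verify it is PD
            try:
                np.linalg.cholesky(E_k + 1e-300 * np.eye(Q))
            except np.linalg.LinAlgError as exc:
                raise AssemblyError(
                    f"conditional covariance of class {model.class_names[k]} "
                    "is not positive definite; enable regularization"
                ) from exc
            mu_q[k], cross[k], sigma_q[k] = mq, C_k, sq

    hidden = []
    for h in range(H):
        w = t[:, K + h]
        n_h = float(w.sum())
        mean = (w @ Y) / n_h
        Yc = Y - mean
        scat = (Yc.T * w) @ Yc
        if _reg_active(ctrl.regularize, n_h, R):
            cov = (scat + nu * psi) / (n_h + nu)
        else:
            cov = scat / n_h
        cov = 0.5 * (cov + cov.T)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise SingularScatterError(
                f"hidden class {h} covariance is singular; enable regularization"
            ) from exc
        hidden.append(GaussianClass(mean, cov, model.class_names[K + h]))

    return AugmentedModel(
        var_names=model.var_names,
        p_count=P,
        learned_means=model.learned_means,  # fixed, shared by reference
        learned_covs=model.learned_covs,
        mu_q=mu_q,
        cross=cross,
        sigma_q=sigma_q,
        hidden=hidden,
        props=props,
        class_names=model.class_names,
        learned_props=model.learned_props,
    )


def _run_em(
    Y: np.ndarray, model: AugmentedModel, ctrl: EMControl
) -> DiscoveryFit:
    psi, nu = _default_prior(Y, ctrl)
    trace: list[float] = []
    t = None
    converged = False
    for it in range(ctrl.max_iter):
        t, ll = _e_step_arrays(Y, model)
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) / (1.0 + abs(trace[-1])) < ctrl.tol:
            converged = True
            break
        model = _m_step(Y, t, model, ctrl, psi, nu)
    if not converged:
        # keep responsibilities consistent with the returned model
        t, ll = _e_step_arrays(Y, model)
        trace.append(ll)
    return DiscoveryFit(model, Responsibilities(t), trace, converged)


def em_discovery(
    test: DataMatrix,
    learned: LearnedClassifier,
    H: int,
    init: AugmentedModel | None = None,
    ctrl: EMControl | None = None,
) -> DiscoveryFit:
    """Fit the discovery-phase model with H hidden classes.

    Initialization defaults to the hierarchical-partition / KL-matching
    strategy; if a class empties mid-run the fit restarts from a random
    partition (fresh sub-seed) up to ``ctrl.restarts`` times.
    """
    ctrl = ctrl or EMControl()
    aligned, p_count = align_test(test, learned)
    Y = aligned.values
    if H < 0:
        raise ValueError("H must be >= 0")
    if init is None:
        init = init_mod.initialize(aligned, learned, H)
    last_err: Exception | None = None
    for attempt in range(ctrl.restarts + 1):
        try:
            if attempt > 0:
                rng = np.random.default_rng((ctrl.seed + 7919 * attempt) % (2**31))
                part = init_mod.random_partition(Y.shape[0], learned.n_classes + H, rng)
                init = init_mod.initialize(aligned, learned, H, partition=part)
            return _run_em(Y, init, ctrl)
        except EmptyClassError as exc:
            last_err = exc
    raise EmptyClassError(
        f"discovery EM failed after {ctrl.restarts} restarts: {last_err}"
    )


def select_H(
    test: DataMatrix,
    learned: LearnedClassifier,
    ctrl: EMControl | None = None,
) -> SelectionResult:
    """Fit every H in ``ctrl.h_range`` and pick the BIC_H maximizer.

    BIC_H = 2 L - eta_H log N; ties break toward fewer hidden classes.
    """
    ctrl = ctrl or EMControl()
    if not ctrl.h_range:
        raise ValueError("h_range must be non-empty")
    aligned, p_count = align_test(test, learned)
    N = aligned.n_obs
    Q = aligned.n_vars - p_count
    K = learned.n_classes
    linkage_cache: dict = {}
    table: dict[int, float | None] = {}
    fits: dict[int, DiscoveryFit] = {}
    errors: dict[int, Exception] = {}
    for H in ctrl.h_range:
        try:
            init = init_mod.initialize(aligned, learned, H, linkage_cache=linkage_cache)
            fit = em_discovery(aligned, learned, H, init=init, ctrl=ctrl)
        except DamdaError as exc:
            table[H] = None
            errors[H] = exc
            continue
        eta = count_params(K, H, p_count, Q)
        table[H] = 2.0 * fit.loglik - eta * np.log(N)
        fits[H] = fit
    if not fits:
        raise DamdaError(f"all hidden-class counts failed: {errors}")
    h_star = max(fits, key=lambda h: (table[h], -h))
    return SelectionResult(fits[h_star].model, h_star, table, fits[h_star])
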