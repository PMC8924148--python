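"""Inductive stepwise variable selection for adaptive classification.

At each step the current relevant set Y^class and a proposal variable
Y^prop are compared under two models: M1, where the proposal carries class
information (a discovery-phase fit on Y^class plus the proposal, maximized
over the hidden-class range), and M2, where the proposal is explained by a
Gaussian regression on a stepwise-chosen subset of Y^class while the
classification model uses Y^class alone.  The proposal is accepted when
BIC1 - BIC2 > 0; removals apply the mirrored inequality.  The search
alternates a best-addition pass and a best-removal pass until a full cycle
changes nothing.  Learned-variable parameters are never re-estimated: a
candidate set only ever slices the learning-phase estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .discovery import EMControl, SelectionResult, select_H
from .edda import DEFAULT_FAMILIES, fit_edda
from .model_core import (
    DamdaError,
    DataMatrix,
    GaussianClass,
    LabelSet,
    LearnedClassifier,
)


@dataclass
class StepRecord:
    cycle: int
    direction: str  # "add" | "remove"
    proposal: str
    bic1: float | None
    bic2: float | None
    accepted: bool
    error: str | None = None

    @property
    def diff(self) -> float | None:
        if self.bic1 is None or self.bic2 is None:
            return None
        return self.bic1 - self.bic2


@dataclass
class SelectionState:
    relevant: list[str]
    h_star: int | None = None
    bic_class: float | None = None
    history: list[StepRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# starting subset


def _single_gaussian_bic_sk(x: np.ndarray) -> float:
    """sklearn-convention BIC (-2LL + p log N) of one univariate Gaussian."""
    n = x.size
    var = max(float(np.var(x)), 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * var) + 1.0)
    return -2.0 * ll + 2.0 * np.log(n)


def mixture_evidence_score(x: np.ndarray, G: int) -> float:
    """BIC gain of the best 2..G-component univariate mixture over 1 Gaussian.

    Positive values indicate multimodality, i.e. potential class structure.
    """
    x = np.asarray(x, float).reshape(-1, 1)
    bic1 = _single_gaussian_bic_sk(x.ravel())
    best = np.inf
    for g in range(2, G + 1):
        gm = GaussianMixture(n_components=g, random_state=0, n_init=1)
        try:
            gm.fit(x)
        except ValueError:
            continue
        best = min(best, gm.bic(x))
    return bic1 - best  # higher-is-better BIC difference


def rank_start_set(test_on_learned: DataMatrix, G: int, S: int) -> list[str]:
    """Top-S training variables ranked by univariate mixture evidence."""
    if S > test_on_learned.n_vars:
        raise ValueError("S cannot exceed the number of variables")
    scores = {
        name: mixture_evidence_score(test_on_learned.values[:, j], G)
        for j, name in enumerate(test_on_learned.var_names)
    }
    ranked = sorted(scores, key=lambda n: (-scores[n], n))
    return ranked[:S]


# ---------------------------------------------------------------------------
# sliced classifier


def subset_classifier(learned: LearnedClassifier, names) -> LearnedClassifier:
    """Restrict the learned classifier to a subset of its variables.

    Pure slicing — no re-estimation; repeated drop/re-add round-trips are
    bit-identical.
    """
    names = list(names)
    unknown = [n for n in names if n not in learned.var_names]
    if unknown:
        raise DamdaError(f"not learned variables: {unknown}")
    idx = [learned.var_names.index(n) for n in names]
    classes = [
        GaussianClass(g.mean[idx], g.cov[np.ix_(idx, idx)], g.name)
        for g in learned.classes
    ]
    return LearnedClassifier(
        classes=classes,
        props=learned.props.copy(),
        family=f"sliced({learned.family})",
        var_names=names,
        bic=None,
        loglik=None,
    )


# ---------------------------------------------------------------------------
# regression arm of the comparison


def _reg_bic_subset(
    Zty: np.ndarray, ZtZ: np.ndarray, yty: float, n: int, subset: tuple[int, ...]
) -> float:
    """Higher-is-better BIC of a Gaussian regression on the given predictors.

    Index 0 is the intercept and is always included; parameters counted are
    the coefficients plus the noise variance.
    """
    cols = (0,) + subset
    A = ZtZ[np.ix_(cols, cols)]
    b = Zty[list(cols)]
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    rss = max(float(yty - b @ beta), 1e-300)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return 2.0 * ll - (len(cols) + 1) * np.log(n)


def bic_reg(
    y_prop: np.ndarray, y_class: DataMatrix | None
) -> tuple[float, list[str]]:
    """Stepwise (bidirectional, BIC-scored) regression of the proposal.

    Returns the best model's higher-is-better BIC and the chosen predictor
    subset; the intercept-only model is always a candidate.
    """
    y = np.asarray(y_prop, float).ravel()
    n = y.size
    if y_class is None or y_class.n_vars == 0:
        return _reg_bic_subset(np.array([y.sum()]), np.array([[float(n)]]),
                               float(y @ y), n, ()), []
    X = y_class.values
    p = X.shape[1]
    Z = np.column_stack([np.ones(n), X])
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)

    current: tuple[int, ...] = ()
    current_bic = _reg_bic_subset(Zty, ZtZ, yty, n, current)
    while True:
        best_bic, best_subset = current_bic, None
        for j in range(1, p + 1):
            if j in current:
                cand = tuple(c for c in current if c != j)
            else:
                cand = tuple(sorted(current + (j,)))
            b = _reg_bic_subset(Zty, ZtZ, yty, n, cand)
            if b > best_bic + 1e-9:
                best_bic, best_subset = b, cand
        if best_subset is None:
            break
        current, current_bic = best_subset, best_bic
    names = [y_class.var_names[j - 1] for j in current]
    return current_bic, names


# ---------------------------------------------------------------------------
# D-AMDA evaluation of a candidate variable set


class _FitCache:
    """Memoized discovery fits keyed by the (unordered) variable set."""

    def __init__(self, test: DataMatrix, learned: LearnedClassifier, ctrl: EMControl):
        self.test = test
        self.learned = learned
        self.ctrl = ctrl
        self._store: dict[frozenset, SelectionResult] = {}

    def fit(self, names) -> SelectionResult:
        key = frozenset(names)
        if key in self._store:
            return self._store[key]
        p_names = [v for v in self.learned.var_names if v in key]
        q_names = [v for v in self.test.var_names if v in key and v not in p_names]
        if not p_names:
            raise DamdaError("candidate set contains no learned variables")
        sliced = subset_classifier(self.learned, p_names)
        sub = self.test.select(p_names + q_names)
        res = select_H(sub, sliced, self.ctrl)
        self._store[key] = res
        return res


# ---------------------------------------------------------------------------
# stepwise search


def _evaluate_candidate(
    cache: _FitCache,
    test: DataMatrix,
    relevant: list[str],
    proposal: str,
    direction: str,
    cycle: int,
) -> StepRecord:
    """BIC1 / BIC2 comparison for one proposal; errors become rejections."""
    try:
        if direction == "add":
            with_set = relevant + [proposal]
            without_set = relevant
        else:
            with_set = relevant
            without_set = [v for v in relevant if v != proposal]
            if not without_set:
                raise DamdaError("removal would empty the relevant set")
        bic_with = cache.fit(with_set).bic
        bic_without = cache.fit(without_set).bic
        reg_b, _ = bic_reg(
            test.select([proposal]).values[:, 0],
            test.select(without_set) if without_set else None,
        )
        # add: accept if BIC_class(with) - [BIC_class(without) + BIC_reg] > 0
        # remove: mirrored — accept removal if the no-class decomposition wins
        bic1 = bic_with
        bic2 = bic_without + reg_b
        accepted_diff = (bic1 - bic2) if direction == "add" else (bic2 - bic1)
        return StepRecord(cycle, direction, proposal, bic1, bic2, accepted_diff > 0)
    except DamdaError as exc:
        return StepRecord(cycle, direction, proposal, None, None, False, str(exc))


def step_decision(
    test: DataMatrix,
    learned: LearnedClassifier,
    state: SelectionState,
    proposal: str,
    direction: str,
    ctrl: EMControl | None = None,
    cache: _FitCache | None = None,
) -> SelectionState:
    """Evaluate one proposal and update the selection state accordingly."""
    ctrl = ctrl or EMControl()
    cache = cache or _FitCache(test, learned, ctrl)
    cycle = (state.history[-1].cycle if state.history else 0) + 1
    rec = _evaluate_candidate(cache, test, state.relevant, proposal, direction, cycle)
    state.history.append(rec)
    if rec.accepted:
        if direction == "add":
            state.relevant = state.relevant + [proposal]
        else:
            state.relevant = [v for v in state.relevant if v != proposal]
        res = cache.fit(state.relevant)
        state.h_star, state.bic_class = res.h_star, res.bic
    return state


def _best_record(records: list[StepRecord]) -> StepRecord | None:
    scored = [r for r in records if r.diff is not None]
    if not scored:
        return None
    # order-invariant argmax; ties broken by variable name
    def key(r: StepRecord):
        d = r.diff if r.direction == "add" else -r.diff
        return (d, tuple(-ord(ch) for ch in r.proposal))

    return max(scored, key=key)


def greedy_search(
    train: DataMatrix,
    labels: LabelSet,
    test: DataMatrix,
    ctrl: EMControl | None = None,
    S: int = 10,
    G: int | None = None,
    families=DEFAULT_FAMILIES,
    start_set: list[str] | None = None,
    max_cycles: int = 60,
) -> tuple[SelectionState, SelectionResult | None, LearnedClassifier]:
    """Greedy stepwise variable selection around the discovery model.

    Each cycle runs one best-addition pass over all test variables outside
    the relevant set, then one best-removal pass over the relevant set; the
    search stops when a full cycle changes nothing.  Within a pass every
    candidate is scored independently, so the outcome does not depend on
    enumeration order.  Returns the selection state (with full history), the
    final discovery fit on the selected variables, and the learned classifier.
    """
    ctrl = ctrl or EMControl()
    learned = fit_edda(train, labels, families)
    missing = [v for v in learned.var_names if v not in test.var_names]
    if missing:
        raise DamdaError(f"test data lacks learned variables: {missing}")
    G = G if G is not None else learned.n_classes + 3
    if start_set is None:
        observed = test.select(learned.var_names)
        start_set = (
            rank_start_set(observed, G, S)
            if S < len(learned.var_names)
            else list(learned.var_names)
        )
    state = SelectionState(relevant=list(start_set))
    cache = _FitCache(test, learned, ctrl)

    for cycle in range(1, max_cycles + 1):
        changed = False
        # --- addition pass: only the argmax proposal can be accepted
        pool = [v for v in test.var_names if v not in state.relevant]
        records = [
            _evaluate_candidate(cache, test, state.relevant, v, "add", cycle)
            for v in pool
        ]
        for r in records:
            r.accepted = False
        state.history.extend(records)
        best = _best_record(records)
        if best is not None and best.diff > 0:
            best.accepted = True
            state.relevant = state.relevant + [best.proposal]
            changed = True
        # --- removal pass
        if len(state.relevant) > 1:
            records = [
                _evaluate_candidate(cache, test, state.relevant, v, "remove", cycle)
                for v in list(state.relevant)
            ]
            for r in records:
                r.accepted = False
            state.history.extend(records)
            best = _best_record([r for r in records if r.direction == "remove"])
            if best is not None and -best.diff > 0:
                best.accepted = True
                state.relevant = [v for v in state.relevant if v != best.proposal]
                changed = True
        if not changed:
            break
    else:
        warnings.warn("variable-selection search hit the cycle limit", stacklevel=2)

    final: SelectionResult | None = None
    try:
        final = cache.fit(state.relevant)
        state.h_star, state.bic_class = final.h_star, final.bic
    except DamdaError as exc:
        warnings.warn(f"final fit on selected set failed: {exc}", stacklevel=2)
    return state, final, learned
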