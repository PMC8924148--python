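# Methods

## Model and estimation

`damda` implements adaptive Gaussian mixture discriminant analysis for the
setting where unlabelled test data carry `Q` extra variables and `H` extra
classes relative to the training data. Estimation is strictly inductive:
after the learning phase the training data are discarded and only the
learned parameters travel forward, which makes the method suitable for
on-line use and keeps the discovery phase free of any re-fitting of
training-variable parameters.

**Learning phase.** An EDDA classifier: per-class sample means, class
frequencies as mixing proportions, and covariances maximizing the labelled
likelihood under one of eight eigen-decomposition families
(EII, VII, EEI, VEI, EVI, VVI, EEE, VVV). All families except VEI have
closed-form constrained MLEs; VEI alternates between class volumes and the
common diagonal shape (fixed point, relative tolerance 1e-8, max 200
iterations). The family is selected by BIC `2L − η log M` with
`η = KP + (K−1) + (family covariance parameters)`; ties break toward fewer
parameters. Richer families with iterative orientation estimation (VEV,
EVE, …) are deliberately out of scope: the closed-form set covers the
behaviour the method needs, including the diagonal-only fits that arise
when `M` is small relative to `P`. A class covariance with a zero-variance
direction is repaired with a `1e-8 ×` mean-diagonal ridge plus a warning.

**Discovery phase.** EM on the test data, with the test columns reordered
so the learned variables come first (in learned order) and extras after —
this makes the block partition of every known-class parameter positional
and auditable. The E step computes responsibilities `t_ic ∝ τ_c N(y_i;
μ*_c, Σ*_c)` in log space with log-sum-exp normalization. The M step:

- mixing proportions `τ_c = N_c/N`, re-estimated for known and hidden
  classes on the test data (the re-normalization alternative, which assumes
  the known-class balance is unchanged, is not the default and is not
  recommended — it is biased when class proportions shift);
- hidden classes: weighted mean and weighted MLE covariance;
- known classes: *inductive conditional estimation*. With `W, V, U` the
  blocks of the weighted scatter `O_k` about the weighted class mean, the
  conditional parameters of extras given training variables are
  `Ĉ_k = Σ̄_k W⁻¹ V` and `Ê_k = (U − V'W⁻¹V)/N_k`, and the marginal extras
  follow as `μ̂_Q = ȳ_Q − (Σ̄⁻¹Ĉ)'(ȳ_P − μ̄)` and
  `Σ̂_Q = Ê + Ĉ'Σ̄⁻¹Ĉ`. These are algebraically identical to the textbook
  forms `Ĉ = (Σ̄⁻¹WΣ̄⁻¹)⁻¹(Σ̄⁻¹V)` etc., but avoid forming `Σ̄⁻¹WΣ̄⁻¹`
  explicitly; the test suite verifies both routes against each other and
  against a direct numerical maximizer of the expected complete-data
  conditional term. Note that `Ê_k` is the Schur complement of the scatter
  and does not depend on `Σ̄_k` at all. Positive definiteness of the
  assembled `Σ*_k` is equivalent to `Ê_k ≻ 0` and is checked every
  iteration.

Convergence uses the relative change criterion
`|L(t) − L(t−1)| / (1 + |L(t)|) < ε` with `ε = 1e-5` (default) and
`max_iter = 500`. `H` is selected by maximizing
`BIC_H = 2L − η_H log N`, where
`η_H = (H + K − 1) + 2HR + H·C(R,2) + 2KQ + KPQ + K·C(Q,2)` counts only
discovery-phase free parameters (learned parameters are constants under the
inductive contract). Ties break toward smaller `H`.

**Initialization.** Ward agglomeration on standardized test columns (a
deterministic, dependency-light stand-in for likelihood-based hierarchical
model-based clustering; the initializer is exchangeable in practice), cut at
`C = K + H` clusters. Each known class is matched to one cluster by the
divergence `tr(Σ̃_g⁻¹Σ̄_k) + (μ̃_g−μ̄_k)'Σ̃_g⁻¹(μ̃_g−μ̄_k) +
log(det Σ̃_g/det Σ̄_k)` (a monotone transform of the Gaussian KL
divergence, used only for ranking). Matching is solved as an exact
assignment problem over injections — "pick the K clusters with minimal
divergence" is ambiguous when one cluster wins for two classes, and exact
assignment is order-independent. Matched clusters inherit the fixed learned
parameters on the training block and their own moments on the extras;
unmatched clusters seed the hidden classes. Clusters with fewer than
`R + 2` members have covariances shrunk toward the pooled covariance with
weight proportional to the deficiency; all initial covariances get an
eigenvalue floor of `1e-8 × trace/R`; cross blocks are halved until the
Schur complement is positive definite. If a class empties mid-run
(`N_c < 1e-8`), the fit restarts from a random non-empty partition (fresh
sub-seed) up to 5 times.

**Regularization.** When class scatters can be singular (`N_k < R`, or
strongly correlated variables), an inverse-Wishart-style prior scatter is
added: `O_k ← O_k + ν Ψ` with the divisor inflated to `N_k + ν`. Defaults:
`Ψ = diag` of pooled test variances, `ν = R + 2` (the weakest proper
choice). Modes: `off` (raise a clear error pointing at the flag when the
relative condition of `W_k` exceeds 1e12), `on` (always), `auto` (only for
classes whose effective size falls below `R`, the point at which the
scatter is necessarily singular). The prior affects covariances only; class
means remain the raw weighted means. Under `auto`, regularization switching
on mid-run changes the M-step objective for that class, so the raw
log-likelihood trace is no longer guaranteed monotone in that iteration;
with the `N_k < R` threshold this occurs only for classes that are already
degenerate.

**Variable selection.** Greedy stepwise search over test variables. Each
cycle runs one best-addition pass (candidates: every test variable outside
the current relevant set — extras are eligible from the first step) and one
best-removal pass; the search stops when a full cycle changes nothing.
A proposal is scored by `BIC_class(Y^class ∪ prop)` against
`BIC_noclass(Y^class) + BIC_reg(prop | Y^reg ⊆ Y^class)`, both
classification BICs maximized over the `H` range; the regression arm is a
bidirectional BIC-stepwise Gaussian linear regression (intercept always
included, intercept-only always a candidate). Additions are accepted when
`BIC1 − BIC2 > 0`; removals apply the mirrored inequality (remove when the
no-classification decomposition of the reduced set wins). Within a pass all
candidates are scored independently and the argmax is taken, so the outcome
is invariant to enumeration order; exact ties break lexicographically.
Discovery fits are cached per unordered variable set. The starting subset
is either all observed variables or the top `S` by univariate mixture
evidence (best BIC gain of a 2..G-component univariate Gaussian mixture
over a single Gaussian, `G = K + 3` by default).

## Synthetic-data generator

The generator emulates the standard three-tier design: `Gen` variables from
a `C = 4`-component Gaussian mixture (2 classes observed in training by
default), `Cor` variables each a noisy linear combination of 2 randomly
chosen `Gen` variables, `Noi` variables independent `N(0, 1)`. Defaults
follow the 100-variable design (10 Gen / 30 Cor / 60 Noi, 20 observed
training variables, `M = N = 400`).

Choices the design left open, fixed once here:

- **Class means** sit at the vertices of a randomly rotated regular
  simplex. `separation` (default 3) is the per-coordinate scale of the
  classic layout `μ_c = separation · e_c`, so pairwise mean distances are
  `√2 · separation` within-class SDs; the scale is applied in Mahalanobis
  units (minimum pairwise Mahalanobis distance `= √2 · separation` w.r.t.
  the average covariance of each pair), so anisotropic covariances cannot
  silently shrink the effective separation. At the default, classes are
  well separated but not trivially so (Bayes error well under 1%).
- **Class covariances**: random SPD with unit geometric-mean eigenvalue and
  condition number ≤ 10.
- **Cor links**: weight magnitudes uniform on [0.7, 1.3] with random signs.
  Wider ranges make the weaker link's marginal correlation with its Gen
  parent arbitrarily small, defeating the purpose of a "correlated"
  variable; with this range every linked correlation stays above ≈ 0.4 in
  the absence of class structure. The noise variance is 0.35 × the signal
  variance, putting typical linked correlations near 0.6.
- Class labels are uniform over the admissible classes in both samples.

What the generator does **not** emulate: spectral smoothness/continuity of
real spectroscopy data, non-Gaussian class shapes, label noise, outliers,
and heteroscedastic measurement error. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to their violation. Marginal correlations between a Cor
variable and *unlinked* Gen variables are near zero only without class
structure; under a multi-class design all Gen-derived columns share the
class-mean signal, which is expected and intentional (Cor variables are
informative about classes exactly through Gen).

## Numerical choices

- Densities in log space throughout; Cholesky factorizations batched across
  classes; posterior normalization by log-sum-exp.
- PD validity: smallest eigenvalue > 1e-10 × largest (scale-free).
- `W_k` solved via symmetric factorization; relative condition threshold
  1e12 before demanding regularization.
- EM: `ε = 1e-5`, `max_iter = 500`, default `h_range = {0,…,5}`; final
  responsibilities always recomputed under the returned parameters.
- Model files: versioned JSON documents; round trips are lossless.

## Problem sizes used in the checks

The statistical suites run at sizes chosen to give stable pass/fail
behaviour at reasonable cost: 200 randomized instances for the EM
contracts; 50 instances for the conditional-estimation optimality check
(P, Q ≤ 2, N ≤ 25, where a derivative-free maximizer is reliable); 50 seeds
for the hidden-class recovery and null studies (N = 600/500); 20 seeds of
the 40-variable Gen/Cor/Noi design for variable selection (N = 400);
`scripts/acceptance.py` re-runs the same studies at 12/12/3 seeds.

## Known limitations

- Hidden-class and cross-block covariances are unconstrained; parsimonious
  families in the discovery phase are not implemented.
- The regularization prior is a documented default, not a calibrated
  choice; heavy regularization biases `Ĉ_k` toward zero.
- The stepwise search is greedy: it can keep a Cor variable when the Gen
  variables it proxies were never observed in training (this mirrors the
  intended behaviour of the design — such variables genuinely carry the
  best available class information).
- Variable matching across train/test is by column name only.
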