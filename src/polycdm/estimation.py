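"""Marginal maximum likelihood (EM) estimation, classification, and fit statistics.

The marginal likelihood of a response vector x_i is
``sum_c pi_c * prod_j P_jc^{x_ij} (1 - P_jc)^{1 - x_ij}`` over all latent
classes c, where P_jc is the class's group probability on item j.  The
E-step computes class posteriors and the expected per-group counts
``N_jl`` (examinees) and ``R_jl`` (correct responses); the M-step maximizes
the weighted Bernoulli complete-data likelihood per item — closed form
``R/N`` for the saturated model, a constrained optimizer for reduced
models — and updates the structural class proportions pi.

A generalized-EM guard accepts an item update only if it does not decrease
the item's weighted complete-data likelihood, so the marginal log-likelihood
is non-decreasing across iterations even when a constrained inner solver
terminates early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression, minimize
from scipy.special import logsumexp

from .attribute_space import AttributeSpec, QMatrix
from .model_irf import (
    ItemModel,
    build_item_model,
    delta_from_group_probs,
    monotonicity_violations,
)

__all__ = [
    "ModelConfig",
    "FitOptions",
    "ExpectedCounts",
    "FitResult",
    "marginal_loglik",
    "e_step",
    "m_step_saturated",
    "m_step_reduced",
    "update_structural",
    "fit_em",
    "standard_errors",
    "classify",
    "eap_marginals",
    "fit_statistics",
]

_FLOOR = 1e-10  # probability floor inside likelihoods only
_EMPTY_GROUP = 1e-3  # expected-count threshold below which a group keeps its value


@dataclass(frozen=True)
class ModelConfig:
    """Per-item (or global) measurement-model choice."""

    kind: str = "saturated"
    link: str = "identity"
    equal_steps: bool = False


@dataclass(frozen=True)
class FitOptions:
    """EM controls.

    ``tol`` bounds the max absolute change in any group success probability
    and ``loglik_tol`` the relative log-likelihood change; both must hold to
    declare convergence.  ``monotone`` imposes monotonicity (in the
    componentwise group order) during estimation.  ``fix_pi_uniform`` pins
    the structural class proportions at uniform instead of estimating them.
    """

    tol: float = 1e-4
    loglik_tol: float = 1e-7
    max_iter: int = 2000
    monotone: bool = True
    fix_pi_uniform: bool = False
    seed: int = 0
    se_method: str = "xpd"  # "xpd" (empirical cross-product) or "none"


@dataclass
class ExpectedCounts:
    """E-step sufficient statistics for one item: expected group sizes and
    expected correct counts."""

    N: np.ndarray
    R: np.ndarray


@dataclass
class FitResult:
    spec: AttributeSpec
    qmatrix: QMatrix
    item_models: list[ItemModel]
    group_probs: list[np.ndarray]
    pi: np.ndarray
    posterior: np.ndarray
    loglik: float
    trace: list[float]
    converged: bool
    n_iter: int
    options: FitOptions
    se: list[np.ndarray] | None = None
    se_available: list[np.ndarray] | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_examinees(self) -> int:
        return self.posterior.shape[0]


# ---------------------------------------------------------------------------
# likelihood / E-step


def _class_prob_matrix(item_models: list[ItemModel], group_probs: list[np.ndarray]) -> np.ndarray:
    C = len(item_models[0].partition.class_to_group)
    P = np.empty((C, len(item_models)))
    for j, (model, p) in enumerate(zip(item_models, group_probs)):
        P[:, j] = p[model.partition.class_to_group]
    return P


def _log_class_likelihood(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """N x C matrix of log P(x_i | class c); P is the C x J class-prob matrix."""
    Pc = np.clip(P, _FLOOR, 1 - _FLOOR)
    return X @ np.log(Pc).T + (1 - X) @ np.log(1 - Pc).T


def marginal_loglik(
    responses: np.ndarray,
    item_models: list[ItemModel],
    pi: np.ndarray,
) -> float:
    """Marginal log-likelihood, computed via log-sum-exp over classes."""
    X = np.asarray(responses, dtype=float)
    probs = [m.group_probabilities() for m in item_models]
    P = _class_prob_matrix(item_models, probs)
    ll = _log_class_likelihood(X, P) + np.log(np.clip(pi, _FLOOR, None))
    return float(logsumexp(ll, axis=1).sum())


def e_step(
    responses: np.ndarray,
    item_models: list[ItemModel],
    pi: np.ndarray,
) -> tuple[np.ndarray, list[ExpectedCounts], float]:
    """Posterior class probabilities and expected group counts per item."""
    X = np.asarray(responses, dtype=float)
    probs = [m.group_probabilities() for m in item_models]
    P = _class_prob_matrix(item_models, probs)
    post, ll = _posterior(X, P, pi)
    counts = _expected_counts(X, post, item_models)
    return post, counts, ll


def _posterior(X: np.ndarray, P: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, float]:
    logjoint = _log_class_likelihood(X, P) + np.log(np.clip(pi, _FLOOR, None))
    norm = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - norm[:, None])
    return post, float(norm.sum())


def _expected_counts(
    X: np.ndarray, post: np.ndarray, item_models: list[ItemModel]
) -> list[ExpectedCounts]:
    Nc = post.sum(axis=0)  # expected examinees per class
    T = X.T @ post  # J x C expected correct per class
    counts = []
    for j, model in enumerate(item_models):
        ctg = model.partition.class_to_group
        G = model.partition.n_groups
        counts.append(
            ExpectedCounts(
                N=np.bincount(ctg, weights=Nc, minlength=G),
                R=np.bincount(ctg, weights=T[j], minlength=G),
            )
        )
    return counts


# ---------------------------------------------------------------------------
# M-steps


def _weighted_bernoulli_ll(p: np.ndarray, N: np.ndarray, R: np.ndarray) -> float:
    pc = np.clip(p, _FLOOR, 1 - _FLOOR)
    return float(R @ np.log(pc) + (N - R) @ np.log(1 - pc))


def _isotonic_lattice(p: np.ndarray, w: np.ndarray, shape: tuple[int, ...],
                      max_cycles: int = 25) -> np.ndarray:
    """Cyclic per-attribute weighted PAVA sweeps on the group lattice.

    Groups are indexed in mixed radix (last attribute fastest), so reshaping
    to ``shape`` exposes each attribute as one tensor axis; 1-D isotonic
    regression along an axis enforces that attribute's orderings.
    """
    t = p.reshape(shape).astype(float)
    wt = np.maximum(w.reshape(shape), 1e-12)
    for _ in range(max_cycles):
        changed = False
        for axis in range(len(shape)):
            moved = np.ascontiguousarray(np.moveaxis(t, axis, -1))
            wmoved = np.ascontiguousarray(np.moveaxis(wt, axis, -1))
            flat = moved.reshape(-1, shape[axis])
            wflat = wmoved.reshape(-1, shape[axis])
            for row in range(flat.shape[0]):
                if np.any(np.diff(flat[row]) < 0):
                    flat[row] = isotonic_regression(
                        flat[row], weights=wflat[row], increasing=True
                    ).x
                    changed = True
            if changed:
                t = np.moveaxis(flat.reshape(moved.shape), -1, axis)
        if not changed:
            break
    return t.reshape(-1)


def m_step_saturated(
    counts: ExpectedCounts,
    previous: np.ndarray,
    partition=None,
    monotone: bool = False,
) -> np.ndarray:
    """Closed-form saturated update ``R/N``; optional monotone projection.

    Groups with expected size below a small threshold keep their previous
    value.  With ``monotone``, violating items are replaced by the weighted
    isotonic fit on the group lattice (the exact constrained MLE on chains;
    cyclic sweeps on the full lattice), which the caller should accept only
    if the complete-data likelihood does not decrease.
    """
    N, R = counts.N, counts.R
    p = previous.astype(float).copy()
    ok = N > _EMPTY_GROUP
    p[ok] = R[ok] / N[ok]
    if monotone and partition is not None and monotonicity_violations(p, partition):
        shape = tuple(
            len(np.unique(partition.groups[:, a]))
            for a in range(partition.groups.shape[1])
        )
        p = _isotonic_lattice(p, N, shape)
    return np.clip(p, 0.0, 1.0)


def _link_probs(design: np.ndarray, delta: np.ndarray, link: str) -> np.ndarray:
    eta = design @ delta
    if link == "identity":
        return eta
    if link == "logit":
        from scipy.special import expit

        return expit(eta)
    return np.exp(eta)


def m_step_reduced(
    counts: ExpectedCounts,
    item_model: ItemModel,
    delta0: np.ndarray,
    monotone: bool = False,
    maxiter: int = 100,
) -> np.ndarray:
    """Maximize the weighted Bernoulli likelihood in delta for a reduced model.

    All constraints are linear in delta: probability bounds for the identity
    link, an upper bound on the linear predictor for the log link, and the
    monotone adjacent-pair differences (the logit and log inverse links are
    increasing, so monotonicity on the linear predictor is equivalent).
    """
    N, R = counts.N, counts.R
    D, link = item_model.design, item_model.link
    eps = 1e-6

    def negll(delta):
        p = np.clip(_link_probs(D, delta, link), _FLOOR, 1 - _FLOOR)
        return -(R @ np.log(p) + (N - R) @ np.log(1 - p))

    def grad(delta):
        p = np.clip(_link_probs(D, delta, link), _FLOOR, 1 - _FLOOR)
        if link == "identity":
            dp = np.ones_like(p)
        elif link == "logit":
            dp = p * (1 - p)
        else:
            dp = p
        return -D.T @ ((R / p - (N - R) / (1 - p)) * dp)

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    if link == "identity":
        rows += [D, -D]
        rhs += [np.full(D.shape[0], eps), np.full(D.shape[0], -(1 - eps))]
    elif link == "log":
        rows.append(-D)
        rhs.append(np.full(D.shape[0], -np.log(1 - eps)))
    if monotone:
        pairs = item_model.partition.adjacent_pairs()
        if pairs:
            A = np.array([D[hi] - D[lo] for lo, hi in pairs])
            rows.append(A)
            rhs.append(np.zeros(len(pairs)))

    if rows:
        Acon = np.vstack(rows)
        bcon = np.concatenate(rhs)
        constraints = [
            {
                "type": "ineq",
                "fun": lambda d, A=Acon, b=bcon: A @ d - b,
                "jac": lambda d, A=Acon: A,
            }
        ]
        res = minimize(
            negll,
            delta0,
            jac=grad,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
    else:
        res = minimize(
            negll, delta0, jac=grad, method="L-BFGS-B", options={"maxiter": maxiter}
        )
    if not np.all(np.isfinite(res.x)):
        return delta0
    return res.x


def update_structural(posteriors: np.ndarray) -> np.ndarray:
    """Saturated multinomial update: mean posterior mass per class."""
    pi = posteriors.mean(axis=0)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# full EM


def _initial_probs(model: ItemModel, rng: np.random.Generator) -> np.ndarray:
    """Linear spacing 0.2..0.8 along the monotone group order, plus noise.

    The spread breaks the symmetry of a flat start (which is a stationary
    point of EM) while keeping the start monotone-compatible.
    """
    part = model.partition
    order = np.lexsort((np.arange(part.n_groups), part.groups.sum(axis=1)))
    base = np.empty(part.n_groups)
    base[order] = np.linspace(0.2, 0.8, part.n_groups)
    base = base + rng.uniform(-0.05, 0.05, size=part.n_groups)
    return np.clip(base, 0.05, 0.95)


def fit_em(
    responses: np.ndarray,
    qmatrix: QMatrix,
    model_config: ModelConfig | list[ModelConfig] = ModelConfig(),
    options: FitOptions = FitOptions(),
    init_probs: list[np.ndarray] | None = None,
    init_pi: np.ndarray | None = None,
) -> FitResult:
    """Fit any per-item model configuration by MMLE/EM.

    ``model_config`` may be a single configuration applied to every item or
    a list with one entry per item.  The fit is deterministic given
    ``options.seed``.  ``init_probs``/``init_pi`` warm-start the group
    probabilities and structural proportions (e.g. from a previous fit).
    """
    X = np.asarray(responses)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("responses must be binary (0/1)")
    X = X.astype(float)
    spec = qmatrix.spec
    J = qmatrix.n_items
    if X.shape[1] != J:
        raise ValueError(f"responses have {X.shape[1]} columns, Q-matrix has {J} items")
    configs = list(model_config) if isinstance(model_config, (list, tuple)) else [model_config] * J
    if len(configs) != J:
        raise ValueError("model_config list length must equal the item count")

    rng = np.random.default_rng(options.seed)
    models: list[ItemModel] = []
    group_probs: list[np.ndarray] = []
    deltas: list[np.ndarray] = []
    for j, cfg in enumerate(configs):
        model = build_item_model(cfg.kind, cfg.link, qmatrix.entries[j], spec,
                                 equal_steps=cfg.equal_steps)
        if init_probs is not None:
            p0 = np.asarray(init_probs[j], dtype=float)
            if not (model.kind == "saturated" and model.link == "identity"):
                p0 = np.clip(p0, 0.01, 0.99)
        else:
            p0 = _initial_probs(model, rng)
        d0 = delta_from_group_probs(model, p0)
        models.append(model)
        deltas.append(d0)
        if model.kind == "saturated" and model.link == "identity":
            group_probs.append(np.clip(p0, 0.0, 1.0))
        else:
            group_probs.append(
                np.clip(_link_probs(model.design, d0, model.link), 0.01, 0.99)
            )

    C = spec.n_classes
    pi = (
        np.asarray(init_pi, dtype=float) / np.sum(init_pi)
        if init_pi is not None
        else np.full(C, 1.0 / C)
    )
    trace: list[float] = []
    converged = False
    warn_msgs: list[str] = []
    post = np.full((X.shape[0], C), 1.0 / C)

    for it in range(options.max_iter):
        P = _class_prob_matrix(models, group_probs)
        post, ll = _posterior(X, P, pi)
        if not np.isfinite(ll):
            raise FloatingPointError("marginal log-likelihood became non-finite")
        trace.append(ll)

        counts = _expected_counts(X, post, models)
        max_change = 0.0
        for j, model in enumerate(models):
            old_p = group_probs[j]
            old_ll = _weighted_bernoulli_ll(old_p, counts[j].N, counts[j].R)
            if model.kind == "saturated" and model.link == "identity":
                new_p = m_step_saturated(
                    counts[j], old_p, model.partition, monotone=options.monotone
                )
                new_d = None
            else:
                new_d = m_step_reduced(
                    counts[j], model, deltas[j], monotone=options.monotone
                )
                new_p = np.clip(_link_probs(model.design, new_d, model.link), 0.0, 1.0)
            # generalized-EM guard: never let an item update lower its
            # complete-data likelihood
            if _weighted_bernoulli_ll(new_p, counts[j].N, counts[j].R) >= old_ll - 1e-9:
                if new_d is not None:
                    deltas[j] = new_d
                max_change = max(max_change, float(np.max(np.abs(new_p - old_p))))
                group_probs[j] = new_p

        if not options.fix_pi_uniform:
            pi = update_structural(post)

        if it > 0:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if max_change < options.tol and rel < options.loglik_tol:
                converged = True
                break

    if not converged:
        warn_msgs.append(f"EM did not converge in {options.max_iter} iterations")
        warnings.warn(warn_msgs[-1], RuntimeWarning, stacklevel=2)

    # final E-step so posterior/loglik correspond to the returned parameters
    P = _class_prob_matrix(models, group_probs)
    post, ll = _posterior(X, P, pi)
    for j, model in enumerate(models):
        if model.kind == "saturated":
            deltas[j] = delta_from_group_probs(model, np.clip(group_probs[j], _FLOOR, 1 - _FLOOR))
        models[j] = model.with_delta(deltas[j])

    fit = FitResult(
        spec=spec,
        qmatrix=qmatrix,
        item_models=models,
        group_probs=[p.copy() for p in group_probs],
        pi=pi,
        posterior=post,
        loglik=ll,
        trace=trace + [ll],
        converged=converged,
        n_iter=len(trace),
        options=options,
        warnings_=warn_msgs,
    )
    if options.se_method == "xpd":
        fit.se, fit.se_available = standard_errors(fit, X)
    return fit


# ---------------------------------------------------------------------------
# standard errors / classification / fit statistics


def standard_errors(
    fit: FitResult, responses: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Item-block empirical cross-product (outer-product-of-scores) SEs.

    Per item, the incomplete-data score of each examinee is the posterior
    expectation of the complete-data score; the inverse of the summed outer
    products estimates the covariance of delta.  Parameters in singular
    information blocks (e.g. a saturated parameter behind an empty group)
    are flagged unavailable, never fabricated.
    """
    X = np.asarray(responses, dtype=float)
    ses: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    for j, model in enumerate(fit.item_models):
        part = model.partition
        G, Pn = part.n_groups, model.n_parameters
        p = np.clip(fit.group_probs[j], _FLOOR, 1 - _FLOOR)
        onehot = (part.class_to_group[:, None] == np.arange(G)).astype(float)
        U = fit.posterior @ onehot  # N x G posterior group mass
        a = (X[:, [j]] - p[None, :]) / (p * (1 - p))[None, :]
        if model.link == "identity":
            dp = np.ones(G)
        elif model.link == "logit":
            dp = p * (1 - p)
        else:
            dp = p
        A = model.design * dp[:, None]  # G x P: dp/ddelta
        S = (U * a) @ A  # N x P score matrix
        info = S.T @ S
        se = np.full(Pn, np.nan)
        avail = np.zeros(Pn, dtype=bool)
        keep = np.diag(info) > 1e-8
        if keep.any():
            sub = info[np.ix_(keep, keep)]
            if np.linalg.matrix_rank(sub) == sub.shape[0]:
                cov_diag = np.diag(np.linalg.inv(sub))
                if (cov_diag > 0).all():
                    se[keep] = np.sqrt(cov_diag)
                    avail[keep] = True
        ses.append(se)
        flags.append(avail)
    return ses, flags


def classify(fit: FitResult, method: str = "MAP") -> np.ndarray:
    """Per-examinee attribute pattern (N x K).

    MAP takes the argmax posterior class (ties go to the lowest pattern
    index); EAP takes, per attribute, the argmax of the marginal posterior
    over its levels.
    """
    from .attribute_space import enumerate_patterns

    patterns = enumerate_patterns(fit.spec)
    method = method.upper()
    if method == "MAP":
        return patterns[np.argmax(fit.posterior, axis=1)]
    if method == "EAP":
        out = np.empty((fit.posterior.shape[0], fit.spec.n_attributes), dtype=int)
        for k, marg in enumerate(eap_marginals(fit)):
            out[:, k] = np.argmax(marg, axis=1)
        return out
    raise ValueError(f"unknown classification method: {method!r}")


def eap_marginals(fit: FitResult) -> list[np.ndarray]:
    """Per-attribute marginal posterior level distributions (N x M_k each)."""
    from .attribute_space import enumerate_patterns

    patterns = enumerate_patterns(fit.spec)
    out = []
    for k in range(fit.spec.n_attributes):
        M = fit.spec.levels[k]
        onehot = (patterns[:, k][:, None] == np.arange(M)).astype(float)
        out.append(fit.posterior @ onehot)
    return out


@dataclass(frozen=True)
class FitStatistics:
    deviance: float
    aic: float
    bic: float
    n_parameters: int
    n_item_parameters: int
    n_structural_parameters: int


def fit_statistics(fit: FitResult) -> FitStatistics:
    """Deviance, AIC, and BIC.

    The parameter count includes the item parameters and the C - 1 free
    structural class proportions of the saturated multinomial.
    """
    n_item = sum(m.n_parameters for m in fit.item_models)
    n_struct = fit.spec.n_classes - 1
    p = n_item + n_struct
    dev = -2.0 * fit.loglik
    N = fit.n_examinees
    return FitStatistics(
        deviance=dev,
        aic=dev + 2 * p,
        bic=dev + p * np.log(N),
        n_parameters=p,
        n_item_parameters=n_item,
        n_structural_parameters=n_struct,
    )
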