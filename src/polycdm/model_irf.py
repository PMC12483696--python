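"""Design matrices and item response functions.

Every model kind is expressed as a linear predictor on an item's latent
groups: ``eta = D @ delta`` with ``D`` the G x P design matrix, followed by
the inverse link (identity, logit, or log) to yield one success probability
per group.  Main effects use cumulative step coding ``I(alpha_k >= m)``, so
the step parameter for level ``m`` of attribute ``k`` is the increment in
the linear predictor for reaching level ``m`` from ``m - 1``; single-
attribute blocks are then lower-triangular matrices of ones, and the
saturated design — one column per (attribute subset, step-level combination)
— is their Kronecker product, hence square and invertible.

Model kinds
-----------
saturated
    One free parameter per latent group (intercept, all main-effect steps,
    all interaction steps).
pgdina
    Each required attribute is collapsed to the dichotomy at-or-above vs.
    below its required level (the specific-attribute-level-mastery
    assumption); the dichotomous G-DINA design is applied to the collapsed
    indicators.
fam / additive_logit / additive_log
    Fully additive: intercept plus every main-effect step, on the identity,
    logit, or log scale respectively.
min_fam / max_fam
    Additive with the required level acting as a minimum bar (only steps at
    or above it) or a maximum requirement (only steps at or below it).
conjunctive / disjunctive
    Two parameters: intercept plus an indicator that all (resp. at least
    one) required attributes are at or above their required levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit as logit_fn

from .attribute_space import (
    AttributeSpec,
    LatentGroupPartition,
    canonical_kind,
    partition_groups,
)

__all__ = [
    "LINKS",
    "ColumnInfo",
    "ItemModel",
    "InvalidParameterError",
    "build_design_matrix",
    "build_item_model",
    "group_probabilities",
    "class_success_matrix",
    "monotonicity_violations",
    "delta_from_group_probs",
]

LINKS = ("identity", "logit", "log")

#: Absolute slack for probability-bound and monotonicity checks.
PROB_TOL = 1e-8


class InvalidParameterError(ValueError):
    """Raised when item parameters imply probabilities outside [0, 1]."""


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one design column.

    ``attrs`` holds original attribute indices (empty tuple = intercept) and
    ``levels`` the step level per attribute in ``attrs``.  ``order`` is the
    interaction order (0 intercept, 1 main effect, ...).
    """

    attrs: tuple[int, ...]
    levels: tuple[int, ...]

    @property
    def order(self) -> int:
        return len(self.attrs)


def _subsets(indices: list[int]) -> list[tuple[int, ...]]:
    """Nonempty subsets ordered by increasing size then lexicographically."""
    out: list[tuple[int, ...]] = []
    for size in range(1, len(indices) + 1):
        from itertools import combinations

        out.extend(combinations(indices, size))
    return out


def _level_combos(level_choices: list[list[int]]) -> list[tuple[int, ...]]:
    """Cartesian product of per-attribute step levels, last varying fastest."""
    from itertools import product

    return list(product(*level_choices))


def build_design_matrix(
    model_kind: str,
    q_row: np.ndarray,
    spec: AttributeSpec,
    equal_steps: bool = False,
) -> tuple[np.ndarray, list[ColumnInfo], LatentGroupPartition]:
    """Construct the G x P design matrix for one item.

    Columns are ordered intercept, then main effects (attribute-major,
    level-minor), then interactions by increasing order and lexicographic
    attribute subset.  ``equal_steps`` merges the step columns of each
    attribute into a single linear-in-level column (supported for the
    additive kinds only).

    Returns the design, per-column metadata, and the item's latent-group
    partition (rows of the design are indexed by its groups).
    """
    kind = canonical_kind(model_kind)
    q_row = np.asarray(q_row, dtype=int)
    part = partition_groups(q_row, spec)
    required = list(part.required)
    groups = part.groups  # G x K*
    G = part.n_groups
    m_req = [spec.levels[k] for k in required]
    q_req = [int(q_row[k]) for k in required]

    def step_col(pos: int, m: int) -> np.ndarray:
        return (groups[:, pos] >= m).astype(float)

    def collapsed(pos: int) -> np.ndarray:
        return (groups[:, pos] >= q_req[pos]).astype(float)

    cols: list[np.ndarray] = [np.ones(G)]
    infos: list[ColumnInfo] = [ColumnInfo(attrs=(), levels=())]

    if kind == "saturated":
        for subset in _subsets(list(range(len(required)))):
            for levels in _level_combos([list(range(1, m_req[a])) for a in subset]):
                col = np.ones(G)
                for a, m in zip(subset, levels):
                    col = col * step_col(a, m)
                cols.append(col)
                infos.append(
                    ColumnInfo(
                        attrs=tuple(required[a] for a in subset), levels=levels
                    )
                )
    elif kind == "pgdina":
        for subset in _subsets(list(range(len(required)))):
            col = np.ones(G)
            for a in subset:
                col = col * collapsed(a)
            cols.append(col)
            infos.append(
                ColumnInfo(
                    attrs=tuple(required[a] for a in subset),
                    levels=tuple(q_req[a] for a in subset),
                )
            )
    elif kind in ("fam", "additive_logit", "additive_log", "min_fam", "max_fam"):
        for a, k in enumerate(required):
            if kind == "min_fam":
                level_range = range(q_req[a], m_req[a])
            elif kind == "max_fam":
                level_range = range(1, q_req[a] + 1)
            else:
                level_range = range(1, m_req[a])
            for m in level_range:
                cols.append(step_col(a, m))
                infos.append(ColumnInfo(attrs=(k,), levels=(m,)))
    elif kind == "conjunctive":
        col = np.ones(G)
        for a in range(len(required)):
            col = col * collapsed(a)
        cols.append(col)
        infos.append(ColumnInfo(attrs=tuple(required), levels=tuple(q_req)))
    elif kind == "disjunctive":
        col = np.zeros(G)
        for a in range(len(required)):
            col = np.maximum(col, collapsed(a))
        cols.append(col)
        infos.append(ColumnInfo(attrs=tuple(required), levels=tuple(q_req)))

    if equal_steps:
        if kind not in ("fam", "additive_logit", "additive_log", "min_fam", "max_fam"):
            raise ValueError("equal_steps is supported for additive kinds only")
        merged_cols: list[np.ndarray] = [cols[0]]
        merged_infos: list[ColumnInfo] = [infos[0]]
        for k in sorted({info.attrs[0] for info in infos[1:]}):
            idx = [i for i, info in enumerate(infos) if info.attrs == (k,)]
            merged_cols.append(np.sum([cols[i] for i in idx], axis=0))
            merged_infos.append(
                ColumnInfo(attrs=(k,), levels=tuple(infos[i].levels[0] for i in idx))
            )
        cols, infos = merged_cols, merged_infos

    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RuntimeError(
            f"rank-deficient design for kind={kind}, q_row={q_row.tolist()}"
        )
    return design, infos, part


@dataclass
class ItemModel:
    """One item's model: design matrix, link, and parameter vector delta."""

    kind: str
    link: str
    q_row: tuple[int, ...]
    design: np.ndarray
    columns: list[ColumnInfo]
    partition: LatentGroupPartition
    delta: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return self.design.shape[1]

    def with_delta(self, delta: np.ndarray) -> "ItemModel":
        return replace(self, delta=np.asarray(delta, dtype=float))

    def group_probabilities(self) -> np.ndarray:
        return group_probabilities(self)


def build_item_model(
    model_kind: str,
    link: str,
    q_row: np.ndarray,
    spec: AttributeSpec,
    delta: np.ndarray | None = None,
    equal_steps: bool = False,
) -> ItemModel:
    if link not in LINKS:
        raise ValueError(f"unknown link: {link!r}")
    design, infos, part = build_design_matrix(model_kind, q_row, spec, equal_steps)
    model = ItemModel(
        kind=canonical_kind(model_kind),
        link=link,
        q_row=tuple(np.asarray(q_row, dtype=int).tolist()),
        design=design,
        columns=infos,
        partition=part,
    )
    if delta is not None:
        delta = np.asarray(delta, dtype=float)
        if delta.shape != (design.shape[1],):
            raise ValueError(
                f"delta has shape {delta.shape}, expected ({design.shape[1]},)"
            )
        model = model.with_delta(delta)
    return model


def group_probabilities(item_model: ItemModel, tol: float = PROB_TOL) -> np.ndarray:
    """Success probability of every latent group implied by delta.

    Identity and log links can produce values outside [0, 1]; such
    parameters are rejected (beyond ``tol``), never silently clipped.
    """
    if item_model.delta is None:
        raise ValueError("item model has no parameter vector")
    eta = item_model.design @ item_model.delta
    if item_model.link == "identity":
        p = eta
    elif item_model.link == "logit":
        p = expit(eta)
    else:
        p = np.exp(eta)
    if (p < -tol).any() or (p > 1 + tol).any():
        raise InvalidParameterError(
            f"group probabilities outside [0,1]: min={p.min():.3g}, max={p.max():.3g}"
        )
    return np.clip(p, 0.0, 1.0)


def class_success_matrix(
    item_models: list[ItemModel], spec: AttributeSpec
) -> np.ndarray:
    """Expand per-group probabilities to the full class space.

    Returns a C x J matrix in which every latent class inherits exactly the
    probability of its group on each item.
    """
    C = spec.n_classes
    P = np.empty((C, len(item_models)))
    for j, model in enumerate(item_models):
        probs = group_probabilities(model)
        P[:, j] = probs[model.partition.class_to_group]
    return P


def monotonicity_violations(
    probs: np.ndarray,
    partition: LatentGroupPartition,
    tol: float = PROB_TOL,
) -> list[tuple[int, int]]:
    """Adjacent group pairs where raising one attribute level lowers success.

    Checks every ordered pair of groups differing by +1 level on exactly one
    required attribute and reports those with ``P(upper) < P(lower) - tol``.
    """
    probs = np.asarray(probs, dtype=float)
    return [
        (lo, hi)
        for lo, hi in partition.adjacent_pairs()
        if probs[hi] < probs[lo] - tol
    ]


def delta_from_group_probs(item_model: ItemModel, probs: np.ndarray) -> np.ndarray:
    """Recover delta from group probabilities (least squares on the link scale).

    Exact for the saturated model, whose design is square and invertible.
    """
    probs = np.asarray(probs, dtype=float)
    eps = 1e-10
    clipped = np.clip(probs, eps, 1 - eps)
    if item_model.link == "identity":
        target = probs
    elif item_model.link == "logit":
        target = logit_fn(clipped)
    else:
        target = np.log(clipped)
    delta, *_ = np.linalg.lstsq(item_model.design, target, rcond=None)
    return delta
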