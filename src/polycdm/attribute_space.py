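"""Polytomous attribute spaces, Q-matrices, and latent-group partitions.

A cognitive-diagnosis model classifies examinees into latent classes, each a
full attribute pattern ``(alpha_1, ..., alpha_K)`` where attribute ``k`` has
``M_k >= 2`` ordered levels ``0, ..., M_k - 1``.  An item's Q-matrix row
specifies, for each attribute, the level required to answer the item
correctly (0 = not required).  The item cannot distinguish classes that agree
on its required attributes; those classes form a *latent group*, and every
item-response function is defined on groups rather than classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttributeSpec",
    "QMatrix",
    "LatentGroupPartition",
    "QMatrixReport",
    "InvalidSpecError",
    "InvalidQMatrixError",
    "enumerate_patterns",
    "partition_groups",
    "count_item_parameters",
    "validate_qmatrix",
]

#: Model kinds understood throughout the package.  ``additive_logit`` and
#: ``additive_log`` share the fully-additive column set but apply it on the
#: link scale.
MODEL_KINDS = (
    "saturated",
    "pgdina",
    "fam",
    "min_fam",
    "max_fam",
    "conjunctive",
    "disjunctive",
    "additive_logit",
    "additive_log",
)

_KIND_ALIASES = {
    "sp-cdm": "saturated",
    "spcdm": "saturated",
    "pg-dina": "pgdina",
    "fa-m": "fam",
    "min-fa-m": "min_fam",
    "max-fa-m": "max_fam",
    "min_fa_m": "min_fam",
    "max_fa_m": "max_fam",
    "pdina": "conjunctive",
    "pdino": "disjunctive",
    "additive-logit": "additive_logit",
    "additive-log": "additive_log",
}


def canonical_kind(model_kind: str) -> str:
    """Normalize a model-kind name; raise ``ValueError`` if unknown."""
    kind = model_kind.strip().lower().replace(" ", "_")
    kind = _KIND_ALIASES.get(kind, kind)
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    return kind


class InvalidSpecError(ValueError):
    """Raised for attribute specifications that define no valid class space."""


class InvalidQMatrixError(ValueError):
    """Raised for structurally invalid Q-matrices."""


@dataclass(frozen=True)
class AttributeSpec:
    """Number of ordered levels per attribute.

    Parameters
    ----------
    levels
        ``M_k`` for each of the K attributes; every ``M_k >= 2``.  The level
        values of attribute ``k`` are ``0, ..., M_k - 1``.
    """

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        levels = tuple(int(m) for m in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 1:
            raise InvalidSpecError("at least one attribute is required")
        if any(m < 2 for m in levels):
            raise InvalidSpecError(f"every attribute needs >= 2 levels, got {levels}")

    @property
    def n_attributes(self) -> int:
        return len(self.levels)

    @property
    def n_classes(self) -> int:
        """Total number of latent classes, the product of the level counts."""
        return int(np.prod(self.levels))


def enumerate_patterns(spec: AttributeSpec) -> np.ndarray:
    """All attribute patterns in lexicographic order, last attribute fastest.

    Returns a ``(prod M_k, K)`` integer array whose first row is all zeros
    and whose last row is ``(M_1-1, ..., M_K-1)``.
    """
    grids = np.meshgrid(*(np.arange(m) for m in spec.levels), indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, spec.n_attributes)


@dataclass(frozen=True)
class QMatrix:
    """J x K matrix of required attribute levels (0 = not required)."""

    entries: np.ndarray
    spec: AttributeSpec

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=int)
        if entries.ndim != 2:
            raise InvalidQMatrixError("Q-matrix must be two-dimensional")
        if entries.shape[1] != self.spec.n_attributes:
            raise InvalidQMatrixError(
                f"Q-matrix has {entries.shape[1]} columns but the spec defines "
                f"{self.spec.n_attributes} attributes"
            )
        levels = np.asarray(self.spec.levels)
        if (entries < 0).any() or (entries >= levels).any():
            bad = np.argwhere((entries < 0) | (entries >= levels))
            j, k = bad[0]
            raise InvalidQMatrixError(
                f"entry q[{j},{k}]={entries[j, k]} outside 0..{levels[k] - 1}"
            )
        if (entries.sum(axis=1) == 0).any():
            j = int(np.flatnonzero(entries.sum(axis=1) == 0)[0])
            raise InvalidQMatrixError(f"item {j} requires no attribute (all-zero row)")
        object.__setattr__(self, "entries", entries)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    def required(self, j: int) -> np.ndarray:
        """Indices of attributes required by item ``j``."""
        return np.flatnonzero(self.entries[j] > 0)


@dataclass(frozen=True)
class LatentGroupPartition:
    """Partition of the class space induced by one item's Q-matrix row.

    ``groups`` lists the reduced attribute patterns (level vectors restricted
    to the required attributes) in lexicographic order, last required
    attribute varying fastest.  ``class_to_group[c]`` maps latent class ``c``
    (in :func:`enumerate_patterns` order) to its group index.
    """

    q_row: tuple[int, ...]
    required: tuple[int, ...]
    groups: np.ndarray
    class_to_group: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.groups.shape[0]

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.class_to_group, minlength=self.n_groups)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Ordered group pairs (lower, upper) differing by +1 on one attribute.

        These are the covering relations of the componentwise order on the
        reduced patterns; monotonicity on them implies monotonicity on the
        whole partial order.
        """
        index = {tuple(g): i for i, g in enumerate(self.groups)}
        pairs: list[tuple[int, int]] = []
        for i, g in enumerate(self.groups):
            for pos in range(len(g)):
                upper = list(g)
                upper[pos] += 1
                hi = index.get(tuple(upper))
                if hi is not None:
                    pairs.append((i, hi))
        return pairs


def partition_groups(q_row: np.ndarray, spec: AttributeSpec) -> LatentGroupPartition:
    """Group the latent classes by their levels on an item's required attributes.

    Two classes share a group iff they agree on every attribute the item
    requires; e.g. with three 3-level attributes and a row requiring levels
    (1, 2) of the first two, the classes 000, 001 and 002 all fall in group 00.
    """
    q_row = np.asarray(q_row, dtype=int)
    required = np.flatnonzero(q_row > 0)
    if required.size == 0:
        raise InvalidQMatrixError("item requires no attribute (all-zero q-row)")
    req_levels = [spec.levels[k] for k in required]

    grids = np.meshgrid(*(np.arange(m) for m in req_levels), indexing="ij")
    groups = np.stack(grids, axis=-1).reshape(-1, required.size)

    patterns = enumerate_patterns(spec)
    restricted = patterns[:, required]
    # mixed-radix index of the restricted pattern == group index, because the
    # group enumeration uses the same last-fastest order
    radix = np.ones(required.size, dtype=int)
    for pos in range(required.size - 2, -1, -1):
        radix[pos] = radix[pos + 1] * req_levels[pos + 1]
    class_to_group = restricted @ radix

    return LatentGroupPartition(
        q_row=tuple(q_row.tolist()),
        required=tuple(required.tolist()),
        groups=groups,
        class_to_group=class_to_group.astype(int),
    )


def count_item_parameters(model_kind: str, q_row: np.ndarray, spec: AttributeSpec) -> int:
    """Number of free item parameters for a model kind on a given q-row.

    The saturated count is the number of latent groups (the product of the
    *maximum* levels of the required attributes — the required levels
    themselves do not enter).  The pG-DINA collapses each required attribute
    to at-or-above vs. below its required level, giving the dichotomous
    G-DINA count ``2**K*``.  The additive families keep the intercept plus
    main-effect step terms; the conjunctive/disjunctive kinds have two
    parameters regardless of the q-row.
    """
    kind = canonical_kind(model_kind)
    q_row = np.asarray(q_row, dtype=int)
    required = np.flatnonzero(q_row > 0)
    if required.size == 0:
        raise InvalidQMatrixError("item requires no attribute (all-zero q-row)")
    m = np.asarray([spec.levels[k] for k in required])
    q = q_row[required]
    if kind == "saturated":
        return int(np.prod(m))
    if kind == "pgdina":
        return int(2 ** required.size)
    if kind in ("fam", "additive_logit", "additive_log"):
        return int(1 + np.sum(m - 1))
    if kind == "min_fam":
        return int(1 + np.sum(m - q))
    if kind == "max_fam":
        return int(1 + np.sum(q))
    # conjunctive / disjunctive
    return 2


@dataclass
class QMatrixReport:
    """Report from the Q-matrix coverage heuristic (never raises)."""

    coverage: dict[tuple[int, int], int] = field(default_factory=dict)
    under_covered: list[tuple[int, int]] = field(default_factory=list)
    all_zero_rows: list[int] = field(default_factory=list)

    @property
    def n_flags(self) -> int:
        return len(self.under_covered) + len(self.all_zero_rows)


def validate_qmatrix(entries: np.ndarray, spec: AttributeSpec) -> QMatrixReport:
    """Heuristic coverage check on a raw Q-matrix array.

    For every attribute ``k`` and level ``m >= 1``, counts the items that
    require exactly that level and flags (k, m) pairs required by fewer than
    two items; also flags all-zero rows.  This is a screening device, not an
    identifiability proof.
    """
    entries = np.asarray(entries, dtype=int)
    report = QMatrixReport()
    report.all_zero_rows = [int(j) for j in np.flatnonzero(entries.sum(axis=1) == 0)]
    for k in range(spec.n_attributes):
        for m in range(1, spec.levels[k]):
            count = int(np.sum(entries[:, k] == m))
            report.coverage[(k, m)] = count
            if count < 2:
                report.under_covered.append((k, m))
    return report
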