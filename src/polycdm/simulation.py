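"""Synthetic data generation for the simulation design.

Study conditions: K in {3, 5} three-level attributes, test lengths J in
{26, 52} (the 52-item form duplicates the 26-item Q-matrix), sample sizes
N in {1000, 2000}, and three item-quality levels defined symmetrically by
guessing and slip: high (g = s = .05), moderate (.10), low (.15).  Attribute
patterns are drawn uniformly over all prod(M_k) classes.

Item-quality profiles carry the generating intercepts (.05/.10/.15) and the
mean main-effect (.16/.15/.13) and interaction-effect (.10/.08/.07) sizes
per quality level.  Generating parameters set every effect equal to its
class mean and then rescale all non-intercept effects by a common factor so
the top latent group's success probability equals 1 - s; item quality
(g, 1 - s) is thereby controlled exactly, all effects are non-negative
(hence monotone), and every group probability lies in [g, 1 - s].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, cycle, product

import numpy as np

from .attribute_space import AttributeSpec, QMatrix, canonical_kind
from .model_irf import ItemModel, build_item_model, class_success_matrix

__all__ = [
    "QualityProfile",
    "SimulationDesign",
    "quality_profile",
    "generate_item_parameters",
    "generate_attributes",
    "generate_responses",
    "make_qmatrix",
    "pattern_index",
    "child_seed",
]

_PROFILES = {
    "high": (0.05, 0.16, 0.10),
    "moderate": (0.10, 0.15, 0.08),
    "low": (0.15, 0.13, 0.07),
}


@dataclass(frozen=True)
class QualityProfile:
    """Generating parameter profile for one item-quality level.

    ``intercept`` is the guessing parameter g; slip is set equal to g, so
    the top group's probability is ``1 - intercept``.
    """

    name: str
    intercept: float
    main_effect: float
    interaction: float

    @property
    def max_probability(self) -> float:
        return 1.0 - self.intercept

    def __post_init__(self) -> None:
        if not 0 < self.intercept < self.max_probability < 1:
            raise ValueError("profile requires 0 < g < 1 - s < 1")


def quality_profile(level: str) -> QualityProfile:
    try:
        g, main, inter = _PROFILES[level]
    except KeyError:
        raise ValueError(f"unknown item quality level: {level!r}") from None
    return QualityProfile(name=level, intercept=g, main_effect=main, interaction=inter)


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(root_seed: int, *path: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed splitting rule."""
    return np.random.SeedSequence([int(root_seed), *map(int, path)])


def generate_item_parameters(
    q_row: np.ndarray,
    spec: AttributeSpec,
    model_kind: str,
    profile: QualityProfile,
    seed: int | np.random.Generator = 0,
) -> ItemModel:
    """Generating item model on the identity link with exactly controlled quality.

    Effects equal their class mean (main vs. interaction) and are rescaled
    by a common positive factor so the all-mastery group's probability is
    ``1 - s``; the result is deterministic given the profile (``seed`` is
    accepted for interface symmetry with the stochastic generators).
    """
    kind = canonical_kind(model_kind)
    model = build_item_model(kind, "identity", q_row, spec)
    g, top = profile.intercept, profile.max_probability
    if top <= g:
        raise ValueError("infeasible quality profile: 1 - s <= g")
    if kind in ("conjunctive", "disjunctive"):
        delta = np.array([g, top - g])
    else:
        effects = np.array(
            [
                profile.main_effect if info.order == 1 else profile.interaction
                for info in model.columns[1:]
            ]
        )
        # with cumulative step coding the top group's design row is all ones
        scale = (top - g) / effects.sum()
        delta = np.concatenate([[g], scale * effects])
    return model.with_delta(delta)


def generate_attributes(
    N: int,
    spec: AttributeSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """N i.i.d. attribute patterns, uniform over all prod(M_k) classes."""
    from .attribute_space import enumerate_patterns

    rng = _rng(seed)
    patterns = enumerate_patterns(spec)
    return patterns[rng.integers(0, len(patterns), size=N)]


def pattern_index(patterns: np.ndarray, spec: AttributeSpec) -> np.ndarray:
    """Class index of each pattern row (mixed radix, last attribute fastest)."""
    radix = np.ones(spec.n_attributes, dtype=int)
    for k in range(spec.n_attributes - 2, -1, -1):
        radix[k] = radix[k + 1] * spec.levels[k + 1]
    return np.asarray(patterns, dtype=int) @ radix


def generate_responses(
    patterns: np.ndarray,
    item_models: list[ItemModel],
    spec: AttributeSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bernoulli responses: x_ij ~ Bernoulli(P_j(class_i))."""
    rng = _rng(seed)
    P = class_success_matrix(item_models, spec)
    p_i = P[pattern_index(patterns, spec)]
    return (rng.random(p_i.shape) < p_i).astype(int)


def make_qmatrix(
    spec: AttributeSpec,
    J: int,
    template: str = "balanced",
    base_items: int | None = None,
    path: str | None = None,
) -> QMatrix:
    """Q-matrix fixture for a simulation condition.

    ``balanced`` (procedural): for every attribute and level m >= 1, two
    single-attribute items requiring exactly that level, then two- and
    three-attribute items cycling through level combinations.  With
    ``base_items`` set, the balanced matrix of that many rows is tiled to
    length J (the duplicated long-form design).  ``csv`` loads a
    user-supplied matrix from ``path``.
    """
    if template == "csv":
        if path is None:
            raise FileNotFoundError("template 'csv' requires a Q-matrix file path")
        from .io import read_qmatrix

        return read_qmatrix(path, spec)
    if template != "balanced":
        raise ValueError(f"unknown Q-matrix template: {template!r}")

    if base_items is not None:
        if J % base_items:
            raise ValueError("J must be a multiple of base_items")
        base = make_qmatrix(spec, base_items)
        return QMatrix(np.tile(base.entries, (J // base_items, 1)), spec)

    K = spec.n_attributes
    rows: list[np.ndarray] = []
    for k in range(K):
        for m in range(1, spec.levels[k]):
            row = np.zeros(K, dtype=int)
            row[k] = m
            rows.append(row.copy())
            rows.append(row.copy())
    if len(rows) > J:
        raise ValueError(
            f"J={J} too small for level coverage ({len(rows)} single-attribute items)"
        )

    n_fill = J - len(rows)
    n_triple = min(2, n_fill) if K >= 3 else 0
    pair_iter = cycle(combinations(range(K), 2))
    combo_counters: dict[tuple[int, int], int] = {}
    for _ in range(n_fill - n_triple):
        pair = next(pair_iter)
        combos = list(
            product(range(1, spec.levels[pair[0]]), range(1, spec.levels[pair[1]]))
        )
        idx = combo_counters.get(pair, 0)
        lv = combos[idx % len(combos)]
        combo_counters[pair] = idx + 1
        row = np.zeros(K, dtype=int)
        row[pair[0]], row[pair[1]] = lv
        rows.append(row)
    triple_iter = cycle(combinations(range(K), 3))
    for t in range(n_triple):
        triple = next(triple_iter)
        row = np.zeros(K, dtype=int)
        for k in triple:
            row[k] = min(1 + t, spec.levels[k] - 1)
        rows.append(row)
    return QMatrix(np.array(rows), spec)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation grid."""

    K: int = 3
    levels: tuple[int, ...] | None = None
    J: int = 26
    N: int = 1000
    quality: str = "high"
    generating_model: str = "saturated"
    replications: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels is None:
            object.__setattr__(self, "levels", (3,) * self.K)
        if len(self.levels) != self.K:
            raise ValueError("levels length must equal K")

    @property
    def spec(self) -> AttributeSpec:
        return AttributeSpec(self.levels)

    def qmatrix(self) -> QMatrix:
        base = 26 if self.J % 26 == 0 else None
        return make_qmatrix(self.spec, self.J, base_items=base)

    def true_item_models(self, qmatrix: QMatrix | None = None) -> list[ItemModel]:
        Q = qmatrix if qmatrix is not None else self.qmatrix()
        profile = quality_profile(self.quality)
        return [
            generate_item_parameters(
                Q.entries[j], self.spec, self.generating_model, profile
            )
            for j in range(Q.n_items)
        ]

    def replicate(self, rep: int, qmatrix: QMatrix | None = None,
                  item_models: list[ItemModel] | None = None):
        """Generate (patterns, responses) for replication ``rep``."""
        Q = qmatrix if qmatrix is not None else self.qmatrix()
        models = item_models if item_models is not None else self.true_item_models(Q)
        rng = np.random.default_rng(child_seed(self.seed, rep))
        patterns = generate_attributes(self.N, self.spec, rng)
        responses = generate_responses(patterns, models, self.spec, rng)
        return patterns, responses
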