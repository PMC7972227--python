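"""Progressive-permutation scenario construction.

A two-group design with ``n1`` and ``n2`` samples is progressively mixed by
exchanging the labels of ``k`` samples drawn from each group, for
``k = 0`` (the observed data) up to ``K = min(n1, n2)``.  The number of
distinct label arrangements at depth ``k`` is ``C(n1,k) * C(n2,k)``; it is
maximal at the *full-mixing* depth ``K_f = ceil((n1*n2 - 1)/(n1 + n2 + 2))``,
which is treated as the fully mixed null.  Because enumerating every
arrangement is infeasible for realistic sample sizes, each depth is explored
with a logarithmic draw budget ``nu = round(N * (ln C(n1,k) + ln C(n2,k)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupLabels",
    "ScenarioGrid",
    "LabelDraw",
    "full_mixing_index",
    "num_scenario_choices",
    "draw_budget",
    "generate_draws",
    "continuous_scenario_draws",
]


def _check_positive_int(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if value < 1:
        raise ValueError(f"{name} must be >= 1, got {value}")
    return int(value)


@dataclass(frozen=True)
class GroupLabels:
    """A binary grouping factor over identified samples.

    Labels take values in {1, 2}; group 1 has ``n1`` samples and group 2
    has ``n2``.
    """

    sample_ids: tuple
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.sample_ids) != labels.size:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {labels.size} labels"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if not np.isin(labels, (1, 2)).all():
            raise ValueError("labels must take values in {1, 2}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both groups must be non-empty")

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 2))

    @property
    def N(self) -> int:
        return self.labels.size

    @classmethod
    def from_array(cls, labels, sample_ids=None) -> "GroupLabels":
        labels = np.asarray(labels)
        if sample_ids is None:
            sample_ids = tuple(range(labels.size))
        return cls(sample_ids=tuple(sample_ids), labels=labels)


@dataclass(frozen=True)
class LabelDraw:
    """One label-exchange draw at mixing depth ``k``.

    ``k`` samples drawn from each group have their labels exchanged,
    starting from the original labels (draws are never chained).
    """

    k: int
    swapped_from_1: np.ndarray  # positions (in the label vector) leaving group 1
    swapped_from_2: np.ndarray
    permuted_labels: np.ndarray


def full_mixing_index(n1: int, n2: int) -> int:
    """Depth ``K_f = ceil((n1*n2 - 1)/(n1 + n2 + 2))`` maximizing the number
    of distinct arrangements; for ``n1 = n2 = n`` this is ``ceil((n-1)/2)``."""
    n1 = _check_positive_int(n1, "n1")
    n2 = _check_positive_int(n2, "n2")
    return -((n1 * n2 - 1) // -(n1 + n2 + 2))  # ceiling division


def num_scenario_choices(n1: int, n2: int, k: int) -> int:
    """Exact count ``C(n1,k) * C(n2,k)`` of distinct label exchanges at depth k."""
    n1 = _check_positive_int(n1, "n1")
    n2 = _check_positive_int(n2, "n2")
    if not isinstance(k, (int, np.integer)) or k < 0 or k > min(n1, n2):
        raise ValueError(f"k must be an integer in [0, min(n1, n2)], got {k!r}")
    return math.comb(n1, int(k)) * math.comb(n2, int(k))


def draw_budget(N: int, n1: int, n2: int, k: int, total_cap: bool = True) -> int:
    """Number of draws ``nu = round(N * (ln C(n1,k) + ln C(n2,k)))`` at depth k.

    Floored at 1 (depths with a single arrangement still get one draw) and,
    when ``total_cap`` is true, capped at the exact number of distinct
    arrangements.  Depth 0 is the observed data and is handled by the caller
    as a single draw.
    """
    if k == 0:
        raise ValueError("the draw budget is defined for k >= 1; k=0 is the observed data")
    n1 = _check_positive_int(n1, "n1")
    n2 = _check_positive_int(n2, "n2")
    if N != n1 + n2:
        raise ValueError(f"N must equal n1 + n2, got {N} != {n1 + n2}")
    if not 1 <= k <= min(n1, n2):
        raise ValueError(f"k must be in [1, min(n1, n2)], got {k}")
    k = int(k)
    log_choices = math.lgamma(n1 + 1) - math.lgamma(k + 1) - math.lgamma(n1 - k + 1)
    log_choices += math.lgamma(n2 + 1) - math.lgamma(k + 1) - math.lgamma(n2 - k + 1)
    nu = max(1, round(N * log_choices))
    if total_cap:
        nu = min(nu, num_scenario_choices(n1, n2, k))
    return nu


@dataclass(frozen=True)
class ScenarioGrid:
    """The evaluated mixing depths and their draw budgets.

    ``ks`` always contains 0, ``K_f`` and ``K`` even when thinned with
    ``k_step > 1``, so the observed data, the fully mixed null and the
    symmetric endpoint are always evaluated.
    """

    n1: int
    n2: int
    seed: int
    k_step: int = 1
    budget_override: int | None = None
    ks: tuple = field(init=False)
    budgets: dict = field(init=False)

    def __post_init__(self):
        K = min(self.n1, self.n2)
        Kf = full_mixing_index(self.n1, self.n2)
        ks = sorted(set(range(0, K + 1, max(1, self.k_step))) | {0, Kf, K})
        budgets = {}
        for k in ks:
            if k == 0:
                budgets[k] = 1
            elif self.budget_override is not None:
                nu = min(self.budget_override, num_scenario_choices(self.n1, self.n2, k))
                budgets[k] = max(1, nu)
            else:
                budgets[k] = draw_budget(self.n1 + self.n2, self.n1, self.n2, k)
        object.__setattr__(self, "ks", tuple(ks))
        object.__setattr__(self, "budgets", budgets)

    @property
    def K(self) -> int:
        return min(self.n1, self.n2)

    @property
    def K_f(self) -> int:
        return full_mixing_index(self.n1, self.n2)


def _draw_rng(seed: int, k: int, i: int) -> np.random.Generator:
    # one independent stream per (depth, draw index) so results do not
    # depend on which depths are evaluated or in what order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k), int(i)]))


def generate_draws(labels: GroupLabels, k: int, budget: int, seed: int) -> list[LabelDraw]:
    """Sample ``budget`` label-exchange draws at depth ``k``.

    Each draw starts from the original labels, picks a uniform k-subset of
    each group (with replacement across draws) and exchanges their labels.
    Deterministic given ``(seed, k, draw index)``.
    """
    K = min(labels.n1, labels.n2)
    if not 0 <= k <= K:
        raise ValueError(f"k must be in [0, {K}], got {k}")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if k == 0:
        return [
            LabelDraw(0, np.empty(0, int), np.empty(0, int), labels.labels.copy())
        ]
    pos1 = np.flatnonzero(labels.labels == 1)
    pos2 = np.flatnonzero(labels.labels == 2)
    draws = []
    for i in range(budget):
        rng = _draw_rng(seed, k, i)
        take1 = pos1[rng.choice(labels.n1, size=k, replace=False)]
        take2 = pos2[rng.choice(labels.n2, size=k, replace=False)]
        permuted = labels.labels.copy()
        permuted[take1] = 2
        permuted[take2] = 1
        draws.append(LabelDraw(k, take1, take2, permuted))
    return draws


def swap_matrix(labels: GroupLabels, k: int, budget: int, seed: int) -> np.ndarray:
    """Boolean (budget, N) matrix of group-1 membership after each draw.

    Fast-path companion of :func:`generate_draws` sharing its RNG streams,
    used by the batch test engines.
    """
    draws = generate_draws(labels, k, budget, seed)
    return np.stack([d.permuted_labels == 1 for d in draws])


def continuous_scenario_draws(outcome, k: int, budget: int, seed: int) -> list[np.ndarray]:
    """Partial-permutation draws of a continuous outcome.

    Each draw selects ``k`` samples uniformly and shuffles their outcome
    values among themselves (an unconstrained uniform shuffle), leaving the
    remaining ``N - k`` values fixed; ``k = N`` is a uniform permutation of
    the whole vector.
    """
    outcome = np.asarray(outcome, dtype=float)
    N = outcome.size
    if not 0 <= k <= N:
        raise ValueError(f"k must be in [0, {N}], got {k}")
    if k == 0:
        return [outcome.copy() for _ in range(budget)]
    draws = []
    for i in range(budget):
        rng = _draw_rng(seed, k, i)
        sel = rng.choice(N, size=k, replace=False)
        permuted = outcome.copy()
        permuted[sel] = permuted[sel][rng.permutation(k)]
        draws.append(permuted)
    return draws
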