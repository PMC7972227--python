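"""Synthetic microbiome count tables for exercising the pipeline.

Three generators cover the study conditions the package is validated under:

* :func:`nb_copula_dataset` — negative-binomial marginals NB(mean m,
  variance m + m^2/kappa) tied together by a Gaussian copula with AR(1)
  correlation ``R_ij = rho^|i-j|``; the first ``nsv`` features carry a
  group mean shift, everything else has mean 1 in both groups.
* :func:`heterogeneous_dataset` — per-subgroup NB-copula blocks with their
  own mean vectors and dispersions, modelling hidden within-group
  heterogeneity; shipped presets ``simdata1``/``simdata2``/``simdata3``
  realize three increasing heterogeneity levels.
* :func:`zero_inflated_dataset` — per-feature zero inflation ``pi_j`` with
  a moment-matched lognormal positive part rounded to counts, for sparse
  microbiome-like tables.

An optional compositional step divides every entry by one global constant
slightly above the largest sample sum; rank-based tests are invariant to
it, which the test suite asserts end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NBCopulaSpec",
    "SubgroupSpec",
    "ZeroInflSpec",
    "nb_copula_dataset",
    "heterogeneous_dataset",
    "zero_inflated_dataset",
    "load_preset",
    "generate_preset",
    "compositionalize",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "simdata1",
    "simdata2",
    "simdata3",
    "table1_grid",
    "set2_dense",
    "set2_sparse",
)


@dataclass(frozen=True)
class NBCopulaSpec:
    """Homogeneous two-group NB-copula design.

    The first ``nsv`` features have group means ``mean1`` vs ``mean2``;
    the remaining ``p - nsv`` features have mean 1 in both groups.
    Variance is ``m + m^2/kappa``.
    """

    n1: int = 30
    n2: int = 30
    p: int = 100
    nsv: int = 30
    mean1: float = 10.0
    mean2: float = 1.0
    kappa: float = 24.0
    rho: float = 0.5
    compositional: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if not 0 <= self.nsv <= self.p:
            raise ValueError("nsv must be in [0, p]")


@dataclass(frozen=True)
class SubgroupSpec:
    """Blocked heterogeneous design: a list of subgroup blocks.

    Each block is ``(n_samples, mean_vector, kappa)``; ``labels`` gives the
    group (1 or 2) of each block.  ``random_mean_blocks`` optionally maps a
    block index to ``[(mu0, var0, count), ...]`` segments whose per-feature
    means are drawn from N(mu0, var0), truncated below at 0.01.
    """

    blocks: tuple
    labels: tuple
    rho: float = 0.5
    compositional: bool = False
    seed: int = 0
    random_mean_blocks: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.blocks) != len(self.labels):
            raise ValueError("one group label per block is required")
        if not set(self.labels) <= {1, 2}:
            raise ValueError("block labels must be 1 or 2")


@dataclass(frozen=True)
class ZeroInflSpec:
    """Zero-inflated design: entry 0 with probability ``pi_j``, else a
    moment-matched lognormal draw with mean ``mu_j`` (plus
    ``group_mean_shift_j`` in group 1) and variance ``var_j``, rounded to a
    count.  Non-positive means give structural zeros."""

    n1: int = 30
    n2: int = 30
    pi: tuple = (0.1,) * 100
    mu: tuple = (1.0,) * 100
    var: tuple = (0.2,) * 100
    group_mean_shift: tuple = (0.0,) * 100
    seed: int = 0

    def __post_init__(self):
        p = len(self.pi)
        if not (len(self.mu) == len(self.var) == len(self.group_mean_shift) == p):
            raise ValueError("pi, mu, var and group_mean_shift must share a length")
        if np.any((np.asarray(self.pi) < 0) | (np.asarray(self.pi) > 1)):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(np.asarray(self.var) <= 0):
            raise ValueError("var must be positive")

    @property
    def p(self) -> int:
        return len(self.pi)


def _ar1_gaussian(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """N(0, R) draws with R_ij = rho^|i-j| via the AR(1) recursion."""
    eps = rng.standard_normal((n, p))
    Z = np.empty_like(eps)
    Z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, p):
        Z[:, j] = rho * Z[:, j - 1] + scale * eps[:, j]
    return Z


def _nb_quantile(u: np.ndarray, mean, kappa) -> np.ndarray:
    """NB quantile transform with size = kappa, so Var = m + m^2/kappa."""
    from scipy import stats

    mean = np.broadcast_to(np.asarray(mean, float), u.shape)
    prob = kappa / (kappa + mean)
    return stats.nbinom.ppf(u, kappa, prob)


def _nb_copula_block(
    rng: np.random.Generator, n: int, means, kappa: float, rho: float
) -> np.ndarray:
    from scipy import stats

    means = np.asarray(means, dtype=float)
    Z = _ar1_gaussian(rng, n, means.size, rho)
    U = stats.norm.cdf(Z)
    return _nb_quantile(U, means[None, :], kappa)


def compositionalize(X: np.ndarray) -> np.ndarray:
    """Divide every entry by one global constant (1.1 x the largest sample
    sum), turning counts into relative abundances without touching
    cross-sample ranks."""
    X = np.asarray(X, dtype=float)
    constant = 1.1 * X.sum(axis=1).max()
    return X / constant


def _package(X: np.ndarray, n1: int, n2: int, compositional: bool):
    if compositional:
        X = compositionalize(X)
    samples = [f"S{i+1}" for i in range(n1 + n2)]
    features = [f"F{j+1}" for j in range(X.shape[1])]
    table = pd.DataFrame(X, index=samples, columns=features)
    y = np.r_[np.ones(n1, int), np.full(n2, 2)]
    labels = pd.Series(y, index=samples, name="group")
    return table, labels


def nb_copula_dataset(spec: NBCopulaSpec):
    """Two-group correlated NB counts; returns (table, labels) as a
    samples x features DataFrame and a group Series."""
    rng = np.random.default_rng(spec.seed)
    means1 = np.ones(spec.p)
    means2 = np.ones(spec.p)
    means1[: spec.nsv] = spec.mean1
    means2[: spec.nsv] = spec.mean2
    X1 = _nb_copula_block(rng, spec.n1, means1, spec.kappa, spec.rho)
    X2 = _nb_copula_block(rng, spec.n2, means2, spec.kappa, spec.rho)
    return _package(np.vstack([X1, X2]), spec.n1, spec.n2, spec.compositional)


def heterogeneous_dataset(spec: SubgroupSpec):
    """Blocked NB-copula counts with per-block means and dispersions."""
    rng = np.random.default_rng(spec.seed)
    parts, labels = [], []
    p = None
    for b, ((n, means, kappa), lab) in enumerate(zip(spec.blocks, spec.labels)):
        if b in spec.random_mean_blocks:
            segments = []
            for mu0, var0, count in spec.random_mean_blocks[b]:
                draw = rng.normal(mu0, np.sqrt(var0), size=count)
                segments.append(np.maximum(draw, 0.01))
            means = np.concatenate(segments)
        means = np.asarray(means, dtype=float)
        if p is None:
            p = means.size
        elif means.size != p:
            raise ValueError("all blocks must cover the same features")
        parts.append(_nb_copula_block(rng, n, means, kappa, spec.rho))
        labels.extend([lab] * n)
    X = np.vstack(parts)
    order = np.argsort(labels, kind="stable")
    X = X[order]
    labels = np.asarray(labels)[order]
    n1 = int(np.sum(labels == 1))
    n2 = labels.size - n1
    return _package(X, n1, n2, spec.compositional)


def zero_inflated_dataset(spec: ZeroInflSpec):
    """Zero-inflated counts with per-feature inflation, mean and variance."""
    rng = np.random.default_rng(spec.seed)
    N = spec.n1 + spec.n2
    pi = np.asarray(spec.pi, float)
    var = np.asarray(spec.var, float)
    mu_base = np.asarray(spec.mu, float)
    shift = np.asarray(spec.group_mean_shift, float)
    mu = np.tile(mu_base, (N, 1))
    mu[: spec.n1] += shift
    X = np.zeros((N, spec.p))
    positive = mu > 0
    # lognormal moment match: sigma2 = ln(1 + V/M^2), mulog = ln M - sigma2/2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.log1p(var[None, :] / mu**2)
        mulog = np.log(mu) - sigma2 / 2.0
    draws = rng.lognormal(
        np.where(positive, mulog, 0.0), np.sqrt(np.where(positive, sigma2, 1.0))
    )
    X[positive] = np.round(draws[positive])
    zero_mask = rng.random((N, spec.p)) < pi[None, :]
    X[zero_mask] = 0.0
    return _package(X, spec.n1, spec.n2, False)


# ---------------------------------------------------------------------------
# shipped presets


def load_preset(name: str) -> dict:
    """Raw parameter dictionary of a shipped preset."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("permcurve.presets").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def _spec_from_preset(cfg: dict, seed: int):
    kind = cfg["kind"]
    if kind == "nb_copula":
        return NBCopulaSpec(seed=seed, **cfg["params"])
    if kind == "subgroups":
        blocks = []
        random_mean_blocks = {}
        for b, block in enumerate(cfg["blocks"]):
            mean = block.get("mean")
            if mean is not None:
                means = np.concatenate(
                    [np.full(count, value, float) for value, count in mean]
                )
            else:
                means = np.zeros(cfg["p"])
                random_mean_blocks[b] = [
                    (mu0, var0, count) for mu0, var0, count in block["random_mean"]
                ]
            blocks.append((block["n"], means, block["kappa"]))
        return SubgroupSpec(
            blocks=tuple(blocks),
            labels=tuple(block["group"] for block in cfg["blocks"]),
            rho=cfg.get("rho", 0.5),
            seed=seed,
            random_mean_blocks=random_mean_blocks,
        )
    if kind == "zero_inflated":
        params = cfg["params"]
        p = params["p"]
        nsv = params["nsv"]
        shift = np.zeros(p)
        shift[:nsv] = np.linspace(
            params["shift_max"], params["shift_min"], nsv
        )
        return ZeroInflSpec(
            n1=params["n1"],
            n2=params["n2"],
            pi=(params["pi"],) * p,
            mu=(params["mu"],) * p,
            var=(params["var"],) * p,
            group_mean_shift=tuple(shift),
            seed=seed,
        )
    raise ValueError(f"unknown preset kind {kind!r}")


def generate_preset(name: str, seed: int = 0):
    """Materialize a shipped preset as (table, labels).

    ``table1_grid`` is a collection of parameter rows rather than a single
    dataset; materialize its rows individually via :class:`NBCopulaSpec`.
    """
    cfg = load_preset(name)
    if cfg["kind"] == "grid":
        raise ValueError(
            "table1_grid is a parameter grid; build NBCopulaSpec rows from "
            "load_preset('table1_grid')['rows']"
        )
    spec = _spec_from_preset(cfg, seed)
    if isinstance(spec, NBCopulaSpec):
        return nb_copula_dataset(spec)
    if isinstance(spec, SubgroupSpec):
        return heterogeneous_dataset(spec)
    return zero_inflated_dataset(spec)
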