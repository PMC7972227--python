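import numpy as np
import pytest

from permcurve import (
    NBCopulaSpec,
    ProgressivePermutation,
    generate_preset,
    nb_copula_dataset,
)

STRONG_SEEDS = (1, 2, 3, 4, 5)
SIMDATA1_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny correlated-count dataset: 8+8 samples, 20 features, 5 shifted."""
    X, y = nb_copula_dataset(
        NBCopulaSpec(n1=8, n2=8, p=20, nsv=5, mean1=10, mean2=1, kappa=24,
                     rho=0.5, seed=7)
    )
    return X, y


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    X, y = small_dataset
    return ProgressivePermutation(n_draws=60, random_state=7).fit(X, y)


@pytest.fixture(scope="session")
def strong_fits():
    """The strong-signal correlated-count benchmark (30 shifted features,
    mean difference 9, dispersion 24) fitted over several seeds."""
    fits = {}
    for seed in STRONG_SEEDS:
        X, y = nb_copula_dataset(NBCopulaSpec(seed=seed))
        fits[seed] = ProgressivePermutation(
            random_state=seed, store_draws=False
        ).fit(X, y)
    return fits


@pytest.fixture(scope="session")
def null_fits():
    """The matched null benchmark: identical group means everywhere."""
    fits = {}
    for seed in STRONG_SEEDS:
        X, y = nb_copula_dataset(NBCopulaSpec(mean1=10, mean2=10, seed=seed))
        fits[seed] = ProgressivePermutation(
            random_state=seed, store_draws=False
        ).fit(X, y)
    return fits


@pytest.fixture(scope="session")
def simdata1_fits():
    """The mildly heterogeneous blocked design over ten replicate seeds."""
    fits = {}
    for seed in SIMDATA1_SEEDS:
        X, y = generate_preset("simdata1", seed=seed)
        fits[seed] = ProgressivePermutation(
            random_state=seed, store_draws=False
        ).fit(X, y)
    return fits


def top_features(fitted, n=50):
    """Indices of the n most significant features in the observed data."""
    return np.argsort(fitted.selection_.observed_p, kind="stable")[:n]
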