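import numpy as np
import pytest

from morphsense import BinnedData, PsychometricParams, eval_performance


@pytest.fixture
def true_params():
    """A well-behaved generating truth: threshold at 88 % dilution, slope 0.3."""
    return PsychometricParams(alpha=12.0, beta=0.3)


@pytest.fixture
def seven_levels():
    """Seven dilution levels spanning the fixture truth's threshold."""
    return np.array([76.0, 80.0, 84.0, 88.0, 90.0, 92.0, 94.0])


def expected_counts(params, dilutions, n_per_level):
    """Noiseless binned data: exact expected correct counts under the model."""
    d = np.asarray(dilutions, dtype=float)
    psi = np.asarray([eval_performance(100.0 - v, params) for v in d])
    n = np.full(d.size, float(n_per_level))
    return BinnedData(d, n, n * psi)


def binomial_counts(params, dilutions, n_per_level, rng):
    """Bernoulli-simulated binned data under the model."""
    d = np.asarray(dilutions, dtype=float)
    psi = np.asarray([eval_performance(100.0 - v, params) for v in d])
    n = np.full(d.size, int(n_per_level))
    k = rng.binomial(n, psi)
    return BinnedData(d, n.astype(float), k.astype(float))


@pytest.fixture
def noiseless_data(true_params, seven_levels):
    return expected_counts(true_params, seven_levels, 240)


@pytest.fixture
def sampled_data(true_params, seven_levels):
    rng = np.random.default_rng(20240915)
    return binomial_counts(true_params, seven_levels, 240, rng)
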