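import numpy as np
import pytest

from inputest import (
    InputFunction,
    NoiseModel,
    PosteriorSpec,
    eflornithine_system,
    kl_basis,
    linear_test_system,
    simulate,
)
from inputest.synthgen import draw_prior_function, linear_gaussian_oracle


class LinearGaussianSetup:
    """A linear one-compartment problem with a KL basis, its dataset and the
    closed-form posterior — the anchor for estimator and sampler tests."""

    def __init__(self, seed=42, n_basis=10, sigma=0.05, tau=2.0, n_obs=25):
        rng = np.random.default_rng(seed)
        self.system = linear_test_system(k=0.5, V=2.0)
        self.basis = kl_basis(1, n_basis, (0.0, 10.0), grid_size=200)
        self.times = np.linspace(0.5, 10.0, n_obs)
        self.truth = draw_prior_function(self.basis, 1.0, rng)
        _, out = simulate(self.system, self.truth, self.times)
        self.sigma = sigma
        self.tau = tau
        self.y = out[:, 0] + sigma * rng.standard_normal(n_obs)
        self.template = InputFunction(self.basis, np.zeros(self.basis.n_total))
        self.spec = PosteriorSpec(
            system=self.system,
            times=self.times,
            values=self.y,
            noise=NoiseModel("additive", sigma),
            input_template=self.template,
            penalty_order=1,
            tau=tau,
        )
        self.oracle = linear_gaussian_oracle(
            self.system, self.basis, self.times, self.y, sigma, tau
        )


@pytest.fixture(scope="session")
def linear_setup():
    return LinearGaussianSetup()


@pytest.fixture(scope="session")
def efl_system():
    return eflornithine_system()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
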