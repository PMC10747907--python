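import numpy as np
import pytest

from skinperm.core import ScalingSet, default_registry
from skinperm.datasets import build_group_datasets
from skinperm.inference import run_mcmc
from skinperm.mcmc import MCMCConfig
from skinperm.synthetic import SyntheticStudySpec, generate_study


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def b1_dataset():
    """First cross-over/varied-pH training data set (seeded assignment)."""
    return build_group_datasets("B", assignment_seed=7)[0]


@pytest.fixture(scope="session")
def synthetic_b():
    """Synthetic cross-over/varied-pH study with known truth (nu = 0.2)."""
    return generate_study(SyntheticStudySpec(design="B", nu=0.2, seed=12))


@pytest.fixture(scope="session")
def synthetic_b_draws(synthetic_b):
    """Short posterior fit of the synthetic study, shared across tests."""
    ds, _ = synthetic_b
    return run_mcmc(ds, config=MCMCConfig(n_iter=2500, n_chains=2, seed=9))


def random_scaling_set(rng: np.random.Generator) -> ScalingSet:
    """Uniform draw from the prior support (log-uniform for multiplicative)."""
    from skinperm.core import SCALING_SUPPORT

    draw = {}
    for name, (lo, hi) in SCALING_SUPPORT.items():
        if name in ScalingSet.MULTIPLICATIVE:
            draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            draw[name] = float(rng.uniform(lo, hi))
    return ScalingSet(**draw)
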