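import numpy as np
import pandas as pd
import pytest

from twinace import SimulationConfig, simulate_dataset
from twinace.twin_models import TwinData


@pytest.fixture(scope="session")
def default_dataset():
    """Default-shaped synthetic dataset (75 MZ / 170 DZ pairs, 7 singletons)."""
    return simulate_dataset(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    from twinace import simulate_cohort
    return simulate_cohort(SimulationConfig(
        n_mz_pairs=6, n_dz_pairs=8, n_singletons=2, n_traits=4, rng_seed=3))


def simulate_pairs(rng, n_mz, n_dz, a2, c2, n_singles=0):
    """Latent twin data directly from the bivariate normal implied by
    the variance decomposition: r_MZ = a2 + c2, r_DZ = a2/2 + c2."""
    def draw(n, r):
        cov = np.array([[1.0, r], [r, 1.0]])
        return rng.multivariate_normal([0.0, 0.0], cov, size=n)

    return TwinData(draw(n_mz, a2 + c2), draw(n_dz, 0.5 * a2 + c2),
                    rng.standard_normal(n_singles))
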