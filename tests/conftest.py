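import numpy as np
import pytest

import dietmetab as dm


@pytest.fixture(scope="session")
def small_config():
    """Reduced ion count keeps unit tests fast; structure is unchanged."""
    return dm.default_config(seed=11, n_ions=160)


@pytest.fixture(scope="session")
def cohort(small_config):
    cohort = dm.simulate_cohort(small_config)
    return dm.simulate_biomarkers(cohort, small_config)


@pytest.fixture(scope="session")
def matrix(cohort, small_config):
    return dm.simulate_metabolome(cohort, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pi_by_enumeration(x, y):
    """Independent oracle: count all n1*n2 pairs directly."""
    wins = ties = 0
    for xi in x:
        for yj in y:
            if xi > yj:
                wins += 1
            elif xi == yj:
                ties += 1
    return (wins + 0.5 * ties) / (len(x) * len(y))
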