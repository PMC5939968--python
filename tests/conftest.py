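import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conttest as ct

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def strong_case():
    """One strongly covarying synthetic case shared across tests."""
    return ct.make_case(L=60, N=300, rho=0.9, gap_rate=0.05, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_random_msa(rng, n_rows, width, gap_rate=0.1):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    probs = np.full(21, (1 - gap_rate) / 20)
    probs[-1] = gap_rate
    grid = rng.choice(letters, size=(n_rows, width), p=probs)
    rows = tuple(
        (f"r{k}", "".join(grid[k])) for k in range(n_rows)
    )
    return ct.Msa(rows)
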