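import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def ar1_chain(rng, phi, n, innovation_sd=1.0):
    """AR(1) chain with coefficient phi, used as a diagnostics fixture."""
    e = rng.standard_normal(n) * innovation_sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - phi**2)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + e[k]
    return x
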