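import numpy as np
import pytest

from lkmefit.distribution import LkmeParams


@pytest.fixture(scope="session")
def unit_params():
    """The KME-reduction point: alpha=beta=theta=1, lam=0."""
    return LkmeParams(1.0, 1.0, 1.0, 0.0)


@pytest.fixture(scope="session")
def random_param_vectors():
    """50 valid parameter vectors spanning the shapes the family supports."""
    rng = np.random.default_rng(20240917)
    out = []
    for _ in range(50):
        out.append(LkmeParams(
            alpha=float(np.exp(rng.uniform(np.log(0.4), np.log(6.0)))),
            beta=float(np.exp(rng.uniform(np.log(0.1), np.log(10.0)))),
            theta=float(np.exp(rng.uniform(np.log(0.2), np.log(5.0)))),
            lam=float(rng.uniform(0.0, 2.0)),
        ))
    return out


@pytest.fixture(scope="session")
def toy_sample():
    """Tiny fixed sample for brute-force objective arithmetic."""
    return np.array([0.5, 1.2, 2.0])
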