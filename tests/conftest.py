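import numpy as np
import pytest

from clawkit import synthetic, wham
from clawkit.constants import KB_KJ_PER_MOL_K

KT300 = KB_KJ_PER_MOL_K * 300.0

#: the canonical dissociation window schedule: 0.5 A spacing over the bound
#: region, 1.0 A over the plateau approach
SCHEDULE_SEGMENTS = [(15.0, 25.0, 0.5), (25.0, 38.0, 1.0)]


@pytest.fixture(scope="session")
def toy_complex():
    return synthetic.gen_toy_complex(synthetic.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def double_well():
    return synthetic.double_well_pmf()


@pytest.fixture(scope="session")
def umbrella_windows(double_well):
    """Moderate-size round-trip fixture shared across WHAM tests."""
    centers = wham.build_window_schedule(SCHEDULE_SEGMENTS)
    return synthetic.gen_umbrella_samples(
        double_well, centers, 2000, synthetic.GeneratorConfig(seed=11), kT=KT300
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
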