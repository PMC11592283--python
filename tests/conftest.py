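import numpy as np
import pytest

from pedplan.phantom import LevelGeometry, PhantomSpec, generate


@pytest.fixture(scope="session")
def default_phantom():
    """One L4 phantom at 1 mm isotropic spacing with analytic ground truth."""
    return generate(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def axis_aligned_phantom():
    """Phantom with PTA = PSA = 0: channels parallel to the y axis."""
    spec = PhantomSpec(
        levels={"L4": LevelGeometry(pta_deg=0.0, psa_deg=0.0)}, seed=7
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
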