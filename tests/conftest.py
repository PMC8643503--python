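import numpy as np
import pytest

from gratiokit.phantom import LesionSphere, PhantomSpec, make_ground_truth
from gratiokit.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom with one centred lesion; noiseless by default."""
    return PhantomSpec(
        grid_shape=(16, 16, 10),
        snr=np.inf,
        lesions=[LesionSphere((8.0, 8.0, 5.0), 2.5)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_ground_truth(small_spec)
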