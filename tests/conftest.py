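import numpy as np
import pytest

from mrct.phantom import PhantomSpec, generate_patient


@pytest.fixture(scope="session")
def noiseless_patient():
    return generate_patient(PhantomSpec(slices_per_patient=6).noiseless(), seed=11)


@pytest.fixture(scope="session")
def noisy_patient():
    return generate_patient(PhantomSpec(slices_per_patient=6), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
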