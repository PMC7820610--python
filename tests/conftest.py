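import numpy as np
import pytest

from headreg import PhantomSpec, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.random((12, 10, 8)), spacing=(1.0, 1.0, 2.0))


@pytest.fixture
def noise_free_spec():
    return PhantomSpec(noise_sd=(0.0, 0.0))


@pytest.fixture
def random_rigid_params(rng):
    from headreg import RegistrationParams

    def factory(max_angle=170.0, max_trans=20.0):
        return RegistrationParams(
            *rng.uniform(-max_angle, max_angle, 3), *rng.uniform(-max_trans, max_trans, 3)
        )

    return factory
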