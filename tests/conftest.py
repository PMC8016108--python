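import pytest

from follisim import FollicleParameters, compute_profiles


@pytest.fixture(scope="session")
def default_params():
    """The published rat-vibrissa parameter set."""
    return FollicleParameters()


@pytest.fixture(scope="session")
def default_profiles(default_params):
    """Deformation profiles of the default model, 201 samples."""
    return compute_profiles(default_params)
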