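import pytest

from ionclamp import build_default_model, find_rest
from ionclamp.channels import CHANNEL_KEYS, DEFAULT_MAGNITUDES


def subset_model(*keys, **kwargs):
    """Default model with every channel outside ``keys`` zeroed."""
    mags = {k: 0.0 for k in CHANNEL_KEYS}
    for k in keys:
        mags[k] = DEFAULT_MAGNITUDES[k]
    return build_default_model(magnitudes=mags, **kwargs)


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def default_rest(default_model):
    return find_rest(default_model)


@pytest.fixture(scope="session")
def na_k_leak_model():
    """Spiking subset: fast Na, delayed-rectifier K, both leaks."""
    return subset_model("na", "k", "k_leak", "na_leak")


@pytest.fixture(scope="session")
def na_k_leak_rest(na_k_leak_model):
    return find_rest(na_k_leak_model)
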