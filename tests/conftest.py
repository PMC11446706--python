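import dataclasses

import pytest

from musclemre.phantom import default_phantom_spec, make_labelmap


def noiseless(spec):
    """Strip every stochastic ingredient from a phantom spec."""
    return dataclasses.replace(
        spec,
        noise_sd=0.0,
        wave_noise_sd=0.0,
        oblique_fraction=0.0,
        stiffness_noise_kpa=0.0,
        outlier_fraction=0.0,
        invalid_fraction=0.0,
    )


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom_spec(seed=7)


@pytest.fixture(scope="session")
def clean_spec(default_spec):
    return noiseless(default_spec)


@pytest.fixture(scope="session")
def clean_labels(clean_spec):
    return make_labelmap(clean_spec)
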