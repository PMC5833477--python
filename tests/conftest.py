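import numpy as np
import pytest

from aldscreen.synth import FieldImageSpec, MixtureSpec, gen_nuclei_field


@pytest.fixture(scope="session")
def sparse_field():
    """A field of 50 well-separated nuclei with a known mixture, plus truth."""
    spec = FieldImageSpec(
        width=512, height=512, n_nuclei=50, min_separation_um=24.0,
        mixture=MixtureSpec(high_fraction=0.2, seed=11),
    )
    img, truth = gen_nuclei_field(spec)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
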