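import numpy as np
import pytest

from petiq.phantom import LesionSpec, PhantomSpec, build_phantom, generate_events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """One subject with a single 2 ml lesion and a desk-scale count level."""
    return PhantomSpec(
        liver_suv=1.57,
        lung_suv=0.5,
        lesions=(LesionSpec((14.0, 24.0, 16.0), 2.0, 3.0),),
        total_true_counts=500_000,
        subject_id="fix0",
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_stream(small_phantom):
    return generate_events(small_phantom, seed=777)
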