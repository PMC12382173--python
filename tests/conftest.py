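import numpy as np
import pytest

from washmap.phantom import (
    PhantomSpec,
    render_ancillary_maps,
    render_phantom,
    two_compartment_lesion,
)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, motion-free two-compartment phantom (64^3 @ 2 mm)."""
    lesion = two_compartment_lesion("L0", (18.0, 12.0, 8.0), 14.0, 12.0, separation_mm=30.0)
    spec = PhantomSpec(lesions=(lesion,), seed=11)
    early, late, truth = render_phantom(spec)
    return spec, early, late, truth


@pytest.fixture(scope="session")
def clean_ancillary(clean_phantom):
    spec, _, _, truth = clean_phantom
    return render_ancillary_maps(spec, truth, tumor_rcbv=3.0, tumor_adc=1.4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
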