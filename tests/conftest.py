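import numpy as np
import pytest

from slnfusion import (
    PhantomSpec,
    RigidTransform,
    build_phantom_labelmap,
    render_ct,
    render_spect,
)
from slnfusion.phantom import BoneArch, default_ct_model, default_spect_model


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact phantom for fast unit tests (same structure inventory as the default)."""
    return PhantomSpec(
        field_of_view=(110.0, 90.0, 80.0),
        sln_centers=((35.0, 52.0, 40.0), (78.0, 52.0, 40.0)),
        vessel_paths=[
            [(55.0, 18.0, 40.0), (55.0, 35.0, 40.0), (35.0, 52.0, 40.0)],
            [(55.0, 35.0, 40.0), (78.0, 52.0, 40.0)],
        ],
        vessel_radius=3.0,
        bone=BoneArch(center=(55.0, 48.0, 40.0), inner_radius=30.0, outer_radius=35.0, y_min=50.0, z_range=(22.0, 58.0)),
        fiducials=[
            (30.0, 25.0, 25.0),
            (82.0, 25.0, 25.0),
            (30.0, 25.0, 58.0),
            (82.0, 25.0, 58.0),
            (55.0, 18.0, 60.0),
        ],
        fiducial_radius=3.5,
    )


@pytest.fixture(scope="session")
def small_labelmap(small_spec):
    return build_phantom_labelmap(small_spec, 1.0)


@pytest.fixture(scope="session")
def default_labelmap_1mm():
    return build_phantom_labelmap(PhantomSpec(), 1.0)


@pytest.fixture(scope="session")
def ct_model():
    return default_ct_model()


@pytest.fixture(scope="session")
def noiseless_ct_model():
    return default_ct_model(noise_sigma=0.0)


@pytest.fixture(scope="session")
def spect_model():
    return default_spect_model()


@pytest.fixture(scope="session")
def small_ct_identity(small_labelmap, noiseless_ct_model):
    """Noiseless identity-pose CT render of the small phantom."""
    return render_ct(small_labelmap, noiseless_ct_model, RigidTransform.identity(), seed=0)


@pytest.fixture(scope="session")
def small_spect_identity(small_labelmap, spect_model):
    return render_spect(small_labelmap, spect_model, RigidTransform.identity(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
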