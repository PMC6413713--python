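import numpy as np
import pytest

from neuroperf.datamodel import REGIONS
from neuroperf.synth import AslTruth, CvrTruth, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced 16x16x4 phantom shared across tests."""
    anatomy, atlas = make_phantom(PhantomSpec.small())
    return anatomy, atlas


@pytest.fixture(scope="session")
def default_phantom():
    anatomy, atlas = make_phantom(PhantomSpec())
    return anatomy, atlas


@pytest.fixture()
def noiseless_asl_truth():
    cbf = {"cortex": 165.0, "hippocampus": 180.0, "thalamus": 200.0}
    return AslTruth({r: cbf.get(r, 150.0) for r in REGIONS}, noise_sigma=0.0)


@pytest.fixture()
def noiseless_cvr_truth():
    """Motor-cortex NTL response parameters applied uniformly."""
    return CvrTruth(
        cbv0={r: 0.51083 for r in REGIONS},
        slope_a={r: 0.061 for r in REGIONS},
        intercept_b={r: 2.178 for r in REGIONS},
        noise_sigma=0.0,
    )
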