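import numpy as np
import pytest

from olmtheta.channels import ModelParameters
from olmtheta.morphology import Morphology, Section


@pytest.fixture
def passive_sphere():
    """Single-compartment passive fixture: A = 10,000 µm², R_m = 60,000 Ω·cm².

    Analytic values: R_in = R_m/A = 600 MΩ, τ = R_m·C_m = 60 ms.
    """
    area = 10_000.0
    diam = 20.0
    soma = Section(
        id=0, parent_id=None, kind="soma",
        length=area / (np.pi * diam), diameter=diam, nseg=1,
    )
    morph = Morphology(sections=[soma])
    params = ModelParameters(
        rank=0, cell=1, h_dist="HS", densities={},
        r_m=60_000.0, c_m=1.0, i_bias=0.0,
    )
    return morph, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
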