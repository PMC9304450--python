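import math

import numpy as np
import pytest

from ataa.constitutive import HGOParams
from ataa.synthetic import gen_biaxial


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def truth_params():
    """A well-conditioned ground-truth material for recovery tests."""
    return HGOParams.from_degrees(c=1.0, k1=0.5, k2=2.0, kappa=0.15,
                                  gamma_deg=40.0)


@pytest.fixture(scope="session")
def mean_table_params():
    """Cohort-mean material parameters used in oracle evaluations."""
    return HGOParams.from_degrees(c=1.77, k1=0.43, k2=2.01, kappa=0.17,
                                  gamma_deg=44.95)


@pytest.fixture(scope="session")
def noiseless_biaxial(truth_params):
    sample, sidecar = gen_biaxial(truth_params, seed=7)
    return sample, sidecar


def random_hgo(rng) -> HGOParams:
    return HGOParams(
        c=float(rng.uniform(0.2, 3.0)),
        k1=float(rng.uniform(0.0, 2.0)),
        k2=float(rng.uniform(0.1, 5.0)),
        kappa=float(rng.uniform(0.0, 1.0 / 3.0)),
        gamma=float(rng.uniform(0.0, math.pi / 2)),
    )
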