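import dataclasses

import numpy as np
import pytest

from dilkit.core import ConvolutionGrid
from dilkit.synthetic import (Geometry, ctp_frame_schedule, default_ctp_aif_params,
                              default_pet_aif_params, dil_reference_ath,
                              dil_reference_f2tc, nondil_reference_ath,
                              nondil_reference_f2tc, pet_frame_schedule,
                              reference_class_specs)


@pytest.fixture(scope="session")
def pet_schedule():
    return pet_frame_schedule()


@pytest.fixture(scope="session")
def ctp_schedule():
    return ctp_frame_schedule()


@pytest.fixture(scope="session")
def pet_aif():
    return default_pet_aif_params()


@pytest.fixture(scope="session")
def ctp_aif():
    return default_ctp_aif_params()


@pytest.fixture(scope="session")
def pet_grid(pet_schedule, pet_aif):
    return ConvolutionGrid(pet_schedule, pet_aif, dt=0.5)


@pytest.fixture(scope="session")
def ctp_grid(ctp_schedule, ctp_aif):
    return ConvolutionGrid(ctp_schedule, ctp_aif, dt=0.2)


@pytest.fixture(scope="session")
def dil_f2tc():
    return dil_reference_f2tc()


@pytest.fixture(scope="session")
def nondil_f2tc():
    return nondil_reference_f2tc()


@pytest.fixture(scope="session")
def dil_ath():
    return dil_reference_ath()


@pytest.fixture(scope="session")
def nondil_ath():
    return nondil_reference_ath()


@pytest.fixture(scope="session")
def tiny_geometry():
    """~64-voxel prostate: keeps per-voxel fitting tests fast."""
    return Geometry().scaled(0.28)


@pytest.fixture(scope="session")
def noiseless_specs():
    """Reference class specs with voxel-level parameter jitter disabled."""
    dil, non = reference_class_specs(param_jitter=0.0)
    return dil, non


def random_f2tc_params(rng):
    """A random valid F2TC parameter vector inside the fitting bounds."""
    from dilkit.pet import F2TCParams
    f = rng.uniform(0.2, 1.5)
    return F2TCParams(
        F=f, W=rng.uniform(0.0, 25.0), K1=f * rng.uniform(0.1, 0.95),
        k2=rng.uniform(0.02, 1.5), k3=rng.uniform(0.0, 0.8),
        k4=rng.uniform(0.0, 0.8), t0=rng.uniform(0.0, 20.0))


def random_ath_params(rng):
    from dilkit.ctp import ATHParams
    return ATHParams(
        BF=rng.uniform(10.0, 150.0), Tc=rng.uniform(2.0, 20.0),
        E=rng.uniform(0.0, 0.8), Ve=rng.uniform(3.0, 40.0),
        t0=rng.uniform(0.0, 10.0))
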