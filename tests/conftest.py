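import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vsasl.model import AcquisitionTiming, PhysioConstants, TissueParams, model_curve

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

EXP1_LCTS = (0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0, 2.4, 2.9, 3.5)
EXP2_LCTS = (0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0)


@pytest.fixture(scope="session")
def consts():
    return PhysioConstants()


@pytest.fixture(scope="session")
def exp1_timing():
    return AcquisitionTiming(EXP1_LCTS)


@pytest.fixture(scope="session")
def exp2_timing():
    return AcquisitionTiming(EXP2_LCTS)


@pytest.fixture(scope="session")
def gm_truth():
    """Grey-matter-like parameter set used for round-trip fits."""
    return TissueParams(
        f=57.0 / 6000.0,
        bolus_duration=2.20,
        macro_bv=1.0e-3,
        macro_bolus_duration=1.22,
        m0=1000.0,
    )


def clean_series(params, timing, consts, slice_index=0):
    """Noise-free VoxelSeries from the forward model (generator as oracle)."""
    from vsasl.fitting import VoxelSeries

    dm = model_curve(params, timing, slice_index, consts)
    return VoxelSeries(
        dm_values=dm,
        lct_values=np.asarray(timing.lct_values),
        slice_index=slice_index,
        m0=params.m0,
    )
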