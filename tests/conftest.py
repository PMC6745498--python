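import numpy as np
import pytest

from placentaq.synthetic import CurveParams, ScanSchedule


@pytest.fixture
def schedule() -> ScanSchedule:
    return ScanSchedule(n_scans=25, scan_duration=163.0)


@pytest.fixture
def wt_params() -> CurveParams:
    """Wild-type-like noiseless curve parameters."""
    return CurveParams(
        baseline=100.0,
        uptake_amplitude=0.6,
        uptake_time=8.0,
        recovery_amplitude=0.5,
        recovery_onset=30.0,
        recovery_rate=0.2,
        noise_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)
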