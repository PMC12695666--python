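import numpy as np
import pytest

from loopx.extrusion import ExtrusionParams, build_ctcf_landscape
from loopx.synth import DistanceTimeSeries


@pytest.fixture
def convergent_sites():
    """Strong convergent CTCF pair flanking a 345-kb TAD in a 2.6-Mb region."""
    c = 1_300_000
    a, b = c - 172_500, c + 172_500
    peaks = [
        (a, "+", 3.0),
        (b, "-", 3.0),
        (a + 115_000, "-", 0.8),
        (b - 86_000, "+", 0.8),
        (a - 200_000, "-", 1.0),
        (b + 250_000, "+", 1.0),
        (a - 600_000, "+", 1.5),
        (b + 600_000, "-", 1.5),
    ]
    return build_ctcf_landscape(peaks, occupancy_target=0.5), a, b


@pytest.fixture
def quick_params():
    return ExtrusionParams(
        density=12.0, residence_time=5.0, motor_speed=1.0, region_length=1_000_000
    )


def make_series(
    distances,
    frame_interval=30.0,
    sigma_d=100.0,
    valid=None,
    condition="untreated",
):
    """Hand-built distance series for analysis-module tests."""
    d = np.asarray(distances, dtype=float)
    n = len(d)
    if valid is None:
        valid = np.isfinite(d)
    valid = np.asarray(valid, dtype=bool)
    sig = np.full(n, float(sigma_d)) if np.isscalar(sigma_d) else np.asarray(sigma_d, float)
    return DistanceTimeSeries(
        times=np.arange(n) * frame_interval,
        distance=np.where(valid, d, np.nan),
        sigma_d=sig,
        valid=valid,
        condition=condition,
    )


@pytest.fixture
def make_series_fn():
    return make_series
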