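import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvloop import BrachialBP, PVLoop, VolumeCurve
from pvloop.synthetic import make_volume_curve

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def bp_typical() -> BrachialBP:
    """A typical heart-failure brachial pressure (cohort-mean 122/65 mmHg)."""
    return BrachialBP(sbp=122.0, dbp=65.0)


@pytest.fixture
def vol_typical() -> VolumeCurve:
    """25-frame dilated-LV volume curve (EDV 336 mL, EF 28%, HR 70)."""
    return make_volume_curve(edv=336.0, ef=28.0, hr=70.0, t_es_frac=0.36)


def rectangle_loop(v_lo=100.0, v_hi=170.0, p_lo=10.0, p_hi=110.0) -> PVLoop:
    """Axis-aligned rectangular loop, counterclockwise, 25 points per side.

    Starts at (v_hi, p_lo) so that the top-left corner (v_lo, p_hi) — the
    maximal P/V vertex — is an exact sample.
    """
    v = np.concatenate([
        np.linspace(v_hi, v_lo, 26)[:-1],   # bottom edge, V decreasing
        np.full(25, v_lo),                  # left edge, P rising
        np.linspace(v_lo, v_hi, 26)[:-1],   # top edge, V increasing
        np.full(25, v_hi),                  # right edge, P falling
    ])
    p = np.concatenate([
        np.full(25, p_lo),
        np.linspace(p_lo, p_hi, 26)[:-1],
        np.full(25, p_hi),
        np.linspace(p_hi, p_lo, 26)[:-1],
    ])
    t = np.arange(100) / 100.0
    return PVLoop(t_grid=t, volumes=v, pressures=p, source="noninvasive")


@pytest.fixture
def rect_loop() -> PVLoop:
    return rectangle_loop()
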