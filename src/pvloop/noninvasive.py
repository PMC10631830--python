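"""Non-invasive PV loop assembly.

Combines a CMR volume curve, a brachial cuff pressure, and a user-estimated
end-diastolic pressure (default 7.5 mmHg) into a 100-point pressure-volume
loop via the time-varying elastance model: the normalized elastance is
warped so its downslope midpoint coincides with the end-systolic frame,
scaled in amplitude to match the estimated LV peak systolic pressure

    LVPsystole = (2*SBP + DBP) / 3

and the end-diastolic pressure, and multiplied with the volume curve
(``P(t) = E(t) * V(t)`` with ``V0 = 0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .elastance import ElastanceCurve, default_elastance, solve_amplitude, warp_to_end_systole
from .errors import InvalidBPError, PressureOrderingError
from .volumes import VolumeCurve, resample_volume_curve, summarize_volumes

__all__ = [
    "BrachialBP",
    "PVLoop",
    "peak_pressure_formula",
    "lvp_systole",
    "compute_noninvasive_loop",
    "LOOP_POINTS",
    "V0_ML",
]

logger = logging.getLogger(__name__)

#: Number of samples per PV loop.
LOOP_POINTS = 100

#: Volume-axis intercept of the ESPVR. Fixed to 0 mL (model simplification);
#: exposed for forward compatibility but the pipeline is only exercised at 0.
V0_ML = 0.0


@dataclass(frozen=True)
class BrachialBP:
    """Brachial cuff pressure pair in mmHg; requires SBP > DBP > 0."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise InvalidBPError(
                f"need SBP > DBP > 0, got {self.sbp}/{self.dbp} mmHg"
            )


def peak_pressure_formula(sbp: float, dbp: float) -> float:
    """Estimated LV peak systolic pressure, ``(2*SBP + DBP) / 3`` mmHg."""
    return (2.0 * sbp + dbp) / 3.0


def lvp_systole(bp: BrachialBP) -> float:
    """Estimated LV peak systolic pressure from a brachial pressure pair."""
    return peak_pressure_formula(bp.sbp, bp.dbp)


@dataclass(frozen=True)
class PVLoop:
    """A closed pressure-volume loop sampled at 100 cycle fractions.

    ``t_grid`` holds uniform cycle fractions in [0, 1); the loop closes by
    wrapping from the last sample back to the first. ``emax_index`` marks the
    maximal-elastance point, the sample maximizing ``P/V`` (V0 = 0).
    ``source`` records provenance: ``"noninvasive"`` (elastance model) or
    ``"invasive"`` (averaged catheter pressures).
    """

    t_grid: np.ndarray
    volumes: np.ndarray
    pressures: np.ndarray
    source: str
    emax_index: int = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        if not (len(t) == len(v) == len(p) == LOOP_POINTS):
            raise ValueError(f"PV loop must have exactly {LOOP_POINTS} points")
        if np.any(v <= 0):
            raise ValueError("loop volumes must be positive")
        if np.any(p < -1e-9):
            raise ValueError("loop pressures must be non-negative")
        p = np.maximum(p, 0.0)
        if self.source not in ("noninvasive", "invasive"):
            raise ValueError("source must be 'noninvasive' or 'invasive'")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "pressures", p)
        ratio = p / v
        # earliest index within floating-point tolerance of the max P/V
        i = int(np.argmax(ratio >= np.max(ratio) * (1.0 - 1e-12)))
        object.__setattr__(self, "emax_index", i)


def compute_noninvasive_loop(
    vol: VolumeCurve,
    bp: BrachialBP,
    edp: float = 7.5,
    elastance: ElastanceCurve | None = None,
) -> PVLoop:
    """Assemble the non-invasive PV loop.

    Pipeline: summarize the volume curve (EDV, end-systolic fraction) ->
    warp the normalized elastance to end systole -> resample volumes onto
    the 100-point loop grid (periodic cubic spline) -> scale the elastance
    amplitude to hit ``lvp_systole(bp)`` and ``edp`` -> multiply to obtain
    pressures. Amplitude scaling is performed directly on the delivered
    100-point grid, so the returned loop satisfies
    ``max(P) = (2*SBP + DBP)/3`` and ``P(end diastole) = edp`` to within the
    solver tolerance (0.01 mmHg).
    """
    if elastance is None:
        elastance = default_elastance()
    summary = summarize_volumes(vol)
    lvp = lvp_systole(bp)
    if lvp <= edp:
        raise PressureOrderingError(
            f"estimated LVPsystole ({lvp:.1f} mmHg) must exceed EDP ({edp} mmHg)"
        )
    warped = warp_to_end_systole(elastance, summary["t_es_frac"])
    vol100 = resample_volume_curve(vol, LOOP_POINTS)
    t_frac = vol100.frame_times / vol100.cycle_duration
    # evaluate warped elastance on the loop grid and scale there, so the
    # stated pressure anchors hold exactly on the delivered samples
    e_vals = warped(t_frac)
    e_offset, e_scale = solve_amplitude(e_vals, vol100.volumes, lvp, edp)
    pressures = (e_offset + e_scale * e_vals) * vol100.volumes
    loop = PVLoop(
        t_grid=t_frac, volumes=vol100.volumes, pressures=pressures,
        source="noninvasive",
    )
    _check_emax_band(loop, summary["t_es_frac"])
    return loop


def _check_emax_band(loop: PVLoop, t_es_frac: float) -> None:
    """Log (not fail) if Emax falls far from end systole.

    Sanity band: the maximal-elastance sample should lie within +/- 15% of
    the cycle around the minimal-volume time.
    """
    t_emax = loop.t_grid[min(loop.emax_index, len(loop.t_grid) - 1)]
    delta = abs(t_emax - t_es_frac)
    delta = min(delta, 1.0 - delta)  # cyclic distance
    if delta > 0.15:
        logger.warning(
            "Emax at cycle fraction %.3f is %.3f away from end systole (%.3f); "
            "check temporal scaling", t_emax, delta, t_es_frac,
        )
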