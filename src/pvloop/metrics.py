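"""Loop-derived haemodynamic metrics.

Seven indices are computed from any closed PV loop, identically for
non-invasive and invasive loops:

- SW, stroke work: area inscribed by the loop (mmHg*mL).
- ESPVR: slope from V0 (= 0 mL) to the Emax point, the loop sample where
  P/V is maximal (mmHg/mL) — a proxy for contractility.
- PE, potential energy: triangle between V0, ESV, and the ESPVR at ESV.
- PVA = SW + PE: total mechanical energy, a correlate of myocardial oxygen
  consumption.
- VE, ventricular efficiency: SW / PVA (dimensionless).
- Ea, arterial elastance: slope from the Emax point to (EDV, 0 mmHg) —
  effective afterload.
- MEP, mean external power: SW * HR / 60, reported in watts
  (1 mmHg*mL = 1.33322e-4 J) and in raw mmHg*mL/min.
- EPEV, energy per ejected volume: PVA / SV (mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, DegenerateLoopError
from .noninvasive import PVLoop

__all__ = [
    "PVMetrics",
    "stroke_work",
    "espvr_slope",
    "potential_energy",
    "arterial_elastance",
    "derived_metrics",
    "compute_all_metrics",
    "MMHG_ML_TO_JOULE",
]

#: Energy conversion: 1 mmHg*mL in joules.
MMHG_ML_TO_JOULE = 1.33322e-4

#: Metric fields compared between methods.
METRIC_NAMES = ("sw", "pe", "espvr", "ve", "ea", "mep", "epev")


@dataclass(frozen=True)
class PVMetrics:
    """Full metric set of one PV loop, with volumetric provenance."""

    sw: float            # mmHg*mL
    pe: float            # mmHg*mL
    pva: float           # mmHg*mL, == sw + pe by construction
    espvr: float         # mmHg/mL
    ea: float            # mmHg/mL
    ve: float            # fraction in (0, 1]
    mep: float           # W
    mep_mmhg_ml_per_min: float
    epev: float          # mmHg
    emax_pressure: float  # mmHg
    emax_volume: float    # mL
    edv: float           # mL
    esv: float           # mL
    sv: float            # mL
    hr: float            # bpm

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def stroke_work(loop: PVLoop) -> float:
    """Absolute shoelace (polygon) area of the closed (V, P) loop, mmHg*mL."""
    return _shoelace(loop.volumes, loop.pressures)


def _shoelace(v: np.ndarray, p: np.ndarray) -> float:
    vertices = np.unique(np.column_stack([v, p]), axis=0)
    if len(vertices) < 3:
        raise DegenerateLoopError("loop has fewer than 3 distinct vertices")
    v2 = np.roll(v, -1)
    p2 = np.roll(p, -1)
    return float(abs(0.5 * np.sum(v * p2 - v2 * p)))


def espvr_slope(loop: PVLoop) -> dict:
    """Emax point and the ESPVR slope through V0 = 0.

    The Emax sample maximizes P/V (ties broken by the earliest index);
    ``espvr = emax_pressure / emax_volume``.
    """
    v = loop.volumes
    p = loop.pressures
    if np.any(v <= 0):
        raise DegenerateGeometryError("all volumes must be positive")
    ratio = p / v
    # earliest index within floating-point tolerance of the maximum, so
    # constant-ratio loops tie-break deterministically to the first sample
    i = int(np.argmax(ratio >= np.max(ratio) * (1.0 - 1e-12)))
    return {
        "espvr": float(p[i] / v[i]),
        "emax_pressure": float(p[i]),
        "emax_volume": float(v[i]),
        "emax_index": i,
    }


def potential_energy(espvr: float, esv: float) -> float:
    """Triangle area between V0, ESV and the ESPVR at ESV: 0.5*ESV*(ESPVR*ESV)."""
    if espvr < 0 or esv < 0:
        raise DegenerateGeometryError("espvr and esv must be non-negative")
    return 0.5 * esv * (espvr * esv)


def arterial_elastance(loop: PVLoop) -> float:
    """Slope from the Emax point down to (EDV, 0 mmHg), mmHg/mL."""
    emax = espvr_slope(loop)
    edv = float(np.max(loop.volumes))
    if edv <= emax["emax_volume"]:
        raise DegenerateGeometryError(
            "EDV must exceed the Emax volume to define the afterload slope"
        )
    return emax["emax_pressure"] / (edv - emax["emax_volume"])


def derived_metrics(sw: float, pe: float, sv: float, hr: float) -> dict:
    """VE, MEP and EPEV from stroke work, potential energy, SV and HR."""
    if sw <= 0 or pe < 0:
        raise DegenerateGeometryError("need sw > 0 and pe >= 0")
    if sv <= 0 or hr <= 0:
        raise DegenerateGeometryError("need sv > 0 and hr > 0")
    pva = sw + pe
    mep_raw = sw * hr / 60.0  # mmHg*mL/s
    return {
        "ve": sw / pva,
        "mep": mep_raw * MMHG_ML_TO_JOULE,  # W (J/s)
        "mep_mmhg_ml_per_min": sw * hr,
        "epev": pva / sv,
    }


def compute_all_metrics(loop: PVLoop, hr: float) -> PVMetrics:
    """Compose the full metric set for one loop; enforces PVA = SW + PE."""
    sw = stroke_work(loop)
    emax = espvr_slope(loop)
    edv = float(np.max(loop.volumes))
    esv = float(np.min(loop.volumes))
    sv = edv - esv
    pe = potential_energy(emax["espvr"], esv)
    ea = arterial_elastance(loop)
    d = derived_metrics(sw, pe, sv, hr)
    return PVMetrics(
        sw=sw,
        pe=pe,
        pva=sw + pe,
        espvr=emax["espvr"],
        ea=ea,
        ve=d["ve"],
        mep=d["mep"],
        mep_mmhg_ml_per_min=d["mep_mmhg_ml_per_min"],
        epev=d["epev"],
        emax_pressure=emax["emax_pressure"],
        emax_volume=emax["emax_volume"],
        edv=edv,
        esv=esv,
        sv=sv,
        hr=hr,
    )
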