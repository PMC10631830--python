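"""Normalized time-varying elastance and its patient-specific scaling.

The ventricle is modelled as a time-varying elastance ``E(t)``: instantaneous
chamber stiffness referenced to the zero-pressure volume ``V0`` (fixed to
0 mL here), so that ``P(t) = E(t) * V(t)``. The normalized shape ``E_N`` is
a population-average curve on normalized cycle time; per subject it is

1. warped in time so that the middle of its downslope coincides with the
   end-systolic (minimal-volume) frame of that subject's CMR cycle, and
2. scaled in amplitude so the modelled pressure matches the estimated LV
   peak systolic pressure and the end-diastolic pressure.

The packaged default shape is a double-Hill product

    E_N(x) = k * [(x/t1)^n1 / (1 + (x/t1)^n1)] * [1 / (1 + (x/t2)^n2)]

with t1 = 0.269, n1 = 1.32, t2 = 0.452, n2 = 21.9 on cycle fraction x,
renormalized to unit peak — a widely used normalized human elastance
approximation. It ships as a CSV data asset so that a user-digitized curve
can be dropped in without code changes (see :func:`read_elastance_csv`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConvergenceError, PressureOrderingError
from .volumes import VolumeCurve

__all__ = [
    "ElastanceCurve",
    "ScaledElastance",
    "default_elastance",
    "warp_to_end_systole",
    "scale_amplitude",
    "solve_amplitude",
    "double_hill",
    "read_elastance_csv",
]

# Double-Hill shape parameters (activation / relaxation), cycle-fraction units.
DOUBLE_HILL_PARAMS = {"tau1": 0.269, "n1": 1.32, "tau2": 0.452, "n2": 21.9}


def double_hill(x: np.ndarray, tau1: float = 0.269, n1: float = 1.32,
                tau2: float = 0.452, n2: float = 21.9) -> np.ndarray:
    """Un-normalized double-Hill elastance shape on cycle fraction x."""
    x = np.asarray(x, dtype=float)
    rise = (x / tau1) ** n1
    return (rise / (1.0 + rise)) / (1.0 + (x / tau2) ** n2)


def _downslope_half_frac(t: np.ndarray, e: np.ndarray) -> float:
    """Cycle fraction where e first falls to half its peak on the descent.

    Linear interpolation between the bracketing samples; the curve must be
    unimodal with unit peak.
    """
    i_pk = int(np.argmax(e))
    half = 0.5 * e[i_pk]
    below = np.nonzero(e[i_pk:] <= half)[0]
    if len(below) == 0:
        raise ValueError("elastance never falls to half peak after the maximum")
    j = i_pk + below[0]
    # interpolate the crossing between samples j-1 and j
    e0, e1 = e[j - 1], e[j]
    t0, t1 = t[j - 1], t[j]
    if e0 == e1:
        return float(t1)
    return float(t0 + (e0 - half) / (e0 - e1) * (t1 - t0))


@dataclass(frozen=True)
class ElastanceCurve:
    """Normalized elastance shape on the normalized cycle [0, 1].

    ``e_norm`` has unit maximum, starts near zero, and is unimodal (single
    dominant peak). ``downslope_half_frac`` marks the middle of the
    downslope: the cycle fraction where the curve first falls to half its
    peak on the descent — the landmark aligned with end systole.
    """

    t_norm: np.ndarray
    e_norm: np.ndarray
    downslope_half_frac: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_norm, dtype=float)
        e = np.asarray(self.e_norm, dtype=float)
        object.__setattr__(self, "t_norm", t)
        object.__setattr__(self, "e_norm", e)
        if t.ndim != 1 or e.ndim != 1 or len(t) != len(e):
            raise ValueError("t_norm and e_norm must be 1-D of equal length")
        if len(t) < 16:
            raise ValueError("elastance curve needs at least 16 samples")
        if t[0] != 0.0 or abs(t[-1] - 1.0) > 1e-12 or np.any(np.diff(t) <= 0):
            raise ValueError("t_norm must increase strictly from 0 to 1")
        if abs(np.max(e) - 1.0) > 1e-9:
            raise ValueError("e_norm must be normalized to unit maximum")
        if e[0] >= 0.05:
            raise ValueError("e_norm must start below 0.05")
        if np.any(e < -1e-12):
            raise ValueError("e_norm must be non-negative")
        i_pk = int(np.argmax(e))
        if np.any(np.diff(e[: i_pk + 1]) < -1e-6) or np.any(np.diff(e[i_pk:]) > 1e-6):
            raise ValueError("e_norm must have a single dominant peak")
        dhf = _downslope_half_frac(t, e)
        object.__setattr__(self, "downslope_half_frac", dhf)
        if not (0.0 < t[i_pk] < dhf < 1.0):
            raise ValueError("need 0 < peak fraction < downslope_half_frac < 1")

    @property
    def peak_frac(self) -> float:
        """Cycle fraction of the elastance maximum."""
        return float(self.t_norm[int(np.argmax(self.e_norm))])

    @classmethod
    def from_samples(cls, t_norm, e_norm) -> "ElastanceCurve":
        """Build from raw samples, renormalizing the peak to 1."""
        e = np.asarray(e_norm, dtype=float)
        return cls(t_norm=np.asarray(t_norm, dtype=float), e_norm=e / np.max(e))

    def __call__(self, frac: np.ndarray) -> np.ndarray:
        """Evaluate by linear interpolation at cycle fractions in [0, 1]."""
        return np.interp(np.asarray(frac, dtype=float), self.t_norm, self.e_norm)


@dataclass(frozen=True)
class ScaledElastance:
    """Absolute elastance over one cycle: ``e_abs = e_offset + e_scale * E_N``.

    ``t_grid`` is in seconds; ``e_abs`` in mmHg/mL. ``e_offset`` anchors the
    end-diastolic pressure, ``e_scale`` is the amplitude multiplier solved so
    the modelled peak pressure matches the target.
    """

    t_grid: np.ndarray
    e_abs: np.ndarray
    e_offset: float
    e_scale: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.e_abs) < 0):
            raise ValueError("absolute elastance must be non-negative")


_DEFAULT_CACHE: ElastanceCurve | None = None


def read_elastance_csv(path) -> ElastanceCurve:
    """Read a normalized elastance curve (columns ``t_norm, e_norm``)."""
    df = pd.read_csv(Path(path))
    if not {"t_norm", "e_norm"}.issubset(df.columns):
        raise ValueError("elastance CSV must have t_norm and e_norm columns")
    return ElastanceCurve.from_samples(
        df["t_norm"].to_numpy(float), df["e_norm"].to_numpy(float)
    )


def default_elastance() -> ElastanceCurve:
    """The packaged default normalized elastance curve (501 samples)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        with resources.as_file(
            resources.files("pvloop.data") / "default_elastance.csv"
        ) as p:
            _DEFAULT_CACHE = read_elastance_csv(p)
    return _DEFAULT_CACHE


def warp_to_end_systole(curve: ElastanceCurve, t_es_frac: float) -> ElastanceCurve:
    """Warp the time axis so the downslope midpoint lands on end systole.

    A piecewise-linear bijection of [0, 1] maps ``[0, downslope_half_frac]``
    onto ``[0, t_es_frac]`` and ``[downslope_half_frac, 1]`` onto
    ``[t_es_frac, 1]``; the warped curve is resampled onto the original
    uniform grid. Endpoint values are preserved exactly.
    """
    if not (0.0 < t_es_frac < 1.0):
        raise ValueError("t_es_frac must lie strictly inside (0, 1)")
    d = curve.downslope_half_frac
    t = curve.t_norm
    # inverse map: warped time t -> native time x
    x = np.where(
        t <= t_es_frac,
        t * d / t_es_frac,
        d + (t - t_es_frac) * (1.0 - d) / (1.0 - t_es_frac),
    )
    e_w = np.interp(x, t, curve.e_norm)
    return ElastanceCurve.from_samples(t, e_w)


def scale_amplitude(
    curve: ElastanceCurve,
    vol: VolumeCurve,
    lvp_sys: float,
    edp: float,
    peak_tol_mmhg: float = 1e-4,
    max_iter: int = 200,
) -> ScaledElastance:
    """Scale a (warped) elastance so modelled pressures hit EDP and LVPsys.

    The affine scaling ``e_abs(t) = e_offset + e_scale * e_norm(t)`` is
    anchored at end diastole: ``e_offset = EDP / EDV`` makes ``P = EDP``
    where the volume is maximal and the normalized elastance is ~0. The
    amplitude ``e_scale`` is then solved by bisection so that
    ``max_t e_abs(t) * V(t) = lvp_sys`` within ``peak_tol_mmhg``; the peak
    pressure is strictly increasing in ``e_scale``, so the bisection always
    converges.

    ``vol`` must already be resampled onto the elastance grid (same number
    of samples, same cycle fractions).
    """
    v = vol.volumes
    if len(v) != len(curve.e_norm):
        raise ValueError("volume curve must be resampled onto the elastance grid")
    e_offset, e_scale = solve_amplitude(
        curve.e_norm, v, lvp_sys, edp, peak_tol_mmhg=peak_tol_mmhg, max_iter=max_iter
    )
    e_abs = e_offset + e_scale * curve.e_norm
    return ScaledElastance(
        t_grid=vol.frame_times, e_abs=e_abs, e_offset=e_offset, e_scale=e_scale
    )


def solve_amplitude(
    e_norm: np.ndarray,
    volumes: np.ndarray,
    lvp_sys: float,
    edp: float,
    peak_tol_mmhg: float = 1e-4,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Solve the affine amplitude scaling on matched sample grids.

    Returns ``(e_offset, e_scale)`` such that
    ``max((e_offset + e_scale * e_norm) * volumes) = lvp_sys`` within
    ``peak_tol_mmhg`` and ``e_offset = edp / max(volumes)``. See
    :func:`scale_amplitude` for the model rationale.
    """
    if lvp_sys <= edp:
        raise PressureOrderingError(
            f"peak systolic pressure ({lvp_sys}) must exceed EDP ({edp})"
        )
    if edp <= 0:
        raise PressureOrderingError("EDP must be positive")
    e_n = np.asarray(e_norm, dtype=float)
    v = np.asarray(volumes, dtype=float)
    edv = float(np.max(v))
    esv = float(np.min(v))
    e_offset = edp / edv

    def peak(scale: float) -> float:
        return float(np.max((e_offset + scale * e_n) * v))

    lo, hi = 0.0, 10.0 * lvp_sys / esv
    if peak(hi) < lvp_sys:  # pragma: no cover - bracket is generous by design
        raise ConvergenceError("bisection bracket does not contain the target peak")
    for _ in range(max_iter):
        scale = 0.5 * (lo + hi)
        p = peak(scale)
        if abs(p - lvp_sys) <= peak_tol_mmhg:
            return e_offset, scale
        if p < lvp_sys:
            lo = scale
        else:
            hi = scale
    raise ConvergenceError(
        f"amplitude bisection did not converge in {max_iter} iterations"
    )
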