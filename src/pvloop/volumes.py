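"""Time-resolved left-ventricular volume curves.

A :class:`VolumeCurve` holds cavity volume over one cardiac cycle as
segmented from short-axis cine CMR (typically 25 frames, retrospectively
gated so that frame 0 is the R-wave, i.e. end diastole). Both the
non-invasive elastance pipeline and the invasive reference pipeline consume
this representation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DegenerateCurveError

__all__ = [
    "VolumeCurve",
    "summarize_volumes",
    "resample_volume_curve",
    "read_volume_csv",
    "write_volume_csv",
]


@dataclass(frozen=True)
class VolumeCurve:
    """LV cavity volume over one cardiac cycle.

    Parameters
    ----------
    frame_times : array-like
        Seconds from the R-wave; strictly increasing, first element 0,
        all within ``[0, cycle_duration)``.
    volumes : array-like
        Cavity volume in mL, one per frame, all positive. At least 8 frames.
    heart_rate : float
        Beats per minute; defines ``cycle_duration = 60 / heart_rate``.
    """

    frame_times: np.ndarray
    volumes: np.ndarray
    heart_rate: float
    ed_frame_index: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "volumes", v)
        if ft.ndim != 1 or v.ndim != 1 or len(ft) != len(v):
            raise ValueError("frame_times and volumes must be 1-D of equal length")
        if len(v) < 8:
            raise ValueError(f"need at least 8 frames, got {len(v)}")
        if not np.all(np.isfinite(ft)) or not np.all(np.isfinite(v)):
            raise ValueError("frame_times and volumes must be finite")
        if np.any(v <= 0):
            raise ValueError("all volumes must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if ft[0] != 0.0:
            raise ValueError("first frame time must be 0 (R-wave)")
        if np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if ft[-1] >= self.cycle_duration:
            raise ValueError("frame_times must lie within [0, cycle_duration)")
        ed = int(np.argmax(v))
        object.__setattr__(self, "ed_frame_index", ed)
        # tolerate interpolation ripple: only warn when the maximum clearly
        # exceeds the frame-0 volume
        if ed != 0 and v[ed] > v[0] * (1.0 + 1e-3):
            warnings.warn(
                f"maximal volume (EDV) found at frame {ed}, not frame 0; "
                "acquisition may not be end-diastole gated",
                stacklevel=3,
            )

    @property
    def cycle_duration(self) -> float:
        """Cycle length in seconds (= 60 / heart rate)."""
        return 60.0 / self.heart_rate

    def __len__(self) -> int:
        return len(self.volumes)

    @classmethod
    def from_frames(cls, volumes, heart_rate: float) -> "VolumeCurve":
        """Build a curve from per-frame volumes with implicit uniform timing.

        Frame *k* of *n* is placed at ``k * cycle_duration / n``; frame 0 is
        the R-wave (end diastole) by convention.
        """
        if heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        v = np.asarray(volumes, dtype=float)
        n = len(v)
        t = np.arange(n) * (60.0 / heart_rate) / n
        return cls(frame_times=t, volumes=v, heart_rate=heart_rate)


def summarize_volumes(curve: VolumeCurve) -> dict:
    """Global volumetric indices of one cycle.

    Returns a dict with EDV and ESV (mL), stroke volume ``SV = EDV - ESV``
    (mL), ejection fraction ``EF = 100 * SV / EDV`` (%), and ``t_es_frac``,
    the cycle fraction of the minimal-volume (end-systolic) frame. Ties on
    the minimum are broken by the earliest frame.

    Raises
    ------
    DegenerateCurveError
        If the curve is constant (EDV == ESV), which implies SV = 0 and
        breaks every downstream loop metric.
    """
    v = curve.volumes
    edv = float(np.max(v))
    esv = float(np.min(v))
    if edv == esv:
        raise DegenerateCurveError("constant volume curve: EDV == ESV, SV = 0")
    i_es = int(np.argmin(v))  # argmin returns the earliest index on ties
    return {
        "EDV": edv,
        "ESV": esv,
        "SV": edv - esv,
        "EF": 100.0 * (edv - esv) / edv,
        "t_es_frac": float(curve.frame_times[i_es] / curve.cycle_duration),
    }


def _periodic_spline(curve: VolumeCurve) -> CubicSpline:
    # close the cycle: V(T) = V(0), so retrospective gating wraps smoothly
    t = np.append(curve.frame_times, curve.cycle_duration)
    v = np.append(curve.volumes, curve.volumes[0])
    return CubicSpline(t, v, bc_type="periodic")


def resample_volume_curve(curve: VolumeCurve, n_points: int) -> VolumeCurve:
    """Resample onto ``n_points`` uniform times via a periodic cubic spline.

    The cycle is treated as closed (``V(T) = V(0)``), matching retrospective
    ECG gating. Requires ``n_points >= len(curve)`` so no information is
    discarded.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if n_points < len(curve):
        raise ValueError(
            f"n_points ({n_points}) must be >= number of frames ({len(curve)})"
        )
    spline = _periodic_spline(curve)
    t_new = np.arange(n_points) * curve.cycle_duration / n_points
    v_new = spline(t_new)
    return VolumeCurve(frame_times=t_new, volumes=v_new, heart_rate=curve.heart_rate)


def volume_at_fraction(curve: VolumeCurve, frac: np.ndarray) -> np.ndarray:
    """Evaluate the periodic spline at arbitrary cycle fractions in [0, 1)."""
    spline = _periodic_spline(curve)
    return spline(np.asarray(frac, dtype=float) * curve.cycle_duration)


def read_volume_csv(path, heart_rate: float | None = None) -> VolumeCurve:
    """Read a volume curve from CSV.

    Accepts either a ``time_s`` column (seconds from R-wave) or a ``frame``
    column (frame indices mapped to uniform times), plus ``volume_ml``.
    The heart rate is taken from, in order of precedence: the
    ``heart_rate`` argument, a sidecar JSON file ``<path>.json`` with key
    ``heart_rate_bpm``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if heart_rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                "heart_rate not given and sidecar JSON "
                f"{sidecar.name} not found"
            )
        heart_rate = float(json.loads(sidecar.read_text())["heart_rate_bpm"])
    if "volume_ml" not in df.columns:
        raise ValueError("CSV must have a volume_ml column")
    v = df["volume_ml"].to_numpy(dtype=float)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        return VolumeCurve(frame_times=t, volumes=v, heart_rate=heart_rate)
    if "frame" in df.columns:
        return VolumeCurve.from_frames(v, heart_rate)
    raise ValueError("CSV must have a time_s or frame column")


def write_volume_csv(curve: VolumeCurve, path) -> None:
    """Write ``time_s, volume_ml`` CSV plus a sidecar JSON with heart rate."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": curve.frame_times, "volume_ml": curve.volumes}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"heart_rate_bpm": curve.heart_rate}))
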