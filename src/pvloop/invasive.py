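"""Invasive catheter-pressure reference pipeline.

Raw LV pressure recordings (nominally 250 Hz, about one minute) are
low-pass filtered at 10 Hz, corrected for the offset observed at catheter
withdrawal, segmented into beats, cleaned of ectopic beats (the ectopic and
both neighbours are discarded; frequent ectopy rejects the recording),
averaged into a 250-point representative beat, and finally paired with the
CMR volume curve to form the reference PV loop. An optional
conductance-volume channel can be linearly calibrated so its maximum equals
the CMR end-diastolic volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ChannelError, FrequentEctopyError, SegmentationError
from .noninvasive import LOOP_POINTS, PVLoop
from .volumes import VolumeCurve, resample_volume_curve

__all__ = [
    "CatheterRecording",
    "BeatSet",
    "AveragedBeat",
    "lowpass_filter",
    "correct_offset",
    "segment_beats",
    "flag_ectopy",
    "average_beats",
    "calibrate_conductance",
    "build_reference_loop",
    "AVG_BEAT_POINTS",
]

#: Samples per averaged representative beat.
AVG_BEAT_POINTS = 250


@dataclass(frozen=True)
class CatheterRecording:
    """Multi-beat LV pressure trace, optionally with a conductance channel.

    ``withdrawal_offset`` is the pressure registered at catheter withdrawal
    from the artery; :func:`correct_offset` subtracts it.
    """

    sample_rate: float
    pressure: np.ndarray
    conductance_volume: np.ndarray | None = None
    withdrawal_offset: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "pressure", p)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("pressure must be a 1-D sample sequence")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressure samples must be finite")
        if self.conductance_volume is not None:
            c = np.asarray(self.conductance_volume, dtype=float)
            if len(c) != len(p):
                raise ValueError("channel lengths differ")
            object.__setattr__(self, "conductance_volume", c)

    @property
    def duration(self) -> float:
        return len(self.pressure) / self.sample_rate


@dataclass(frozen=True)
class BeatSet:
    """Beat segmentation of a recording.

    ``beat_boundaries`` holds (start, end) sample-index pairs of complete
    beats (end exclusive, equal to the next onset); ``rr_intervals`` the
    matching cycle lengths in seconds. ``ectopic_flags`` and
    ``retained_indices`` are populated by :func:`flag_ectopy`; before that
    every beat is retained.
    """

    beat_boundaries: tuple
    rr_intervals: np.ndarray
    ectopic_flags: np.ndarray
    retained_indices: tuple

    def __post_init__(self) -> None:
        b = tuple(tuple(pair) for pair in self.beat_boundaries)
        object.__setattr__(self, "beat_boundaries", b)
        object.__setattr__(
            self, "rr_intervals", np.asarray(self.rr_intervals, dtype=float)
        )
        object.__setattr__(
            self, "ectopic_flags", np.asarray(self.ectopic_flags, dtype=bool)
        )
        object.__setattr__(self, "retained_indices", tuple(self.retained_indices))
        for (s0, e0), (s1, _) in zip(b, b[1:]):
            if not (s0 < e0 <= s1):
                raise ValueError("beat boundaries must be ordered and non-overlapping")

    @property
    def n_beats(self) -> int:
        return len(self.beat_boundaries)


@dataclass(frozen=True)
class AveragedBeat:
    """Pointwise-average beat on a normalized [0, 1] beat-time axis."""

    pressures: np.ndarray
    n_beats_averaged: int
    peak_sd: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "pressures", p)
        if len(p) != AVG_BEAT_POINTS:
            raise ValueError(f"averaged beat must have {AVG_BEAT_POINTS} points")
        if self.n_beats_averaged < 1:
            raise ValueError("need at least one averaged beat")


def lowpass_filter(rec: CatheterRecording, cutoff: float = 10.0) -> CatheterRecording:
    """Zero-phase low-pass filter (2nd-order Butterworth, forward-backward).

    DC gain is 1; the effective 4th-order magnitude response attenuates a
    tone at twice the cutoff by more than 20 dB. Both channels are filtered.
    """
    nyq = rec.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff ({cutoff} Hz) must be below Nyquist ({nyq} Hz)")
    b, a = butter(2, cutoff, fs=rec.sample_rate)
    p = filtfilt(b, a, rec.pressure)
    c = rec.conductance_volume
    if c is not None:
        c = filtfilt(b, a, c)
    return replace(rec, pressure=p, conductance_volume=c)


def correct_offset(rec: CatheterRecording) -> CatheterRecording:
    """Subtract the withdrawal offset from every pressure sample."""
    return replace(
        rec, pressure=rec.pressure - rec.withdrawal_offset, withdrawal_offset=0.0
    )


def segment_beats(
    rec: CatheterRecording,
    min_upstroke_fraction: float = 0.5,
    foot_fraction: float = 0.02,
) -> BeatSet:
    """Detect beat onsets at the diastolic foot of each systolic upstroke.

    Upstrokes are located as prominent peaks of dP/dt (at least
    ``min_upstroke_fraction`` of the global maximum, separated by >= 0.3 s).
    The onset of each beat — the diastolic foot just before isovolumic
    contraction — is then found by the intersecting-tangent construction:
    the tangent at the dP/dt maximum is extended down to the diastolic
    pressure level (the last sample before the upstroke where dP/dt is
    below ``foot_fraction`` of its peak), and the intersection gives the
    onset. Complete beats span consecutive onsets.
    """
    p = rec.pressure
    fs = rec.sample_rate
    if np.ptp(p) < 1.0:
        raise SegmentationError("trace is (near-)constant; no beats detectable")
    dp = np.gradient(p) * fs
    peaks, _ = find_peaks(
        dp,
        height=min_upstroke_fraction * np.max(dp),
        distance=max(1, int(0.3 * fs)),
    )
    if len(peaks) < 2:
        raise SegmentationError("fewer than two upstrokes detected")
    gap = np.median(np.diff(peaks))
    onsets = []
    for pk in peaks:
        lo = max(0, pk - int(0.6 * gap))
        below = np.nonzero(dp[lo:pk] <= foot_fraction * dp[pk])[0]
        if len(below) == 0:
            continue  # upstroke truncated at the start of the recording
        foot = lo + below[-1]
        # intersecting tangent: project the max-slope tangent down to the
        # diastolic baseline pressure at the foot
        onset = pk - (p[pk] - p[foot]) / dp[pk] * fs
        onsets.append(int(np.clip(round(onset), lo, pk)))
    if len(onsets) < 2:
        raise SegmentationError("fewer than two beat onsets resolved")
    onsets = np.asarray(onsets)
    boundaries = tuple(
        (int(s), int(e)) for s, e in zip(onsets[:-1], onsets[1:])
    )
    rr = np.diff(onsets) / fs
    n = len(boundaries)
    return BeatSet(
        beat_boundaries=boundaries,
        rr_intervals=rr,
        ectopic_flags=np.zeros(n, dtype=bool),
        retained_indices=tuple(range(n)),
    )


def flag_ectopy(
    beats: BeatSet,
    rr_tolerance: float = 0.20,
    max_ectopic_fraction: float = 0.25,
) -> BeatSet:
    """Flag ectopic beats by RR deviation and drop them with both neighbours.

    A beat whose RR interval deviates from the median by more than
    ``rr_tolerance`` (fraction of the median) is ectopic; the ectopic beat
    and its immediate neighbours are removed from ``retained_indices``. If
    more than ``max_ectopic_fraction`` of beats are ectopic the recording is
    rejected outright (:class:`FrequentEctopyError`), mirroring the
    exclusion of high-ectopic-burden studies.
    """
    if beats.n_beats < 3:
        raise ValueError("need at least 3 beats to assess ectopy")
    rr = beats.rr_intervals
    med = float(np.median(rr))
    flags = np.abs(rr - med) / med > rr_tolerance
    frac = float(np.mean(flags))
    if frac > max_ectopic_fraction:
        raise FrequentEctopyError(
            f"{frac:.0%} of beats ectopic exceeds {max_ectopic_fraction:.0%}; "
            "recording must be excluded"
        )
    drop = set()
    for i in np.nonzero(flags)[0]:
        drop.update({i - 1, i, i + 1})
    retained = tuple(i for i in range(beats.n_beats) if i not in drop)
    return replace(beats, ectopic_flags=flags, retained_indices=retained)


def average_beats(rec: CatheterRecording, beats: BeatSet) -> AveragedBeat:
    """Average the retained beats on a normalized 250-point time axis.

    Each retained beat is linearly resampled to 250 points on [0, 1] of its
    own duration, then the beats are averaged pointwise. ``peak_sd`` is the
    sample SD of the per-beat peak pressures (beat-to-beat variability).
    """
    if len(beats.retained_indices) == 0:
        raise ValueError("no retained beats to average")
    x_new = np.linspace(0.0, 1.0, AVG_BEAT_POINTS, endpoint=False)
    resampled = []
    peaks = []
    for i in beats.retained_indices:
        s, e = beats.beat_boundaries[i]
        seg = rec.pressure[s:e]
        x_old = np.linspace(0.0, 1.0, len(seg), endpoint=False)
        resampled.append(np.interp(x_new, x_old, seg))
        peaks.append(np.max(seg))
    stack = np.vstack(resampled)
    peak_sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    return AveragedBeat(
        pressures=stack.mean(axis=0),
        n_beats_averaged=len(resampled),
        peak_sd=peak_sd,
    )


def calibrate_conductance(rec: CatheterRecording, cmr_edv: float) -> CatheterRecording:
    """Scale the conductance channel so its maximum equals the CMR EDV."""
    c = rec.conductance_volume
    if c is None:
        raise ChannelError("recording has no conductance-volume channel")
    cmax = float(np.max(c))
    if cmax <= 0:
        raise ChannelError("conductance channel has no positive samples")
    return replace(rec, conductance_volume=c * (cmr_edv / cmax))


def build_reference_loop(avg: AveragedBeat, vol: VolumeCurve) -> PVLoop:
    """Pair the averaged pressure beat with the CMR volume curve.

    Both signals are expressed on a normalized beat-time axis anchored at
    end diastole (pressure beat onset on one side, maximal-volume frame on
    the other): the volume curve is resampled to 250 points with a periodic
    spline, paired with the averaged pressures, and the resulting loop is
    linearly interpolated down to 100 points.
    """
    vol250 = resample_volume_curve(vol, AVG_BEAT_POINTS)
    t250 = np.arange(AVG_BEAT_POINTS) / AVG_BEAT_POINTS
    t100 = np.arange(LOOP_POINTS) / LOOP_POINTS
    v = np.interp(t100, t250, vol250.volumes, period=1.0)
    p = np.interp(t100, t250, avg.pressures, period=1.0)
    p = np.maximum(p, 0.0)  # filtered noise may dip a hair below zero
    return PVLoop(t_grid=t100, volumes=v, pressures=p, source="invasive")
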