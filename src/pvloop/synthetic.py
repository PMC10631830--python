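"""Synthetic paired CMR + catheter datasets with known ground truth.

Real validation data for this method (paired cine CMR volume curves and LV
catheter pressure recordings) cannot be publicly shared, so every pipeline
stage is exercised against synthetic datasets generated here. The
generator emulates exactly the features the pipelines consume:

- a smooth two-phase LV volume curve (ejection to ESV at the end-systolic
  fraction, biphasic refill with an early rapid-filling wave and an atrial
  kick), sampled at 25 cine frames;
- a ground-truth pressure beat built from the same elastance model
  (``P = E * V``), from which multi-beat 250 Hz catheter traces are
  synthesized with beat-to-beat peak-pressure variability (default
  1.96*SD = 6.1 mmHg), additive sample noise, optional short-coupled
  ectopic beats with reduced peaks, and a withdrawal pressure offset;
- a brachial cuff pressure constructed by inverting the peak-pressure
  formula around the true peak plus an optional systematic brachial
  overestimation (default +11 mmHg).

A "shape-mismatch" mode perturbs the elastance used for the ground truth so
that model error between generator and estimator can be emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastance import (
    ElastanceCurve,
    ScaledElastance,
    default_elastance,
    double_hill,
    solve_amplitude,
    warp_to_end_systole,
)
from .metrics import PVMetrics, compute_all_metrics
from .noninvasive import LOOP_POINTS, BrachialBP, PVLoop, peak_pressure_formula
from .volumes import VolumeCurve

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "make_volume_curve",
    "make_ground_truth",
    "make_catheter_recording",
    "make_cohort",
]

_DENSE = 1000  # samples of the dense ground-truth beat


def _ramp(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 cosine ramp, clipped outside [0, 1]; C1 at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def volume_fraction(x: np.ndarray, t_es_frac: float) -> np.ndarray:
    """Normalized volume shape g(x) with g(0)=1, g(t_es)=0, g(1^-)->1.

    Systole is a single smooth ejection; diastole refills in two phases:
    72% of the stroke during early rapid filling (first 45% of diastole)
    and the remaining 28% during the atrial kick (last 30% of diastole),
    with a diastasis plateau in between.
    """
    x = np.mod(np.asarray(x, dtype=float), 1.0)
    g = np.empty_like(x)
    sys_mask = x <= t_es_frac
    g[sys_mask] = 1.0 - _ramp(x[sys_mask] / t_es_frac)
    u = (x[~sys_mask] - t_es_frac) / (1.0 - t_es_frac)
    g[~sys_mask] = 0.72 * _ramp(u / 0.45) + 0.28 * _ramp((u - 0.70) / 0.30)
    return g


def make_volume_curve(
    edv: float,
    ef: float,
    hr: float,
    t_es_frac: float,
    n_frames: int = 25,
) -> VolumeCurve:
    """Sample the analytic volume shape at cine frame times.

    ``edv`` in mL, ``ef`` in percent (0 < ef < 100), ``t_es_frac`` the
    end-systolic cycle fraction in (0, 1). Frame 0 is end diastole.
    """
    if not (0.0 < ef < 100.0):
        raise ValueError("ef must lie strictly inside (0, 100) percent")
    if not (0.0 < t_es_frac < 1.0):
        raise ValueError("t_es_frac must lie strictly inside (0, 1)")
    if edv <= 0:
        raise ValueError("edv must be positive")
    if n_frames < 8:
        raise ValueError("need at least 8 frames")
    esv = edv * (1.0 - ef / 100.0)
    x = np.arange(n_frames) / n_frames
    v = esv + (edv - esv) * volume_fraction(x, t_es_frac)
    return VolumeCurve.from_frames(v, heart_rate=hr)


@dataclass
class GroundTruth:
    """Known truth behind one synthetic dataset.

    Regenerating with the same seed is bit-identical. ``beat_onsets`` is
    filled in by :func:`make_catheter_recording` with the true beat start
    indices of the synthesized trace.
    """

    true_elastance: ScaledElastance
    true_loop: PVLoop
    true_metrics: PVMetrics
    seed: int
    edv: float
    ef: float
    hr: float
    t_es_frac: float
    peak_pressure: float
    edp: float
    beat_t_frac: np.ndarray
    beat_pressure: np.ndarray
    beat_onsets: np.ndarray | None = None


@dataclass(frozen=True)
class SyntheticDataset:
    """One paired synthetic "CMR + catheter" dataset."""

    label: str
    volume_curve: VolumeCurve
    recording: "CatheterRecording"  # noqa: F821 - imported lazily below
    bp: BrachialBP
    truth: GroundTruth


def _perturbed_elastance(rng: np.random.Generator) -> ElastanceCurve:
    """Double-Hill shape with jittered parameters (shape-mismatch mode)."""
    x = np.linspace(0.0, 1.0, 501)
    e = double_hill(
        x,
        tau1=0.269 * rng.uniform(0.9, 1.1),
        n1=1.32 * rng.uniform(0.9, 1.1),
        tau2=0.452 * rng.uniform(0.95, 1.05),
        n2=21.9 * rng.uniform(0.8, 1.2),
    )
    return ElastanceCurve.from_samples(x, e)


def make_ground_truth(
    edv: float,
    ef: float,
    hr: float,
    t_es_frac: float,
    peak_pressure: float,
    edp: float = 7.5,
    elastance: ElastanceCurve | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Build the true loop, metrics and dense pressure beat for one state.

    The true pressure is generated from the elastance model itself
    (self-consistency mode by default): the normalized curve is warped to
    ``t_es_frac``, amplitude-scaled so the 100-point loop peaks exactly at
    ``peak_pressure`` with end-diastolic pressure ``edp``, and multiplied
    with the analytic volume shape.
    """
    if elastance is None:
        elastance = default_elastance()
    esv = edv * (1.0 - ef / 100.0)
    warped = warp_to_end_systole(elastance, t_es_frac)
    t100 = np.arange(LOOP_POINTS) / LOOP_POINTS
    v100 = esv + (edv - esv) * volume_fraction(t100, t_es_frac)
    e100 = warped(t100)
    e_offset, e_scale = solve_amplitude(e100, v100, peak_pressure, edp)
    p100 = (e_offset + e_scale * e100) * v100
    loop = PVLoop(t_grid=t100, volumes=v100, pressures=p100, source="noninvasive")
    metrics = compute_all_metrics(loop, hr)
    t_dense = np.arange(_DENSE) / _DENSE
    v_dense = esv + (edv - esv) * volume_fraction(t_dense, t_es_frac)
    p_dense = (e_offset + e_scale * warped(t_dense)) * v_dense
    scaled = ScaledElastance(
        t_grid=t100 * 60.0 / hr,
        e_abs=e_offset + e_scale * e100,
        e_offset=e_offset,
        e_scale=e_scale,
    )
    return GroundTruth(
        true_elastance=scaled,
        true_loop=loop,
        true_metrics=metrics,
        seed=seed,
        edv=edv,
        ef=ef,
        hr=hr,
        t_es_frac=t_es_frac,
        peak_pressure=peak_pressure,
        edp=edp,
        beat_t_frac=t_dense,
        beat_pressure=p_dense,
    )


def make_catheter_recording(
    truth: GroundTruth,
    n_beats: int = 24,
    peak_sd_1p96: float = 6.1,
    noise_sd: float = 1.0,
    ectopic_beats: int = 0,
    withdrawal_offset: float = 0.0,
    seed: int = 0,
):
    """Synthesize a multi-beat 250 Hz pressure trace from the true beat.

    Each beat is a copy of the dense ground-truth beat rescaled so per-beat
    peak pressures are Gaussian around the true peak with
    ``1.96 * SD = peak_sd_1p96`` (the beat-to-beat variability observed in
    real recordings), plus i.i.d. Gaussian sample noise of SD ``noise_sd``.
    Ectopic beats are short-coupled (RR shortened to 0.6 of nominal) with a
    30% reduced peak. True beat-onset indices are stored in
    ``truth.beat_onsets``.
    """
    from .invasive import CatheterRecording  # local import avoids a cycle

    if n_beats < 3:
        raise ValueError("need at least 3 beats")
    if ectopic_beats >= n_beats / 2:
        raise ValueError(
            "that many ectopics would trigger frequent-ectopy rejection by design"
        )
    rng = np.random.default_rng(seed)
    fs = 250.0
    rr = 60.0 / truth.hr
    n_norm = int(round(rr * fs))
    n_ect = int(round(0.6 * rr * fs))
    if ectopic_beats > 0:
        positions = rng.choice(
            np.arange(2, n_beats - 2), size=ectopic_beats, replace=False
        )
    else:
        positions = np.array([], dtype=int)
    sigma_peak = peak_sd_1p96 / 1.96
    segments = []
    onsets = []
    pos = 0
    for i in range(n_beats):
        scale = (truth.peak_pressure + rng.normal(0.0, sigma_peak)) / truth.peak_pressure
        n_samp = n_norm
        if i in positions:
            scale *= 0.7
            n_samp = n_ect
        x = np.arange(n_samp) / n_samp
        beat = scale * np.interp(x, truth.beat_t_frac, truth.beat_pressure)
        segments.append(beat)
        onsets.append(pos)
        pos += n_samp
    pressure = np.concatenate(segments)
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, size=len(pressure))
    pressure = pressure + withdrawal_offset
    truth.beat_onsets = np.asarray(onsets)
    return CatheterRecording(
        sample_rate=fs, pressure=pressure, withdrawal_offset=withdrawal_offset
    )


def make_cohort(
    n_datasets: int = 8,
    brachial_bias_mmHg: float = 11.0,
    peak_sd_1p96: float = 6.1,
    noise_sd: float = 1.0,
    edp: float = 7.5,
    shape_mismatch: bool = False,
    seed: int = 0,
) -> list[SyntheticDataset]:
    """Generate paired datasets across random haemodynamic states.

    Per dataset: EDV in 150-400 mL, EF in 15-45%, HR in 60-90 bpm, true LV
    peak pressure in 90-140 mmHg, end-systolic fraction on the cine frame
    grid in 0.30-0.42 of the cycle; 20-28 recorded beats. The brachial
    pressure pair is constructed by inverting ``(2*SBP + DBP)/3`` around
    the true peak plus ``brachial_bias_mmHg`` (jittered by 25% between
    datasets; a zero bias is applied exactly), with a pulse pressure drawn
    in 35-60 mmHg.
    """
    if n_datasets < 3:
        raise ValueError("need at least 3 datasets")
    rng = np.random.default_rng(seed)
    datasets = []
    for k in range(n_datasets):
        edv = rng.uniform(150.0, 400.0)
        ef = rng.uniform(15.0, 45.0)
        hr = rng.uniform(60.0, 90.0)
        peak = rng.uniform(90.0, 140.0)
        n_frames = 25
        frame = int(round(rng.uniform(0.30, 0.42) * n_frames))
        t_es = frame / n_frames
        sub_seed = int(rng.integers(0, 2**31 - 1))
        el = _perturbed_elastance(rng) if shape_mismatch else None
        truth = make_ground_truth(
            edv, ef, hr, t_es, peak, edp=edp, elastance=el, seed=sub_seed
        )
        n_beats = int(rng.integers(20, 29))
        rec = make_catheter_recording(
            truth,
            n_beats=n_beats,
            peak_sd_1p96=peak_sd_1p96,
            noise_sd=noise_sd,
            withdrawal_offset=float(rng.uniform(-3.0, 3.0)),
            seed=sub_seed,
        )
        if brachial_bias_mmHg == 0.0:
            target = peak
        else:
            target = peak + brachial_bias_mmHg * rng.normal(1.0, 0.25)
        pp = rng.uniform(35.0, 60.0)
        sbp = target + pp / 3.0
        dbp = sbp - pp
        assert abs(peak_pressure_formula(sbp, dbp) - target) < 1e-9
        datasets.append(
            SyntheticDataset(
                label=f"synthetic-{k:02d}",
                volume_curve=make_volume_curve(edv, ef, hr, t_es, n_frames),
                recording=rec,
                bp=BrachialBP(sbp=sbp, dbp=dbp),
                truth=truth,
            )
        )
    return datasets
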