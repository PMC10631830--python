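import numpy as np
import pytest

from pvloop import (
    AveragedBeat,
    BeatSet,
    CatheterRecording,
    average_beats,
    build_reference_loop,
    calibrate_conductance,
    correct_offset,
    flag_ectopy,
    lowpass_filter,
    segment_beats,
    stroke_work,
)
from pvloop.errors import ChannelError, FrequentEctopyError, SegmentationError
from pvloop.metrics import compute_all_metrics
from pvloop.synthetic import make_catheter_recording, make_ground_truth, make_volume_curve

FS = 250.0


def sine_recording(freq_hz: float, seconds: float = 8.0, amp: float = 10.0,
                   offset: float = 50.0) -> CatheterRecording:
    t = np.arange(int(seconds * FS)) / FS
    return CatheterRecording(sample_rate=FS,
                             pressure=offset + amp * np.sin(2 * np.pi * freq_hz * t))


# function-scoped: make_catheter_recording records the true beat onsets on
# the GroundTruth it was given, so sharing one truth across tests would alias
@pytest.fixture
def truth():
    return make_ground_truth(336.0, 28.0, 70.0, 0.36, 110.0)


@pytest.fixture
def clean_recording(truth):
    return make_catheter_recording(
        truth, n_beats=20, peak_sd_1p96=0.0, noise_sd=0.0, seed=5
    )


class TestFilter:
    def test_dc_gain_unity(self):
        rec = CatheterRecording(sample_rate=FS, pressure=np.full(2500, 50.0))
        out = lowpass_filter(rec)
        assert np.allclose(out.pressure, 50.0, atol=1e-9)

    def test_passband_tone_preserved(self):
        out = lowpass_filter(sine_recording(1.0))
        mid = out.pressure[500:-500]
        assert np.ptp(mid) == pytest.approx(20.0, rel=0.05)

    def test_stopband_tone_suppressed(self):
        out = lowpass_filter(sine_recording(40.0))
        mid = out.pressure[500:-500]
        assert np.ptp(mid) < 0.1 * 20.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(sine_recording(1.0), cutoff=130.0)


class TestOffsetCorrection:
    @pytest.mark.parametrize("offset", [0.0, 5.0, -3.2])
    def test_subtracts_withdrawal_offset(self, offset):
        p = np.linspace(5.0, 100.0, 1000) + offset
        rec = CatheterRecording(sample_rate=FS, pressure=p, withdrawal_offset=offset)
        out = correct_offset(rec)
        assert np.allclose(out.pressure, p - offset)
        assert out.withdrawal_offset == 0.0

    def test_diastolic_minima_shifted_by_offset(self, truth):
        rec = make_catheter_recording(
            truth, n_beats=10, peak_sd_1p96=0.0, noise_sd=0.0,
            withdrawal_offset=5.0, seed=2,
        )
        corrected = correct_offset(rec)
        assert np.min(corrected.pressure) == pytest.approx(
            np.min(rec.pressure) - 5.0
        )


class TestSegmentation:
    def test_regular_beats_at_75_bpm(self):
        t = make_ground_truth(250.0, 35.0, 75.0, 0.36, 120.0)
        rec = make_catheter_recording(t, n_beats=20, peak_sd_1p96=0.0,
                                      noise_sd=0.0, seed=1)
        beats = segment_beats(lowpass_filter(rec))
        assert 19 <= beats.n_beats + 1 <= 20  # complete beats span onsets
        assert np.allclose(beats.rr_intervals, 0.8, atol=1 / FS)

    def test_constant_trace_rejected(self):
        rec = CatheterRecording(sample_rate=FS, pressure=np.full(2500, 60.0))
        with pytest.raises(SegmentationError):
            segment_beats(rec)

    def test_onsets_recover_generator_truth(self, truth, clean_recording):
        beats = segment_beats(lowpass_filter(clean_recording))
        detected = np.array([s for s, _ in beats.beat_boundaries])
        errors = [np.min(np.abs(o - truth.beat_onsets)) for o in detected]
        assert max(errors) <= 3

    def test_noise_does_not_break_onset_recovery(self, truth):
        rec = make_catheter_recording(truth, n_beats=20, peak_sd_1p96=6.1,
                                      noise_sd=1.0, seed=9)
        beats = segment_beats(lowpass_filter(rec))
        detected = np.array([s for s, _ in beats.beat_boundaries])
        errors = [np.min(np.abs(o - truth.beat_onsets)) for o in detected]
        assert max(errors) <= 3


class TestEctopy:
    def test_single_ectopic_discards_three_beats(self, truth):
        rec = make_catheter_recording(truth, n_beats=22, peak_sd_1p96=0.0,
                                      noise_sd=0.0, ectopic_beats=1, seed=3)
        beats = flag_ectopy(segment_beats(lowpass_filter(rec)))
        n_complete = beats.n_beats
        assert int(np.sum(beats.ectopic_flags)) == 1
        assert len(beats.retained_indices) == n_complete - 3

    def test_no_ectopy_retains_all(self, clean_recording):
        beats = flag_ectopy(segment_beats(lowpass_filter(clean_recording)))
        assert beats.retained_indices == tuple(range(beats.n_beats))

    def test_frequent_ectopy_rejects_recording(self):
        # 10 of 20 RR intervals deviant -> ectopic fraction 0.5 > 0.25
        rr = np.tile([0.8, 0.8, 0.5, 0.5], 5)
        bounds = np.concatenate([[0], np.cumsum((rr * FS).astype(int))])
        beats = BeatSet(
            beat_boundaries=tuple(zip(bounds[:-1], bounds[1:])),
            rr_intervals=rr,
            ectopic_flags=np.zeros(20, bool),
            retained_indices=tuple(range(20)),
        )
        with pytest.raises(FrequentEctopyError):
            flag_ectopy(beats)


def manual_beatset(onsets, n_total):
    bounds = tuple(zip(onsets[:-1], onsets[1:]))
    n = len(bounds)
    return BeatSet(
        beat_boundaries=bounds,
        rr_intervals=np.diff(onsets) / FS,
        ectopic_flags=np.zeros(n, bool),
        retained_indices=tuple(range(n)),
    )


class TestAveraging:
    def test_identical_beats_average_to_single_beat(self, truth, clean_recording):
        beats = manual_beatset(truth.beat_onsets, len(clean_recording.pressure))
        avg = average_beats(clean_recording, beats)
        s, e = beats.beat_boundaries[0]
        single = np.interp(
            np.linspace(0, 1, 250, endpoint=False),
            np.linspace(0, 1, e - s, endpoint=False),
            clean_recording.pressure[s:e],
        )
        assert len(avg.pressures) == 250
        assert np.allclose(avg.pressures, single, atol=1e-9)

    def test_noise_averages_down(self, truth):
        # pointwise averaging of N noisy copies: RMSE < 2*sigma/sqrt(N)
        sigma, worst = 1.0, []
        for seed in range(100):
            rec = make_catheter_recording(truth, n_beats=24, peak_sd_1p96=0.0,
                                          noise_sd=sigma, seed=seed)
            beats = manual_beatset(truth.beat_onsets, len(rec.pressure))
            avg = average_beats(rec, beats)
            clean = make_catheter_recording(truth, n_beats=24, peak_sd_1p96=0.0,
                                            noise_sd=0.0, seed=seed)
            ref = average_beats(clean, beats)
            n = avg.n_beats_averaged
            rmse = np.sqrt(np.mean((avg.pressures - ref.pressures) ** 2))
            worst.append(rmse - 2 * sigma / np.sqrt(n))
        assert max(worst) < 0.0

    def test_commutes_with_uniform_offset(self, truth, clean_recording):
        beats = manual_beatset(truth.beat_onsets, len(clean_recording.pressure))
        shifted = CatheterRecording(
            sample_rate=FS, pressure=clean_recording.pressure + 7.0
        )
        a = average_beats(clean_recording, beats)
        b = average_beats(shifted, beats)
        assert np.allclose(b.pressures, a.pressures + 7.0, atol=1e-12)

    def test_empty_retained_set_rejected(self, truth, clean_recording):
        beats = manual_beatset(truth.beat_onsets, len(clean_recording.pressure))
        from dataclasses import replace

        with pytest.raises(ValueError):
            average_beats(clean_recording, replace(beats, retained_indices=()))


class TestConductanceCalibration:
    def test_scales_max_to_cmr_edv(self):
        c = np.linspace(20.0, 80.0, 1000)
        rec = CatheterRecording(sample_rate=FS, pressure=np.ones(1000),
                                conductance_volume=c)
        out = calibrate_conductance(rec, cmr_edv=336.0)
        assert np.max(out.conductance_volume) == pytest.approx(336.0)
        assert np.allclose(out.conductance_volume, c * 4.2)

    def test_already_calibrated_is_identity(self):
        c = np.linspace(100.0, 336.0, 1000)
        rec = CatheterRecording(sample_rate=FS, pressure=np.ones(1000),
                                conductance_volume=c)
        out = calibrate_conductance(rec, cmr_edv=336.0)
        assert np.allclose(out.conductance_volume, c)

    def test_missing_or_zero_channel_rejected(self):
        rec = CatheterRecording(sample_rate=FS, pressure=np.ones(1000))
        with pytest.raises(ChannelError):
            calibrate_conductance(rec, 336.0)
        rec0 = CatheterRecording(sample_rate=FS, pressure=np.ones(1000),
                                 conductance_volume=np.zeros(1000))
        with pytest.raises(ChannelError):
            calibrate_conductance(rec0, 336.0)


class TestReferenceLoop:
    def test_loop_has_100_points(self, truth, clean_recording):
        beats = flag_ectopy(segment_beats(lowpass_filter(clean_recording)))
        avg = average_beats(lowpass_filter(clean_recording), beats)
        vol = make_volume_curve(336.0, 28.0, 70.0, 0.36)
        loop = build_reference_loop(avg, vol)
        assert len(loop.volumes) == 100
        assert loop.source == "invasive"

    def test_constant_pressure_gives_zero_area(self):
        avg = AveragedBeat(pressures=np.full(250, 40.0), n_beats_averaged=5,
                           peak_sd=0.0)
        vol = make_volume_curve(336.0, 28.0, 70.0, 0.36)
        loop = build_reference_loop(avg, vol)
        assert stroke_work(loop) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_ground_truth_stroke_work(self, truth, clean_recording):
        rec = lowpass_filter(clean_recording)
        beats = flag_ectopy(segment_beats(rec))
        avg = average_beats(rec, beats)
        vol = make_volume_curve(336.0, 28.0, 70.0, 0.36)
        loop = build_reference_loop(avg, vol)
        assert stroke_work(loop) == pytest.approx(truth.true_metrics.sw, rel=0.02)

    def test_metric_identity_holds_for_reference_loops(self, truth, clean_recording):
        rec = lowpass_filter(clean_recording)
        avg = average_beats(rec, flag_ectopy(segment_beats(rec)))
        vol = make_volume_curve(336.0, 28.0, 70.0, 0.36)
        m = compute_all_metrics(build_reference_loop(avg, vol), hr=70.0)
        assert m.pva == m.sw + m.pe
        assert 0.0 < m.ve <= 1.0
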