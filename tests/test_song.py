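"""Filtering, pulse detection, bursts, IPIs, temperature correction, indices."""

import numpy as np
import pytest

from coldsong import song, synthetic
from coldsong.song import IPISeries
from coldsong.synthetic import AudioRecording, PulseTrain


def tone(freq, fs=10_000.0, seconds=2.0):
    t = np.arange(int(fs * seconds)) / fs
    return AudioRecording(np.sin(2 * np.pi * freq * t), fs)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_out_of_band_tone_attenuated(self):
        out = song.bandpass(tone(50.0))
        assert rms(out.samples) < 0.1 * rms(tone(50.0).samples)

    def test_in_band_tone_passes(self):
        audio = tone(400.0)
        out = song.bandpass(audio)
        ratio = rms(out.samples) / rms(audio.samples)
        assert 0.7 <= ratio <= 1.0

    def test_silence_stays_silence(self):
        out = song.bandpass(AudioRecording(np.zeros(1000), 10_000.0))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            song.bandpass(tone(400.0), low=100.0, high=6000.0)


class TestDetectPulses:
    def test_recovers_synthetic_pulses_within_1ms(self, song_params, rng):
        train = synthetic.gen_pulse_train(song_params, 25.0, rng)
        audio = synthetic.synthesize_audio(train, song_params, rng)
        detected = song.detect_pulses(song.bandpass(audio))
        assert len(detected) == len(train)
        errors_ms = np.abs(detected.pulse_times - train.pulse_times) * 1000
        assert errors_ms.max() < 1.0

    def test_pure_noise_yields_no_pulses(self, song_params, rng):
        noise = AudioRecording(rng.normal(0, song_params.noise_sd, 40_000),
                               song_params.sample_rate)
        assert len(song.detect_pulses(song.bandpass(noise))) == 0

    def test_refractory_window_merges_close_pulses(self, song_params):
        train = PulseTrain(np.array([0.100, 0.105]))  # 5 ms apart
        audio = synthetic.synthesize_audio(
            train, synthetic.SongSimParams(noise_sd=0.0))
        detected = song.detect_pulses(audio, refractory_ms=10.0)
        assert len(detected) == 1

    def test_single_clean_pulse_located_precisely(self):
        params = synthetic.SongSimParams(noise_sd=0.0)
        train = PulseTrain(np.array([0.250]))
        audio = synthetic.synthesize_audio(train, params, duration=0.5)
        detected = song.detect_pulses(audio)
        assert len(detected) == 1
        assert abs(detected.pulse_times[0] - 0.250) < 0.001

    def test_empty_audio(self):
        detected = song.detect_pulses(AudioRecording(np.empty(0), 10_000.0))
        assert len(detected) == 0


class TestBurstsAndIpis:
    def test_gap_splits_bursts(self):
        train = PulseTrain(np.array([0, 35, 70, 500, 535, 570]) / 1000.0)
        bursts = song.segment_bursts(train, max_gap_ms=100.0)
        assert [len(b) for b in bursts] == [3, 3]

    def test_single_pulse_is_its_own_burst(self):
        bursts = song.segment_bursts(PulseTrain(np.array([0.5])))
        assert [len(b) for b in bursts] == [1]

    def test_all_close_pulses_form_one_burst(self):
        train = PulseTrain(np.arange(10) * 0.035)
        assert len(song.segment_bursts(train)) == 1

    def test_ipis_from_three_pulse_burst(self):
        bursts = [np.array([0.0, 0.035, 0.070])]
        series = song.extract_ipis(bursts, 25.0)
        np.testing.assert_allclose(series.ipis_ms, [35.0, 35.0])

    def test_two_pulse_burst_contributes_nothing(self):
        series = song.extract_ipis([np.array([0.0, 0.040])], 25.0)
        assert series.n_ipi == 0

    def test_k_bursts_of_m_pulses_give_k_m_minus_1_ipis(self):
        bursts = [np.arange(5) * 0.03 + off for off in (0.0, 1.0, 2.0)]
        series = song.extract_ipis(bursts, 25.0)
        assert series.n_ipi == 3 * (5 - 1)


@pytest.mark.parametrize("start,end,expected",
                         [(24.0, 24.2, 24.1), (25.0, 25.0, 25.0),
                          (23.9, 24.1, 24.0)])
def test_recording_temperature(start, end, expected):
    assert song.recording_temperature(start, end) == pytest.approx(expected)


class TestTemperatureCorrection:
    def test_identity_at_reference(self):
        assert song.correct_ipi(37.7, 25.0) == pytest.approx(37.7, abs=1e-12)

    def test_printed_slope_arithmetic(self):
        assert song.correct_ipi(35.0, 24.0) == pytest.approx(33.9563, abs=1e-9)
        assert song.correct_ipi(35.0, 26.0) == pytest.approx(36.0437, abs=1e-9)

    def test_affine_round_trip(self):
        once = song.correct_ipi(35.0, 23.0, slope=-1.0437)
        back = song.correct_ipi(once, 23.0, slope=1.0437)
        assert back == pytest.approx(35.0, abs=1e-12)

    def test_linearity_mean_commutes(self, rng):
        ipis = rng.uniform(30, 40, size=50)
        temp = 23.7
        corrected = [song.correct_ipi(x, temp) for x in ipis]
        assert np.mean(corrected) == pytest.approx(
            song.correct_ipi(np.mean(ipis), temp), abs=1e-9)


class TestSlopeEstimation:
    def test_colinear_songs_recover_exact_slope(self):
        songs = [IPISeries(np.full(20, 35.0 - 1.5 * (t - 25.0)), t, f"s{t}")
                 for t in (23.0, 24.5, 26.0)]
        fit = song.estimate_ipi_temperature_slope(songs)
        assert fit.slope == pytest.approx(-1.5, abs=1e-9)

    def test_identical_means_give_zero_slope(self):
        songs = [IPISeries(np.full(20, 35.0), t, f"s{t}")
                 for t in (23.0, 24.0, 26.0)]
        assert song.estimate_ipi_temperature_slope(songs).slope == \
            pytest.approx(0.0, abs=1e-12)

    def test_constant_temperature_rejected(self):
        songs = [IPISeries(np.full(20, 35.0), 25.0, f"s{i}") for i in range(4)]
        with pytest.raises(ValueError):
            song.estimate_ipi_temperature_slope(songs)


class TestIndices:
    def test_song_index_simple(self):
        series = IPISeries(np.full(100, 30.0), 25.0)  # 3 s total
        assert song.song_index(series, 30.0) == pytest.approx(0.1)

    def test_song_index_no_ipis_is_zero(self):
        assert song.song_index(IPISeries(np.empty(0), 25.0), 30.0) == 0.0

    def test_song_index_exceeding_duration_rejected(self):
        series = IPISeries(np.full(100, 400.0), 25.0)  # 40 s of song
        with pytest.raises(ValueError):
            song.song_index(series, 30.0)

    def test_courtship_index_full_coverage(self):
        assert song.courtship_index([(0.0, 60.0)], 60.0) == pytest.approx(1.0)

    def test_courtship_index_half(self):
        assert song.courtship_index([(0.0, 30.0)], 60.0) == pytest.approx(0.5)

    def test_overlapping_intervals_merged(self):
        idx = song.courtship_index([(0.0, 10.0), (5.0, 15.0)], 20.0)
        assert idx == pytest.approx(0.75)

    def test_indices_invariant_under_time_rescaling(self):
        series = IPISeries(np.full(20, 35.0), 25.0)
        k = 3.0
        scaled = IPISeries(np.full(20, 35.0 * k), 25.0)
        assert song.song_index(series, 10.0) == pytest.approx(
            song.song_index(scaled, 10.0 * k))
        assert song.courtship_index([(1.0, 4.0)], 10.0) == pytest.approx(
            song.courtship_index([(1.0 * k, 4.0 * k)], 10.0 * k))


class TestRetention:
    def _metrics(self, n_ipi):
        return song.SongMetrics(
            song_id=f"s{n_ipi}", n_ipi=n_ipi, mean_ipi_raw=35.0,
            mean_ipi_corrected=35.0, song_index=0.1, courtship_index=0.5,
            courtship_duration_s=60.0, mated=True)

    def test_boundary_inclusive_at_15(self):
        retained = song.retain_songs([self._metrics(14), self._metrics(15)])
        assert [m.n_ipi for m in retained] == [15]
        assert not self._metrics(14).retained
        assert self._metrics(15).retained

    def test_empty_list(self):
        assert song.retain_songs([]) == []


def test_pipeline_round_trip_mean_ipi(song_params, rng):
    """Synthesis -> filter -> detect -> segment -> IPIs recovers mean IPI."""
    temp = 24.2
    train = synthetic.gen_pulse_train(song_params, temp, rng)
    audio = synthetic.synthesize_audio(train, song_params, rng)
    detected = song.detect_pulses(song.bandpass(audio))
    bursts = song.segment_bursts(detected)
    series = song.extract_ipis(bursts, temp)
    truth = song.extract_ipis(
        song.segment_bursts(train), temp)
    assert series.n_ipi == truth.n_ipi
    assert series.mean_ipi == pytest.approx(truth.mean_ipi, abs=0.5)
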