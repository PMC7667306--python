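"""Stimulus synthesis and envelope-spectrum characterisation."""

import numpy as np
import pytest

from beatmeter import stimulus as st


class TestAccentPattern:
    @pytest.mark.parametrize(
        "meter,n_beats,accent_db,expected",
        [
            ("duple", 4, 10.0, [3.1623, 1.0, 3.1623, 1.0]),
            ("triple", 3, 0.0, [1.0, 1.0, 1.0]),
            ("triple", 6, 6.0, [1.9953, 1.0, 1.0, 1.9953, 1.0, 1.0]),
        ],
    )
    def test_gain_sequences(self, meter, n_beats, accent_db, expected):
        pat = st.build_accent_pattern(meter, n_beats, accent_db)
        assert pat.accent_gains == pytest.approx(expected, abs=1e-4)

    def test_rejects_partial_measures(self):
        with pytest.raises(ValueError, match="multiple"):
            st.build_accent_pattern("triple", 4, 10.0)
        with pytest.raises(ValueError):
            st.build_accent_pattern("duple", 0, 10.0)

    def test_rejects_unknown_meter(self):
        with pytest.raises(ValueError, match="meter_label"):
            st.build_accent_pattern("quadruple", 4, 10.0)


class TestSynthesis:
    def test_duration_is_beats_times_ioi(self):
        pat = st.build_accent_pattern("duple", 32, 10.0)
        stim = st.synthesize_stimulus(pat)
        assert stim.duration_s == pytest.approx(9.6)

    def test_rms_normalised_to_reference(self):
        pat = st.build_accent_pattern("triple", 33, 10.0)
        stim = st.synthesize_stimulus(pat)
        assert stim.rms == pytest.approx(0.01, rel=1e-9)

    def test_gain_linearity_without_normalisation(self):
        one = st.AccentPattern("duple", np.array([1.0, 1.0]), ioi_s=0.3)
        two = st.AccentPattern("duple", np.array([2.0, 2.0]), ioi_s=0.3)
        s1 = st.synthesize_stimulus(one, normalize_rms=False)
        s2 = st.synthesize_stimulus(two, normalize_rms=False)
        np.testing.assert_allclose(s2.samples, 2.0 * s1.samples, atol=1e-12)

    def test_rejects_overlapping_tones(self):
        pat = st.build_accent_pattern("duple", 4, 10.0, ioi_s=0.05)
        with pytest.raises(ValueError, match="overlap"):
            st.synthesize_stimulus(pat, st.ToneModel(duration_s=0.1))


class TestEnvelope:
    def test_constant_tone_gives_constant_envelope(self):
        fs = 4000.0
        t = np.arange(int(2.0 * fs)) / fs
        a = 0.7
        stim = st.AudioStimulus(samples=a * np.sin(2 * np.pi * 220.0 * t), fs_hz=fs)
        env = st.envelope(stim)
        core = env.samples[int(0.2 * fs) : -int(0.2 * fs)]
        assert np.all(np.abs(core - a) < 0.02 * a)

    def test_silence_gives_zero_envelope(self):
        stim = st.AudioStimulus(samples=np.zeros(8000), fs_hz=4000.0)
        env = st.envelope(stim)
        np.testing.assert_allclose(env.samples, 0.0, atol=1e-12)

    def test_accented_tone_pair_preserves_gain_ratio(self):
        pat = st.build_accent_pattern("duple", 2, 10.0)
        stim = st.synthesize_stimulus(pat, normalize_rms=False)
        env = st.envelope(stim)
        fs = stim.fs_hz
        peak_strong = env.samples[: int(0.3 * fs)].max()
        peak_weak = env.samples[int(0.3 * fs) :].max()
        assert peak_strong / peak_weak == pytest.approx(10 ** 0.5, rel=0.02)


class TestSpectrum:
    def test_on_grid_sinusoid_peaks_at_its_frequency(self):
        fs = 200.0
        t = np.arange(int(100.0 * fs)) / fs
        spec = st.spectrum_of(np.sin(2 * np.pi * 2.0 * t), 0.01, fs_hz=fs)
        assert spec.freqs_hz[np.argmax(spec.power)] == pytest.approx(2.0)

    def test_amplitude_doubling_quadruples_power(self):
        fs = 200.0
        t = np.arange(int(100.0 * fs)) / fs
        a = 0.3
        x = 2 * a * np.sin(2 * np.pi * 2.0 * t) + a * np.sin(2 * np.pi * 5.0 * t)
        spec = st.spectrum_of(x, 0.01, fs_hz=fs)
        p2 = spec.power[np.argmin(np.abs(spec.freqs_hz - 2.0))]
        p5 = spec.power[np.argmin(np.abs(spec.freqs_hz - 5.0))]
        assert p2 / p5 == pytest.approx(4.0, rel=0.01)

    def test_short_signal_without_padding_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            st.spectrum_of(np.ones(100), 0.01, fs_hz=100.0, allow_padding=False)

    def test_doubling_gains_quadruples_envelope_power(self):
        pat = st.build_accent_pattern("duple", 8, 10.0)
        doubled = st.AccentPattern("duple", 2.0 * pat.accent_gains, ioi_s=0.3)
        tone = st.ToneModel(fs_hz=4410.0)
        s1 = st.envelope(st.synthesize_stimulus(pat, tone, normalize_rms=False))
        s2 = st.envelope(st.synthesize_stimulus(doubled, tone, normalize_rms=False))
        sp1 = st.spectrum_of(s1, 0.05)
        sp2 = st.spectrum_of(s2, 0.05)
        mask = sp1.power > 1e-9 * sp1.power.max()
        np.testing.assert_allclose(sp2.power[mask] / sp1.power[mask], 4.0, rtol=1e-6)


class TestFindPeak:
    def test_single_nonzero_bin(self):
        freqs = np.arange(0, 5.0, 0.05)
        power = np.zeros_like(freqs)
        power[np.argmin(np.abs(freqs - 3.35))] = 2.0
        spec = st.Spectrum(freqs, power, 0.05)
        peak = st.find_peak(spec, (3.2, 3.5))
        assert peak.freq_hz == pytest.approx(3.35)
        assert peak.power == 2.0

    def test_all_equal_ties_to_lowest_frequency(self):
        freqs = np.arange(0, 5.0, 0.05)
        spec = st.Spectrum(freqs, np.ones_like(freqs), 0.05)
        assert st.find_peak(spec, (3.2, 3.5)).freq_hz == pytest.approx(3.2)

    def test_matches_brute_force_on_random_spectra(self, rng):
        freqs = np.arange(0, 10.0, 0.01)
        for _ in range(50):
            power = rng.random(freqs.size)
            lo = rng.uniform(0, 8)
            hi = lo + rng.uniform(0.05, 2)
            spec = st.Spectrum(freqs, power, 0.01)
            peak = st.find_peak(spec, (lo, hi))
            # oracle: literal scan over band bins
            best = max(
                (p, -f) for f, p in zip(freqs, power) if lo <= f <= hi
            )
            assert peak.power == best[0]
            assert peak.freq_hz == -best[1]

    def test_empty_band_rejected(self):
        spec = st.Spectrum(np.arange(0, 5.0, 0.05), np.ones(100), 0.05)
        with pytest.raises(ValueError):
            st.find_peak(spec, (3.201, 3.249))


class TestStimulusRatio:
    def test_equal_amplitudes_give_unit_ratio(self):
        fs = 200.0
        t = np.arange(int(100.0 * fs)) / fs
        x = np.sin(2 * np.pi * 3.35 * t) + np.sin(2 * np.pi * 1.65 * t)
        spec = st.spectrum_of(x, 0.01, fs_hz=fs)
        assert st.stimulus_beat_meter_ratio(spec, "duple") == pytest.approx(1.0, rel=1e-6)

    def test_meter_amplitude_doubled_gives_quarter_ratio(self):
        fs = 200.0
        t = np.arange(int(100.0 * fs)) / fs
        a = 0.4
        x = a * np.sin(2 * np.pi * 3.35 * t) + 2 * a * np.sin(2 * np.pi * 1.65 * t)
        spec = st.spectrum_of(x, 0.01, fs_hz=fs)
        assert st.stimulus_beat_meter_ratio(spec, "duple") == pytest.approx(0.25, rel=1e-6)

    def test_zero_meter_power_rejected(self):
        freqs = np.arange(0, 5.0, 0.05)
        power = np.zeros_like(freqs)
        power[np.argmin(np.abs(freqs - 3.35))] = 1.0
        spec = st.Spectrum(freqs, power, 0.05)
        with pytest.raises(ValueError, match="meter"):
            st.stimulus_beat_meter_ratio(spec, "duple")


class TestEnvelopeSpectrumStructure:
    def test_duple_peaks_at_beat_and_meter_frequencies(self, duple_env_spectrum):
        assert st.find_peak(duple_env_spectrum, (2.5, 4.5)).freq_hz == pytest.approx(3.33)
        assert st.find_peak(duple_env_spectrum, (1.4, 2.0)).freq_hz == pytest.approx(1.67)

    def test_triple_peaks_at_beat_and_meter_frequencies(self, triple_env_spectrum):
        assert st.find_peak(triple_env_spectrum, (2.5, 4.5)).freq_hz == pytest.approx(3.33)
        assert st.find_peak(triple_env_spectrum, (0.9, 1.4)).freq_hz == pytest.approx(1.11)

    def test_unaccented_stream_has_no_meter_component(self):
        # accent 0 dB: isochronous identical tones, so no energy at the
        # meter frequency beyond numerical leakage
        pat = st.build_accent_pattern("duple", 32, 0.0)
        stim = st.synthesize_stimulus(pat, st.ToneModel(fs_hz=4410.0))
        spec = st.spectrum_of(
            st.envelope(st.tile_to_duration(stim, 120.0)), 0.01
        )
        p_beat = st.find_peak(spec, (3.2, 3.5)).power
        p_meter = st.find_peak(spec, (1.6, 1.9)).power
        assert p_meter < 0.01 * p_beat

    @pytest.mark.parametrize(
        "tone",
        [
            st.ToneModel(fs_hz=11025.0),
            st.ToneModel(f0_hz=440.0, n_harmonics=3, decay_tau_s=0.02, fs_hz=11025.0),
            st.ToneModel(f0_hz=150.0, duration_s=0.05, n_harmonics=12, fs_hz=11025.0),
        ],
    )
    def test_peak_locations_are_timbre_invariant(self, tone):
        for meter, n_beats, meter_band, f_meter in [
            ("duple", 32, (1.4, 2.0), 1.67),
            ("triple", 33, (0.9, 1.4), 1.11),
        ]:
            pat = st.build_accent_pattern(meter, n_beats, 10.0)
            stim = st.synthesize_stimulus(pat, tone)
            spec = st.spectrum_of(st.envelope(st.tile_to_duration(stim, 100.0)), 0.01)
            assert st.find_peak(spec, (2.5, 4.5)).freq_hz == pytest.approx(3.33)
            assert st.find_peak(spec, meter_band).freq_hz == pytest.approx(f_meter)


def test_wav_and_spectrum_files_round_trip(tmp_path):
    from scipy.io import wavfile

    pat = st.build_accent_pattern("duple", 4, 10.0)
    stim = st.synthesize_stimulus(pat)
    st.write_wav(stim, tmp_path / "d.wav", params={"accent_db": 10.0})
    fs, data = wavfile.read(tmp_path / "d.wav")
    assert fs == int(stim.fs_hz)
    np.testing.assert_allclose(data, stim.samples.astype(np.float32))
    assert (tmp_path / "d.wav.json").exists()

    spec = st.spectrum_of(stim, 0.1)
    st.write_spectrum_csv(spec, tmp_path / "s.csv")
    arr = np.loadtxt(tmp_path / "s.csv", delimiter=",", skiprows=1)
    np.testing.assert_allclose(arr[:, 0], spec.freqs_hz)
    np.testing.assert_allclose(arr[:, 1], spec.power)
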