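"""Metrical auditory stimulus synthesis and spectral characterisation.

A stimulus is an isochronous stream of short complex tones (300 ms
inter-onset interval, i.e. a 3.33 Hz beat).  Meter is imposed by accenting
every second tone (duple: strong-weak, 1.67 Hz) or every third tone
(triple: strong-weak-weak, 1.11 Hz) by a fixed gain in dB.  The amplitude
envelope of such a stream carries its rhythmic periodicities, so its power
spectrum peaks at the beat frequency and — whenever the accents are
non-zero — at the meter frequency.

The tone timbre here is a deterministic damped harmonic complex (f0 220 Hz,
1/k harmonic amplitudes, exponential decay); peak *locations* in the
envelope spectrum are timbre-invariant even though peak *ratios* are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.fft import next_fast_len, rfft
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "METER_PERIODS",
    "BEAT_HZ",
    "METER_HZ",
    "AccentPattern",
    "ToneModel",
    "AudioStimulus",
    "Spectrum",
    "SpectralPeak",
    "build_accent_pattern",
    "synthesize_tone",
    "synthesize_stimulus",
    "tile_to_duration",
    "envelope",
    "spectrum_of",
    "find_peak",
    "stimulus_beat_meter_ratio",
    "write_wav",
    "write_spectrum_csv",
]

#: beats per metrical group
METER_PERIODS = {"duple": 2, "triple": 3}

#: beat frequency for the default 300 ms inter-onset interval
BEAT_HZ = 1.0 / 0.3

#: meter (inter-strong-beat) frequency for the default IOI
METER_HZ = {"duple": 1.0 / 0.6, "triple": 1.0 / 0.9}

#: reference RMS amplitude used when normalising stimuli
RMS_REFERENCE = 0.01


def _check_meter(meter_label: str) -> int:
    if meter_label not in METER_PERIODS:
        raise ValueError(
            f"meter_label must be one of {sorted(METER_PERIODS)}, got {meter_label!r}"
        )
    return METER_PERIODS[meter_label]


@dataclass(frozen=True)
class AccentPattern:
    """Per-beat amplitude gains of a metrical tone stream."""

    meter_label: str
    accent_gains: np.ndarray
    ioi_s: float = 0.3

    def __post_init__(self):
        _check_meter(self.meter_label)
        gains = np.asarray(self.accent_gains, dtype=float)
        if gains.ndim != 1 or gains.size == 0:
            raise ValueError("accent_gains must be a non-empty 1-D sequence")
        if np.any(gains <= 0):
            raise ValueError("all accent gains must be positive")
        if self.ioi_s <= 0:
            raise ValueError("ioi_s must be positive")
        object.__setattr__(self, "accent_gains", gains)

    @property
    def n_beats(self) -> int:
        return int(self.accent_gains.size)

    @property
    def duration_s(self) -> float:
        return self.n_beats * self.ioi_s


@dataclass(frozen=True)
class ToneModel:
    """Deterministic damped harmonic complex used for every beat.

    ``n_harmonics`` partials at multiples of ``f0_hz`` with 1/k amplitudes,
    an exponential decay of time constant ``decay_tau_s`` and a raised-cosine
    onset ramp of ``ramp_s``.
    """

    f0_hz: float = 220.0
    duration_s: float = 0.1
    n_harmonics: int = 8
    decay_tau_s: float = 0.04
    ramp_s: float = 0.005
    fs_hz: float = 22050.0

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass(frozen=True)
class AudioStimulus:
    """A sampled waveform (unitless amplitude)."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum on a uniform frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    resolution_hz: float

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("freqs_hz and power must have identical shape")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        if f.size > 1:
            steps = np.diff(f)
            if not np.allclose(steps, self.resolution_hz, rtol=1e-9, atol=1e-12):
                raise ValueError("frequency grid must be uniform at resolution_hz")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class SpectralPeak:
    freq_hz: float
    power: float
    band_hz: tuple[float, float]


def build_accent_pattern(
    meter_label: str,
    n_beats: int,
    accent_db: float = 10.0,
    ioi_s: float = 0.3,
) -> AccentPattern:
    """Strong/weak gain sequence for ``n_beats`` beats of the given meter.

    The weak-tone gain is 1; the strong tone is the weak tone amplified by
    ``accent_db`` decibels (amplitude factor ``10**(accent_db/20)``), placed
    at beat 0 of every metrical group.
    """
    period = _check_meter(meter_label)
    if n_beats <= 0 or n_beats % period != 0:
        raise ValueError(
            f"n_beats must be a positive multiple of the {meter_label} "
            f"period {period}, got {n_beats}"
        )
    if accent_db < 0:
        raise ValueError("accent_db must be >= 0")
    gains = np.ones(n_beats)
    gains[::period] = 10.0 ** (accent_db / 20.0)
    return AccentPattern(meter_label=meter_label, accent_gains=gains, ioi_s=ioi_s)


def synthesize_tone(tone: ToneModel) -> np.ndarray:
    """Render one damped harmonic complex, peak-normalised to 1."""
    n = int(round(tone.duration_s * tone.fs_hz))
    t = np.arange(n) / tone.fs_hz
    y = np.zeros(n)
    for k in range(1, tone.n_harmonics + 1):
        y += np.sin(2 * np.pi * k * tone.f0_hz * t) / k
    y *= np.exp(-t / tone.decay_tau_s)
    n_ramp = int(round(tone.ramp_s * tone.fs_hz))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        y[:n_ramp] *= ramp
    peak = np.max(np.abs(y))
    if peak > 0:
        y /= peak
    return y


def synthesize_stimulus(
    pattern: AccentPattern,
    tone: ToneModel | None = None,
    normalize_rms: bool = True,
) -> AudioStimulus:
    """Place one tone at each beat onset, scaled by the pattern's gains.

    Total duration is ``n_beats * ioi_s``.  When ``normalize_rms`` is true
    the waveform is rescaled to the 0.01 RMS reference.
    """
    tone = tone or ToneModel()
    if tone.duration_s > pattern.ioi_s:
        raise ValueError(
            f"tone duration {tone.duration_s} s exceeds inter-onset "
            f"interval {pattern.ioi_s} s (overlapping tones)"
        )
    fs = tone.fs_hz
    n_total = int(round(pattern.duration_s * fs))
    y = np.zeros(n_total)
    one_tone = synthesize_tone(tone)
    for k, gain in enumerate(pattern.accent_gains):
        start = int(round(k * pattern.ioi_s * fs))
        stop = min(start + one_tone.size, n_total)
        y[start:stop] += gain * one_tone[: stop - start]
    if normalize_rms:
        rms = np.sqrt(np.mean(np.square(y)))
        if rms == 0:
            raise ValueError("cannot RMS-normalise a silent stimulus")
        y *= RMS_REFERENCE / rms
    return AudioStimulus(samples=y, fs_hz=fs)


def tile_to_duration(stim: AudioStimulus, duration_s: float) -> AudioStimulus:
    """Repeat the whole stimulus an integer number of times to reach
    at least ``duration_s`` seconds (keeps the metrical period exact)."""
    if stim.samples.size == 0:
        raise ValueError("cannot tile an empty stimulus")
    n_rep = max(1, int(np.ceil(duration_s / stim.duration_s)))
    return AudioStimulus(samples=np.tile(stim.samples, n_rep), fs_hz=stim.fs_hz)


def envelope(stim: AudioStimulus, lp_hz: float = 30.0) -> AudioStimulus:
    """Slow amplitude envelope: analytic-signal magnitude, low-passed.

    The low-pass (default 30 Hz, zero-phase Butterworth) removes carrier
    ripple so only rhythm-band energy remains.
    """
    x = stim.samples
    if x.size == 0:
        raise ValueError("empty stimulus")
    # hilbert() does a full-length FFT; pad to a fast length for speed
    n = x.size
    env = np.abs(hilbert(x, N=next_fast_len(n))[:n])
    sos = butter(4, lp_hz, btype="low", fs=stim.fs_hz, output="sos")
    env = sosfiltfilt(sos, env)
    return AudioStimulus(samples=np.maximum(env, 0.0), fs_hz=stim.fs_hz)


def spectrum_of(
    signal: AudioStimulus | np.ndarray,
    resolution_hz: float,
    fs_hz: float | None = None,
    allow_padding: bool = True,
) -> Spectrum:
    """One-sided power spectrum on a grid of integer multiples of
    ``resolution_hz``.

    The signal is zero-padded up to the next integer multiple of
    ``1/resolution_hz`` seconds so that every grid frequency is an exact
    FFT bin; only the bins at multiples of ``resolution_hz`` are returned.
    Power is ``(2/N)^2 |X|^2 / 2`` (on-bin sinusoid of amplitude a has
    power a^2/2), arbitrary units squared.
    """
    if isinstance(signal, AudioStimulus):
        x, fs = signal.samples, signal.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz is required when passing a bare array")
        x, fs = np.asarray(signal, dtype=float), fs_hz
    if resolution_hz <= 0:
        raise ValueError("resolution_hz must be positive")
    n_res = fs / resolution_hz
    if abs(n_res - round(n_res)) > 1e-6:
        raise ValueError("fs_hz / resolution_hz must be an integer")
    n_res = int(round(n_res))
    if x.size < n_res and not allow_padding:
        raise ValueError(
            f"signal shorter than 1/resolution_hz = {1 / resolution_hz:.3f} s "
            "and zero-padding not requested"
        )
    q = max(1, int(np.ceil(x.size / n_res)))
    n_fft = n_res * q
    X = rfft(x, n_fft)
    # keep every q-th fine bin -> exact multiples of resolution_hz
    X = X[::q]
    n_sig = x.size
    power = 0.5 * np.square(2.0 * np.abs(X) / n_sig)
    freqs = np.arange(X.size) * resolution_hz
    return Spectrum(freqs_hz=freqs, power=power, resolution_hz=resolution_hz)


def find_peak(spec: Spectrum, band_hz: tuple[float, float]) -> SpectralPeak:
    """Maximum-power bin in the closed band; ties go to the lower frequency."""
    lo, hi = band_hz
    if lo > hi:
        raise ValueError(f"empty band [{lo}, {hi}]")
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not np.any(mask):
        raise ValueError(f"band [{lo}, {hi}] Hz contains no grid bins")
    f_band = spec.freqs_hz[mask]
    p_band = spec.power[mask]
    i = int(np.argmax(p_band))  # argmax returns the first (= lowest) maximum
    return SpectralPeak(freq_hz=float(f_band[i]), power=float(p_band[i]), band_hz=(lo, hi))


#: peak-search bands (Hz) used throughout: beat, then meter per condition
BEAT_BAND = (3.2, 3.5)
METER_BANDS = {"duple": (1.6, 1.9), "triple": (1.0, 1.4)}


def stimulus_beat_meter_ratio(
    spec: Spectrum,
    meter_label: str,
    beat_band: tuple[float, float] = BEAT_BAND,
    meter_band: tuple[float, float] | None = None,
) -> float:
    """Beat-band peak power divided by meter-band peak power."""
    _check_meter(meter_label)
    meter_band = meter_band or METER_BANDS[meter_label]
    p_beat = find_peak(spec, beat_band)
    p_meter = find_peak(spec, meter_band)
    if p_meter.power == 0:
        raise ValueError("meter-band power is zero; ratio undefined")
    return p_beat.power / p_meter.power


def write_wav(stim: AudioStimulus, path: str | Path, params: dict | None = None) -> None:
    """Write float32 WAV plus a JSON sidecar of synthesis parameters."""
    path = Path(path)
    wavfile.write(path, int(round(stim.fs_hz)), stim.samples.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"fs_hz": stim.fs_hz, "n_samples": int(stim.samples.size), "rms": stim.rms}
    if params:
        meta.update(params)
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    arr = np.column_stack([spec.freqs_hz, spec.power])
    np.savetxt(path, arr, delimiter=",", header="freq_hz,power", comments="")
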