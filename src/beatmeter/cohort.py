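"""Synthetic cohort generator: sensor blocks, ECG, and the latent coupling.

The generator emulates the study conditions end to end so every analysis
stage can be tested by parameter recovery:

* **Sensor blocks** — per task condition, a multichannel recording
  (default 20 channels, 1000 Hz, ~6 min) in which each of 30 stimulus
  repetitions contributes two phase-locked sinusoids: one at the 3.333 Hz
  beat frequency and one at the meter frequency (1.667 Hz duple /
  1.111 Hz triple), over additive 1/f-like channel noise.  The subject's
  latent ``log10_ratio`` sets the squared amplitude ratio of the two
  components, so the frequency-tagging chain should read it back.
* **Cardiac data** — an IBI series with a prescribed RMSSD (stationary
  Gaussian fluctuation around the mean IBI whose successive-difference
  standard deviation equals the target), rendered into an ECG-like trace
  with one stereotyped QRS transient per beat.
* **Coupling** — the latent link the statistics stage must recover:
  ``log10(RMSSD) = intercept + slope * log10(ratio) + noise``.  The
  built-in profiles carry the duple-condition estimates
  (slope −0.56, intercept 1.83, residual noise calibrated to R² = 0.481)
  and the triple-condition estimates (−0.29, 1.74, R² = 0.23).
  Rest-condition RMSSD is the subject's mean task RMSSD plus a fixed
  positive offset (default 6.3 ms, echoing the rest-above-task ordering
  55.18 vs 48.9 ms).

One root seed drives everything; per-subject and per-condition substreams
are spawned deterministically, so identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np

from .entrainment import SensorTimeSeries
from .hrv import IBISeries
from .stimulus import BEAT_HZ, METER_HZ, METER_PERIODS

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "PROFILES",
    "profile_config",
    "powerlaw_noise",
    "simulate_evoked_block",
    "simulate_ibi_series",
    "render_ecg",
    "generate_cohort",
    "iter_cohort",
]

#: cohort distribution of the true log10 beat-to-meter ratio.  Centre is the
#: log of the reported group-mean ratio (~2.5); the spread reproduces a
#: between-subject ratio SD of ~1.2 around a mean of ~2.48 (CV ~0.49) on the
#: log10 scale.
MU_LOG10_RATIO = {"duple": float(np.log10(2.48)), "triple": float(np.log10(2.52))}
SD_LOG10_RATIO = 0.21


def _noise_sd_for_r2(slope: float, sd_x: float, r2: float) -> float:
    """Residual SD giving the requested R^2 for y = a + b x + e."""
    return abs(slope) * sd_x * float(np.sqrt(1.0 / r2 - 1.0))


#: named coupling profiles: the duple- and triple-condition regression
#: estimates, with residual noise calibrated to the corresponding R².
PROFILES = {
    "duple": {
        "coupling_slope": -0.56,
        "coupling_intercept": 1.83,
        "coupling_noise_sd": _noise_sd_for_r2(-0.56, SD_LOG10_RATIO, 0.481),
        "mu_log10_ratio": MU_LOG10_RATIO["duple"],
        "sd_log10_ratio": SD_LOG10_RATIO,
        "task_meter": "duple",
    },
    "triple": {
        "coupling_slope": -0.29,
        "coupling_intercept": 1.74,
        "coupling_noise_sd": _noise_sd_for_r2(-0.29, SD_LOG10_RATIO, 0.23),
        "mu_log10_ratio": MU_LOG10_RATIO["triple"],
        "sd_log10_ratio": SD_LOG10_RATIO,
        "task_meter": "triple",
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study conditions: 15 subjects, rest + duple +
    triple conditions, 1000 Hz sampling, ~6 min task blocks of 30 stimulus
    repetitions with 2 s gaps, 850 ms mean IBI.
    """

    n_subjects: int = 15
    conditions: tuple[str, ...] = ("rest", "duple", "triple")
    mu_log10_ratio: float = MU_LOG10_RATIO["duple"]
    sd_log10_ratio: float = SD_LOG10_RATIO
    coupling_slope: float = -0.56
    coupling_intercept: float = 1.83
    coupling_noise_sd: float = PROFILES["duple"]["coupling_noise_sd"]
    rest_rmssd_offset_ms: float = 6.3
    mean_ibi_ms: float = 850.0
    ibi_ar1: float = 0.0
    n_channels: int = 20
    block_s: float = 360.0
    rest_s: float = 300.0
    n_reps: int = 30
    gap_s: float = 2.0
    stim_duration_s: dict | None = None  # per meter; default 9.6 duple / 9.9 triple
    snr_single_epoch_db: float = -10.0
    noise_exponent: float = 1.0
    noise_white_frac: float = 0.1
    ecg_snr_db: float = 20.0
    fs_neural_hz: float = 1000.0
    fs_ecg_hz: float = 1000.0
    seed: int = 0

    def stim_duration(self, meter_label: str) -> float:
        if self.stim_duration_s is not None:
            return self.stim_duration_s[meter_label]
        # whole measures closest to ~10 s at 0.3 s IOI:
        # duple 16 measures x 0.6 s = 9.6 s, triple 11 x 0.9 s = 9.9 s
        return {"duple": 9.6, "triple": 9.9}[meter_label]

    def validate(self) -> None:
        checks = [
            ("n_subjects", self.n_subjects >= 2),
            ("sd_log10_ratio", self.sd_log10_ratio >= 0),
            ("coupling_noise_sd", self.coupling_noise_sd >= 0),
            ("mean_ibi_ms", self.mean_ibi_ms > 0),
            ("n_channels", self.n_channels >= 1),
            ("n_reps", self.n_reps >= 1),
            ("gap_s", self.gap_s >= 0),
            ("block_s", self.block_s > 0),
            ("fs_neural_hz", self.fs_neural_hz > 0),
            ("fs_ecg_hz", self.fs_ecg_hz > 0),
            ("conditions", len(self.conditions) >= 1
             and all(c in ("rest", "duple", "triple") for c in self.conditions)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid CohortConfig field: {name}")
        for meter in self.conditions:
            if meter == "rest":
                continue
            need = self.n_reps * (self.stim_duration(meter) + self.gap_s)
            if self.block_s < 0.95 * need:
                raise ValueError(
                    f"invalid CohortConfig field: block_s ({self.block_s} s) cannot "
                    f"hold {self.n_reps} x {self.stim_duration(meter)}+{self.gap_s} s"
                )


def profile_config(name: str, **overrides) -> CohortConfig:
    """A :class:`CohortConfig` preset to a named coupling profile."""
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    params = {k: v for k, v in PROFILES[name].items() if k != "task_meter"}
    params.update(overrides)
    return CohortConfig(**params)


@dataclass
class SubjectRecord:
    """One subject's simulated data plus the generating ground truth."""

    subject_id: str
    sensor: dict[str, SensorTimeSeries] = field(default_factory=dict)
    event_times: dict[str, np.ndarray] = field(default_factory=dict)
    ecg: dict[str, np.ndarray] = field(default_factory=dict)
    ecg_peak_times: dict[str, np.ndarray] = field(default_factory=dict)
    ibi_series: dict[str, IBISeries] = field(default_factory=dict)
    true_log10_ratio: dict[str, float] = field(default_factory=dict)
    true_rmssd_ms: dict[str, float] = field(default_factory=dict)


def powerlaw_noise(
    n: int, fs_hz: float, exponent: float, rng: np.random.Generator,
    white_frac: float = 0.1,
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise with a white floor.

    Shaped in the frequency domain: amplitude ∝ sqrt(1/f^exponent +
    white_frac) with random phases; normalised to std 1.
    """
    if n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = np.sqrt(1.0 / np.power(freqs[1:], exponent) + white_frac)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def simulate_evoked_block(
    true_log10_ratio: float,
    meter_label: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[SensorTimeSeries, np.ndarray]:
    """Sensor block with phase-locked beat + meter components per repetition.

    Amplitudes satisfy ``(A_beat / A_meter)^2 = 10**true_log10_ratio`` with
    ``A_meter`` fixed at 1; both components run for the stimulus duration
    after each event onset, phase zero at onset.  Channel noise is
    1/f^noise_exponent scaled so the single-epoch, single-channel SNR
    (component power over noise power) equals ``snr_single_epoch_db``;
    per-channel gains vary so that only the ratio, not absolute power, is
    comparable across channels.  Returns the block and the event onsets (s).
    """
    if not np.isfinite(true_log10_ratio):
        raise ValueError("true_log10_ratio must be finite")
    if meter_label not in METER_PERIODS:
        raise ValueError(f"meter_label must be one of {sorted(METER_PERIODS)}")
    fs = config.fs_neural_hz
    n = int(round(config.block_s * fs))
    dur = config.stim_duration(meter_label)
    a_meter = 1.0
    a_beat = float(10.0 ** (true_log10_ratio / 2.0))
    first = 1.5  # leave room for the -1 s epoch edge
    event_times = first + np.arange(config.n_reps) * (dur + config.gap_s)
    if event_times[-1] + dur > config.block_s:
        raise ValueError("repetitions do not fit inside block_s")
    signal = np.zeros(n)
    n_dur = int(round(dur * fs))
    t_rel = np.arange(n_dur) / fs
    rep = a_beat * np.sin(2 * np.pi * BEAT_HZ * t_rel) + a_meter * np.sin(
        2 * np.pi * METER_HZ[meter_label] * t_rel
    )
    for t0 in event_times:
        start = int(round(t0 * fs))
        signal[start : start + n_dur] += rep
    sig_power = 0.5 * (a_beat**2 + a_meter**2)
    noise_sd = float(np.sqrt(sig_power / 10.0 ** (config.snr_single_epoch_db / 10.0)))
    gains = rng.uniform(0.5, 1.5, size=config.n_channels)
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        noise = powerlaw_noise(n, fs, config.noise_exponent, rng,
                               white_frac=config.noise_white_frac)
        data[ch] = gains[ch] * (signal + noise_sd * noise)
    return SensorTimeSeries(data=data, fs_hz=fs, unit_label="a.u."), event_times


def simulate_ibi_series(
    true_rmssd_ms: float,
    duration_s: float,
    mean_ibi_ms: float,
    rng: np.random.Generator,
    ar1: float = 0.0,
) -> IBISeries:
    """IBI series with a prescribed RMSSD.

    IBIs are ``mean + x`` where ``x`` is stationary Gaussian (optionally
    AR(1) with coefficient ``ar1``) whose successive-difference standard
    deviation equals ``true_rmssd_ms``:  for marginal SD s and lag-1
    correlation phi, SD(diff) = s * sqrt(2 (1 - phi)).
    """
    if true_rmssd_ms < 0:
        raise ValueError("true_rmssd_ms must be >= 0")
    if duration_s <= 10.0 * mean_ibi_ms / 1000.0:
        raise ValueError("duration_s too short: need more than 10 mean IBIs")
    if not (0 <= ar1 < 1):
        raise ValueError("ar1 must be in [0, 1)")
    sd_x = true_rmssd_ms / np.sqrt(2.0 * (1.0 - ar1))
    if mean_ibi_ms - 6.0 * sd_x <= 0:
        raise ValueError(
            f"target RMSSD {true_rmssd_ms} ms too large for mean IBI "
            f"{mean_ibi_ms} ms (negative intervals likely)"
        )
    n_max = int(np.ceil(duration_s * 1000.0 / mean_ibi_ms)) + 10
    if sd_x == 0:
        x = np.zeros(n_max)
    elif ar1 == 0:
        x = sd_x * rng.standard_normal(n_max)
    else:
        innov_sd = sd_x * np.sqrt(1.0 - ar1**2)
        x = np.empty(n_max)
        x[0] = sd_x * rng.standard_normal()
        eps = innov_sd * rng.standard_normal(n_max)
        for k in range(1, n_max):
            x[k] = ar1 * x[k - 1] + eps[k]
    ibis = mean_ibi_ms + x
    cum = np.cumsum(ibis)
    keep = cum <= duration_s * 1000.0
    return IBISeries(ibis_ms=ibis[keep])


def _qrs_template(fs_hz: float, width_s: float = 0.015) -> np.ndarray:
    """Stereotyped QRS-like transient: a Mexican-hat wavelet, peak 1."""
    half = int(round(4 * width_s * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    u = (t / width_s) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def render_ecg(
    ibis: IBISeries,
    fs_hz: float,
    rng: np.random.Generator,
    snr_db: float = 20.0,
    wander_amp: float = 0.05,
    wander_hz: float = 0.3,
    t_start_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like trace with one QRS transient per beat.

    Returns ``(trace, peak_times_s)`` where the peak times are the ground
    truth.  White noise is added at ``snr_db`` (QRS peak amplitude over
    noise SD, in dB) plus a slow sinusoidal baseline wander.
    """
    if len(ibis) == 0:
        return np.zeros(0), np.zeros(0)
    if np.any(ibis.ibis_ms <= 300.0):
        raise ValueError("all IBIs must exceed 300 ms for ECG rendering")
    peak_times = t_start_s + np.concatenate([[0.0], np.cumsum(ibis.ibis_ms) / 1000.0])
    n = int(round((peak_times[-1] + t_start_s) * fs_hz)) + 1
    trace = np.zeros(n)
    tmpl = _qrs_template(fs_hz)
    half = tmpl.size // 2
    for t in peak_times:
        c = int(round(t * fs_hz))
        lo, hi = c - half, c + half + 1
        s_lo, s_hi = max(0, lo), min(n, hi)
        trace[s_lo:s_hi] += tmpl[s_lo - lo : tmpl.size - (hi - s_hi)]
    tt = np.arange(n) / fs_hz
    trace += wander_amp * np.sin(2 * np.pi * wander_hz * tt + rng.uniform(0, 2 * np.pi))
    if np.isfinite(snr_db):
        noise_sd = 10.0 ** (-snr_db / 20.0)
        trace += noise_sd * rng.standard_normal(n)
    return trace, peak_times


def _task_conditions(config: CohortConfig) -> list[str]:
    return [c for c in config.conditions if c != "rest"]


def iter_cohort(config: CohortConfig) -> Iterator[SubjectRecord]:
    """Yield subjects one at a time (constant memory for large cohorts)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    for i in range(config.n_subjects):
        yield _make_subject(config, i, subject_seeds[i])


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], dict]:
    """Materialise the whole cohort plus a ground-truth manifest."""
    records = list(iter_cohort(config))
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "subjects": {
            r.subject_id: {
                "true_log10_ratio": dict(r.true_log10_ratio),
                "true_rmssd_ms": dict(r.true_rmssd_ms),
            }
            for r in records
        },
    }
    return records, manifest


def _make_subject(
    config: CohortConfig, index: int, seed_seq: np.random.SeedSequence
) -> SubjectRecord:
    # independent substreams: latent draws, then one per condition stage
    streams = seed_seq.spawn(1 + 3 * len(config.conditions))
    latent_rng = np.random.default_rng(streams[0])
    rec = SubjectRecord(subject_id=f"S{index:03d}")
    tasks = _task_conditions(config)
    # latent coupling
    for cond in tasks:
        lr = config.mu_log10_ratio + config.sd_log10_ratio * latent_rng.standard_normal()
        log10_rmssd = (
            config.coupling_intercept
            + config.coupling_slope * lr
            + config.coupling_noise_sd * latent_rng.standard_normal()
        )
        rec.true_log10_ratio[cond] = float(lr)
        rec.true_rmssd_ms[cond] = float(10.0**log10_rmssd)
    if "rest" in config.conditions:
        task_mean = (
            float(np.mean([rec.true_rmssd_ms[c] for c in tasks]))
            if tasks else 10.0**config.coupling_intercept
        )
        rec.true_rmssd_ms["rest"] = task_mean + config.rest_rmssd_offset_ms
    # rendered data
    for j, cond in enumerate(config.conditions):
        rng_sensor = np.random.default_rng(streams[1 + 3 * j])
        rng_ibi = np.random.default_rng(streams[2 + 3 * j])
        rng_ecg = np.random.default_rng(streams[3 + 3 * j])
        duration = config.rest_s if cond == "rest" else config.block_s
        ibis = simulate_ibi_series(
            rec.true_rmssd_ms[cond], duration, config.mean_ibi_ms, rng_ibi,
            ar1=config.ibi_ar1,
        )
        trace, peak_times = render_ecg(
            ibis, config.fs_ecg_hz, rng_ecg, snr_db=config.ecg_snr_db
        )
        rec.ibi_series[cond] = ibis
        rec.ecg[cond] = trace
        rec.ecg_peak_times[cond] = peak_times
        if cond != "rest":
            block, events = simulate_evoked_block(
                rec.true_log10_ratio[cond], cond, config, rng_sensor
            )
            rec.sensor[cond] = block
            rec.event_times[cond] = events
    return rec
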