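"""File formats, run configuration, and the end-to-end pipeline.

Interchange conventions: CSV with documented column names; times in
seconds from block onset, intervals in ms, frequencies in Hz, power in
arbitrary units squared.  Every output directory receives a serialized
copy of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import entrainment as ent
from . import hrv as hrv_mod
from . import stats as stats_mod
from .cohort import CohortConfig, profile_config
from .stimulus import BEAT_BAND, METER_BANDS

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "read_evoked_csv",
    "write_evoked_csv",
    "read_ecg_txt",
    "write_ecg_txt",
    "read_ibi_csv",
    "write_ibi_csv",
    "write_ratios_csv",
    "read_ratios_csv",
    "write_hrv_csv",
    "read_hrv_csv",
    "write_sensor_block_txt",
    "read_sensor_block_txt",
]

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["subject", "condition", "f_beat_hz", "p_beat", "f_meter_hz", "p_meter", "ratio"]
HRV_COLUMNS = ["subject", "condition", "n_ibis", "rmssd_ms"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation → analysis → stats run."""

    profile: str = "duple"
    cohort_overrides: dict = field(default_factory=dict)
    resolution_hz: float = 0.05
    filter_lo_hz: float = 0.1
    filter_hi_hz: float = 40.0
    tmin_s: float = -1.0
    tmax_s: float = 11.0
    beat_band: tuple[float, float] = BEAT_BAND
    meter_bands: dict = field(default_factory=lambda: dict(METER_BANDS))
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "beatmeter_run"

    def validate(self) -> None:
        if self.resolution_hz <= 0:
            raise ValueError("invalid RunConfig field: resolution_hz")
        if not (0 < self.filter_lo_hz < self.filter_hi_hz):
            raise ValueError("invalid RunConfig field: filter_lo_hz/filter_hi_hz")
        if self.n_boot < 1:
            raise ValueError("invalid RunConfig field: n_boot")
        if self.tmin_s >= self.tmax_s:
            raise ValueError("invalid RunConfig field: tmin_s/tmax_s")
        self.cohort_config().validate()

    def cohort_config(self) -> CohortConfig:
        return profile_config(self.profile, seed=self.seed, **self.cohort_overrides)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["beat_band"] = list(self.beat_band)
        d["meter_bands"] = {k: list(v) for k, v in self.meter_bands.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "beat_band" in d:
            d["beat_band"] = tuple(d["beat_band"])
        if "meter_bands" in d:
            d["meter_bands"] = {k: tuple(v) for k, v in d["meter_bands"].items()}
        return cls(**d)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------- file formats

def write_evoked_csv(evoked: ent.EvokedResponse, path: str | Path) -> None:
    """Pre-averaged evoked as CSV: first column time_s, one column per channel."""
    n = evoked.data.shape[1]
    t = evoked.tmin_s + np.arange(n) / evoked.fs_hz
    cols = {"time_s": t}
    for ch in range(evoked.data.shape[0]):
        cols[f"ch{ch:03d}"] = evoked.data[ch]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_evoked_csv(path: str | Path, n_epochs_averaged: int = 1) -> ent.EvokedResponse:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("evoked CSV needs at least 2 samples")
    fs = 1.0 / float(np.mean(np.diff(t)))
    data = df.drop(columns=["time_s"]).to_numpy().T
    return ent.EvokedResponse(
        data=data, fs_hz=fs, tmin_s=float(t[0]),
        tmax_s=float(t[0] + data.shape[1] / fs),
        n_epochs_averaged=n_epochs_averaged,
    )


def write_ecg_txt(trace: np.ndarray, fs_hz: float, path: str | Path) -> None:
    """Single-column text with a `# fs_hz=<rate>` header line."""
    np.savetxt(path, np.asarray(trace, float), header=f"fs_hz={fs_hz}")


def read_ecg_txt(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "fs_hz=" not in first:
        raise ValueError(f"{path}: missing '# fs_hz=<rate>' header")
    fs = float(first.split("fs_hz=")[1])
    return np.loadtxt(path), fs


def write_ibi_csv(ibis: hrv_mod.IBISeries, path: str | Path) -> None:
    """Two-column CSV: beat index, ibi_ms."""
    pd.DataFrame({"beat": np.arange(len(ibis)), "ibi_ms": ibis.ibis_ms}).to_csv(
        path, index=False
    )


def read_ibi_csv(path: str | Path) -> hrv_mod.IBISeries:
    return hrv_mod.IBISeries(ibis_ms=pd.read_csv(path)["ibi_ms"].to_numpy())


def write_sensor_block_txt(ts: ent.SensorTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, header=f"fs_hz={ts.fs_hz} unit={ts.unit_label}")


def read_sensor_block_txt(path: str | Path) -> ent.SensorTimeSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if "fs_hz=" not in first:
        raise ValueError(f"{path}: missing fs_hz header")
    fs = float(first.split("fs_hz=")[1].split()[0])
    unit = first.split("unit=")[1].split()[0] if "unit=" in first else "a.u."
    return ent.SensorTimeSeries(data=np.loadtxt(path), fs_hz=fs, unit_label=unit)


def write_ratios_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=RATIO_COLUMNS).to_csv(path, index=False)


def read_ratios_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratios CSV missing columns {sorted(missing)}")
    return df


def write_hrv_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=HRV_COLUMNS).to_csv(path, index=False)


def read_hrv_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(HRV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"HRV CSV missing columns {sorted(missing)}")
    return df


# ----------------------------------------------------------- analysis helpers

def analyze_sensor_block(
    block: ent.SensorTimeSeries,
    event_times: np.ndarray,
    condition: str,
    config: RunConfig,
) -> ent.BeatMeterRatio:
    """Band-pass → epoch/average → Welch PSD → beat-to-meter ratio."""
    filtered = ent.bandpass(block, config.filter_lo_hz, config.filter_hi_hz)
    evoked = ent.epoch_and_average(filtered, event_times, config.tmin_s, config.tmax_s)
    psd = ent.welch_psd(evoked, config.resolution_hz)
    return ent.extract_ratio(
        psd, condition, beat_band=config.beat_band,
        meter_band=config.meter_bands.get(condition),
    )


def analyze_ecg(trace: np.ndarray, fs_hz: float, condition: str) -> hrv_mod.HRVResult:
    """R-peak detection → IBIs → RMSSD."""
    peaks = hrv_mod.detect_r_peaks(trace, fs_hz)
    ibis = hrv_mod.ibis_from_peaks(peaks)
    return hrv_mod.rmssd(ibis, condition=condition)


# ------------------------------------------------------------------ pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, run both analysis chains, and compute the stats.

    Writes ``ratios.csv``, ``hrv.csv``, bootstrap distribution CSVs,
    ``report.json``, ``report.md`` and a config copy into
    ``config.out_dir``; returns the report dictionary.  Subjects are
    processed one at a time so memory stays flat in the cohort size.
    """
    try:
        config.validate()
    except ValueError as e:
        raise PipelineError(f"config: {e}") from e
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")
    cohort_cfg = config.cohort_config()
    logger.info("pipeline: cohort of %d subjects, profile %s, seed %d",
                cohort_cfg.n_subjects, config.profile, config.seed)

    ratio_rows: list[dict] = []
    hrv_rows: list[dict] = []
    try:
        for rec in cohort_mod.iter_cohort(cohort_cfg):
            for cond in cohort_cfg.conditions:
                if cond != "rest":
                    bm = analyze_sensor_block(
                        rec.sensor[cond], rec.event_times[cond], cond, config
                    )
                    ratio_rows.append({
                        "subject": rec.subject_id, "condition": cond,
                        "f_beat_hz": bm.f_beat_hz, "p_beat": bm.p_beat,
                        "f_meter_hz": bm.f_meter_hz, "p_meter": bm.p_meter,
                        "ratio": bm.ratio,
                    })
                res = analyze_ecg(rec.ecg[cond], cohort_cfg.fs_ecg_hz, cond)
                hrv_rows.append({
                    "subject": rec.subject_id, "condition": cond,
                    "n_ibis": res.n_ibis, "rmssd_ms": res.rmssd_ms,
                })
    except (ValueError, hrv_mod.NoPeaksError) as e:
        raise PipelineError(f"analysis: {e}") from e

    write_ratios_csv(ratio_rows, out / "ratios.csv")
    write_hrv_csv(hrv_rows, out / "hrv.csv")
    logger.info("pipeline: %d ratio rows, %d HRV rows", len(ratio_rows), len(hrv_rows))

    ratios = pd.DataFrame(ratio_rows)
    hrv_df = pd.DataFrame(hrv_rows)
    report: dict = {
        "n_subjects": cohort_cfg.n_subjects,
        "seed": config.seed,
        "profile": config.profile,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "conditions": list(cohort_cfg.conditions),
    }
    try:
        report.update(compute_stats(ratios, hrv_df, config, out))
    except stats_mod.DegenerateDataError as e:
        raise PipelineError(f"stats degenerate: {e}") from e
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(_report_markdown(report))
    return report


def compute_stats(
    ratios: pd.DataFrame, hrv_df: pd.DataFrame, config: RunConfig, out: Path | None = None
) -> dict:
    """The inference layer on tidy ratio/HRV tables (also usable standalone)."""
    report: dict = {}
    hrv_wide = hrv_df.pivot(index="subject", columns="condition", values="rmssd_ms")
    conds = [c for c in ("rest", "duple", "triple") if c in hrv_wide.columns]
    if len(conds) >= 2 and not hrv_wide[conds].isna().any().any():
        an = stats_mod.rm_anova_gg(hrv_wide[conds].to_numpy(), conds)
        report["hrv_anova"] = {
            "F": an.F, "df1": an.df1, "df2": an.df2, "epsilon": an.epsilon,
            "p_gg": an.p_gg, "eta2": an.eta2, "posthoc": an.posthoc,
            "condition_means_ms": {c: float(hrv_wide[c].mean()) for c in conds},
        }
    report["bootstrap_ratio"] = {}
    report["regression"] = {}
    for cond, grp in ratios.groupby("condition"):
        boot, samples = stats_mod.bootstrap_mean(
            grp["ratio"].to_numpy(), n_reps=config.n_boot, seed=config.seed,
            return_samples=True,
        )
        report["bootstrap_ratio"][cond] = {
            "mean": boot.mean, "ci_lo": boot.ci_lo, "ci_hi": boot.ci_hi,
            "n_reps": boot.n_reps, "seed": boot.seed,
        }
        if out is not None:
            pd.DataFrame({"resample_mean": samples}).to_csv(
                out / f"bootstrap_ratio_{cond}.csv", index=False
            )
        merged = grp.merge(
            hrv_df[hrv_df["condition"] == cond], on=["subject", "condition"]
        )
        fit = stats_mod.loglog_regression(
            merged["ratio"].to_numpy(), merged["rmssd_ms"].to_numpy()
        )
        report["regression"][cond] = {
            "r": fit.r, "r2": fit.r2, "slope": fit.slope,
            "intercept": fit.intercept, "p": fit.p, "n": fit.n,
        }
        if out is not None:
            merged.assign(
                log10_ratio=np.log10(merged["ratio"]),
                log10_rmssd=np.log10(merged["rmssd_ms"]),
            )[["subject", "log10_ratio", "log10_rmssd"]].to_csv(
                out / f"scatter_{cond}.csv", index=False
            )
    rest = hrv_df[hrv_df["condition"] == "rest"].set_index("subject")["rmssd_ms"]
    if len(rest):
        report["rest_hrv_vs_ratio"] = {}
        for cond, grp in ratios.groupby("condition"):
            g = grp.set_index("subject")
            common = g.index.intersection(rest.index)
            if len(common) >= 3:
                r, p = stats_mod.pearson(
                    g.loc[common, "ratio"].to_numpy(), rest.loc[common].to_numpy()
                )
                report["rest_hrv_vs_ratio"][cond] = {"r": r, "p": p, "n": int(len(common))}
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Beat/meter entrainment & HRV report", ""]
    lines.append(f"- subjects: {report['n_subjects']}; seed: {report['seed']}; "
                 f"profile: {report['profile']}")
    if "hrv_anova" in report:
        a = report["hrv_anova"]
        lines += ["", "## RMSSD repeated-measures ANOVA",
                  f"F({a['df1']}, {a['df2']}) = {a['F']:.3f}, "
                  f"Greenhouse-Geisser epsilon = {a['epsilon']:.3f}, "
                  f"p_GG = {a['p_gg']:.4f}, partial eta^2 = {a['eta2']:.3f}",
                  "", "| condition | mean RMSSD (ms) |", "|---|---|"]
        lines += [f"| {c} | {m:.2f} |" for c, m in a["condition_means_ms"].items()]
        lines += ["", "| pair | t | p (Bonferroni) |", "|---|---|---|"]
        lines += [f"| {p['a']} vs {p['b']} | {p['t']:.3f} | {p['p_bonferroni']:.4f} |"
                  for p in a["posthoc"]]
    if report.get("bootstrap_ratio"):
        lines += ["", "## Bootstrap mean beat-to-meter ratio",
                  "| condition | mean | 95% CI |", "|---|---|---|"]
        lines += [f"| {c} | {b['mean']:.3f} | [{b['ci_lo']:.3f}, {b['ci_hi']:.3f}] |"
                  for c, b in report["bootstrap_ratio"].items()]
    if report.get("regression"):
        lines += ["", "## log10(RMSSD) ~ log10(beat-to-meter ratio)",
                  "| condition | slope | intercept | r | R^2 | p | n |",
                  "|---|---|---|---|---|---|---|"]
        lines += [f"| {c} | {g['slope']:.3f} | {g['intercept']:.3f} | {g['r']:.3f} | "
                  f"{g['r2']:.3f} | {g['p']:.4f} | {g['n']} |"
                  for c, g in report["regression"].items()]
    if report.get("rest_hrv_vs_ratio"):
        lines += ["", "## Resting RMSSD vs task beat-to-meter ratio (Pearson)",
                  "| condition | r | p | n |", "|---|---|---|---|"]
        lines += [f"| {c} | {g['r']:.3f} | {g['p']:.4f} | {g['n']} |"
                  for c, g in report["rest_hrv_vs_ratio"].items()]
    return "\n".join(lines) + "\n"
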