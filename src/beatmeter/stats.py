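"""Group- and individual-level inference.

* one-way repeated-measures ANOVA with Greenhouse–Geisser sphericity
  correction and Bonferroni-corrected paired post hocs (HRV across
  rest / duple / triple),
* subject-resampling bootstrap of the mean beat-to-meter ratio with a
  percentile 95% interval,
* ordinary least squares of log10(RMSSD) on log10(beat-to-meter ratio),
* plain Pearson correlations, and a signed-rank convenience wrapper.

Log transforms use base 10 throughout so regression intercepts are
interpretable as log10(ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "AnovaResult",
    "BootstrapResult",
    "RegressionResult",
    "rm_anova_gg",
    "bootstrap_mean",
    "loglog_regression",
    "pearson",
    "signed_rank",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    epsilon: float
    p_uncorrected: float
    p_gg: float
    eta2: float
    posthoc: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci_lo: float
    ci_hi: float
    n_reps: int
    seed: int


@dataclass(frozen=True)
class RegressionResult:
    r: float
    r2: float
    slope: float
    intercept: float
    p: float
    n: int


def rm_anova_gg(
    values: np.ndarray, condition_labels: list[str] | None = None
) -> AnovaResult:
    """One-way within-subject ANOVA on a subjects × conditions table.

    The Greenhouse–Geisser epsilon is computed from the double-centred
    covariance matrix of the conditions and applied multiplicatively to
    both degrees of freedom.  ``eta2`` is partial eta squared,
    SS_condition / (SS_condition + SS_error).  Post hocs are paired
    t-tests with Bonferroni multiply-and-cap p-values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D subjects x conditions table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed")
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = x - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = float(ms_cond / ms_err) if ms_err > 0 else 0.0
    # Greenhouse-Geisser epsilon from the double-centred covariance
    S = np.cov(x, rowvar=False, ddof=1)
    Sdc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    denom = (k - 1) * np.sum(Sdc**2)
    eps = float(np.trace(Sdc) ** 2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p_unc = float(sps.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
    eta2 = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    labels = condition_labels or [f"c{j}" for j in range(k)]
    pairs = list(combinations(range(k), 2))
    posthoc = []
    for a, b in pairs:
        d = x[:, a] - x[:, b]
        if np.allclose(d, d[0]):
            t, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(x[:, a], x[:, b])
        posthoc.append({
            "a": labels[a], "b": labels[b],
            "t": float(t), "p_uncorrected": float(p),
            "p_bonferroni": float(min(1.0, p * len(pairs))),
        })
    return AnovaResult(F=F, df1=df1, df2=df2, epsilon=eps,
                       p_uncorrected=p_unc, p_gg=p_gg, eta2=eta2, posthoc=posthoc)


def bootstrap_mean(
    values: np.ndarray, n_reps: int = 1000, seed: int = 0,
    return_samples: bool = False,
):
    """Bootstrap the mean by resampling subjects with replacement.

    Reports the mean of the resample means and the percentile 2.5/97.5
    interval; fully determined by ``seed``.  With ``return_samples`` the
    resample means are returned alongside (for distribution plots/files).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_reps, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    result = BootstrapResult(mean=float(means.mean()), ci_lo=float(lo),
                             ci_hi=float(hi), n_reps=n_reps, seed=seed)
    return (result, means) if return_samples else result


def loglog_regression(x_ratio: np.ndarray, y_rmssd: np.ndarray) -> RegressionResult:
    """OLS of log10(y) on log10(x) with the Pearson r of the transformed data."""
    x = np.asarray(x_ratio, dtype=float)
    y = np.asarray(y_rmssd, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    for name, arr in (("x_ratio", x), ("y_rmssd", y)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(f"{name} must be strictly positive; offending index {bad[0]}")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DegenerateDataError("zero variance after log transform; r undefined")
    fit = sps.linregress(lx, ly)
    return RegressionResult(r=float(fit.rvalue), r2=float(fit.rvalue**2),
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            p=float(fit.pvalue), n=int(x.size))


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Related-samples Wilcoxon signed-rank test (statistic, p)."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
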