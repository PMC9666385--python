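"""Fit-comparison statistics: corrected AIC, effective degrees of
freedom, relative likelihood, and intraclass correlation.

Trace residuals are strongly autocorrelated, so the nominal sample count
overstates the information in a fit.  Assuming normally distributed but
correlated residuals, the log-likelihood is
``ln L = N/2 (-ln MSE - 1 - ln 2pi)`` with N the *effective* degrees of
freedom, estimated by a Satterthwaite-Welch argument from the
autocorrelation of the pre-perturbation (baseline) data: if R is the
implied Toeplitz correlation matrix over the scored window,
``N = (tr R)^2 / tr(R^2)``.  Dividing AIC by N gives a per-degree-of-
freedom score,

    cAIC = AIC / N = 2 k / N + ln(MSE) + 1 + ln(2 pi),

comparable across datasets of different lengths.  Two models differing
in cAIC by more than ``2 ln(20) / N`` stand in at least a 20:1 relative
likelihood (the conventional 95% support level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CaicResult",
    "IccResult",
    "caic",
    "caic_threshold",
    "relative_likelihood",
    "combined_crossval_caic",
    "effective_df",
    "effective_df_from_autocorr",
    "baseline_autocorrelation",
    "icc",
]

_LN2PI = float(np.log(2.0 * np.pi))


def caic(k: int, mse: float, n_eff: float) -> float:
    """Corrected AIC: 2k/N + ln(MSE) + 1 + ln(2*pi)."""
    if mse <= 0:
        raise ValueError("MSE must be positive")
    if n_eff <= 0:
        raise ValueError("effective degrees of freedom must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(2.0 * k / n_eff + np.log(mse) + 1.0 + _LN2PI)


def caic_threshold(n_eff: float) -> float:
    """cAIC margin supporting a 20:1 relative likelihood: 2 ln(20) / N."""
    if n_eff <= 0:
        raise ValueError("effective degrees of freedom must be positive")
    return float(2.0 * np.log(20.0) / n_eff)


def relative_likelihood(aic_min: float, aic: float) -> float:
    """exp((AIC_min - AIC)/2); the evidence for a model relative to the best."""
    if aic < aic_min:
        raise ValueError("aic_min must be the smaller value")
    return float(np.exp((aic_min - aic) / 2.0))


def combined_crossval_caic(
    test_mses, test_dfs, n_trials: int, k: int
) -> float:
    """Out-of-sample cAIC over a set of held-out trials.

    MSE is the mean of the per-trial test MSEs; N is the mean per-trial
    effective df multiplied by the number of trials.
    """
    test_mses = np.asarray(test_mses, dtype=float)
    test_dfs = np.asarray(test_dfs, dtype=float)
    if test_mses.size == 0 or test_dfs.size == 0:
        raise ValueError("empty MSE or df input")
    if np.any(test_dfs <= 0):
        raise ValueError("effective dfs must be positive")
    return caic(k, float(np.mean(test_mses)), float(np.mean(test_dfs)) * n_trials)


def baseline_autocorrelation(segments, max_lag: int | None = None) -> np.ndarray:
    """Pooled autocorrelation of pre-onset segments.

    Each segment is demeaned; autocovariances are averaged across
    segments (weighted by the number of lagged products) and normalized
    by the pooled lag-0 autocovariance.  Estimates are tapered to zero
    from the first lag whose magnitude drops below the 2/sqrt(n_total)
    significance bound, so sampling noise at long lags cannot collapse
    the effective degrees of freedom.
    """
    segs = [np.asarray(s, dtype=float) - np.mean(s) for s in segments]
    if not segs or any(s.size < 2 for s in segs):
        raise ValueError("need at least one segment with >= 2 samples")
    n_total = sum(s.size for s in segs)
    longest = max(s.size for s in segs)
    if max_lag is None:
        max_lag = longest - 1
    max_lag = min(max_lag, longest - 1)

    gamma = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for s in segs:
        for k in range(min(max_lag, s.size - 1) + 1):
            gamma[k] += np.sum(s[k:] * s[: s.size - k])
            counts[k] += s.size  # per-segment normalization by n, as usual for acf
    if gamma[0] <= 0:
        raise ValueError("degenerate (constant) baseline segments")
    rho = np.where(counts > 0, gamma / np.maximum(counts, 1), 0.0)
    rho = rho / rho[0]

    cutoff = 2.0 / np.sqrt(n_total)
    insignificant = np.abs(rho[1:]) < cutoff
    if np.any(insignificant):
        first = int(np.argmax(insignificant)) + 1
        rho[first:] = 0.0
    return rho


def effective_df_from_autocorr(rho: np.ndarray, n: int) -> float:
    """Satterthwaite-Welch effective df for a length-n window whose
    residual correlation is Toeplitz with autocorrelations ``rho``.

    N = (tr R)^2 / tr(R^2) = n^2 / (n + 2 sum_k (n - k) rho_k^2),
    clipped to [1, n].
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    rho = np.asarray(rho, dtype=float)
    lags = np.arange(1, min(rho.size, n))
    tr_r2 = n + 2.0 * float(np.sum((n - lags) * rho[lags] ** 2))
    return float(np.clip(n * n / tr_r2, 1.0, n))


def effective_df(baseline_segments, n: int) -> float:
    """Effective degrees of freedom of a scored window of length ``n``,
    from the pooled autocorrelation of pre-onset baseline segments."""
    rho = baseline_autocorrelation(baseline_segments)
    return effective_df_from_autocorr(rho, n)


@dataclass(frozen=True)
class CaicResult:
    """A cAIC evaluation bundled with its ingredients."""

    k: int
    mse: float
    n_eff: float
    value: float
    threshold: float

    @classmethod
    def evaluate(cls, k: int, mse: float, n_eff: float) -> "CaicResult":
        return cls(k=k, mse=mse, n_eff=n_eff,
                   value=caic(k, mse, n_eff), threshold=caic_threshold(n_eff))


@dataclass(frozen=True)
class IccResult:
    """Per-parameter reliability across repeated estimates."""

    sigma_between: float
    sigma_within: float
    icc: float

    @property
    def band(self) -> str:
        if self.icc < 0.5:
            return "poor"
        if self.icc < 0.75:
            return "moderate"
        if self.icc < 0.9:
            return "good"
        return "excellent"


def icc(samples: np.ndarray) -> IccResult:
    """Intraclass correlation of a (subjects x iterations) parameter table.

    sigma_within pools the unbiased per-subject variance across subjects;
    sigma_between is the standard deviation of subject means.
    ICC = sb^2 / (sb^2 + sw^2).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 iterations")
    var_within = float(np.mean(np.var(x, axis=1, ddof=1)))
    var_between = float(np.var(np.mean(x, axis=1), ddof=1))
    total = var_between + var_within
    if total == 0:
        raise ValueError("ICC undefined: no variance between or within subjects")
    return IccResult(
        sigma_between=float(np.sqrt(var_between)),
        sigma_within=float(np.sqrt(var_within)),
        icc=var_between / total,
    )
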