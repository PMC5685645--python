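"""Effective number of independent samples for autocorrelated datasets.

Consecutively recorded samples (e.g. from Monte Carlo sampling) are
correlated, with an autocorrelation that typically decays exponentially,
C(n) ~ C(0) alpha^n.  Summing the resulting variance inflation for a
first-order Markov process gives an effective sample count
N_eff = N (1 - alpha) / (1 + alpha), which should replace N in every
finite-size (complexity, probability) term so that dependence is not
mistaken for signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatable import DataTable

__all__ = ["AutocorrFit", "autocorrelation", "fit_alpha", "effective_n",
           "estimate_n_eff"]


@dataclass
class AutocorrFit:
    """Exponential fit of the sample autocorrelation."""

    c0: float                  # total lag-0 variance across variables
    c: np.ndarray              # normalized autocorrelation, c[0] = 1
    alpha: float               # per-step decay in [0, 1)
    decay_length: float        # R = -1 / ln(alpha); 0 when alpha = 0
    n_samples: int
    n_eff: int


def autocorrelation(data: DataTable, max_lag: int) -> np.ndarray:
    """Variance-weighted average autocorrelation over variables, per lag.

    Each variable enters as its centered integer-coded series; lag-n
    covariances are summed over variables and normalized by the summed lag-0
    variance, so high-variance variables carry proportionally more weight.
    Constant series are excluded; missing entries break the pairs they touch.
    """
    n = data.n_samples
    if not (1 <= max_lag < n):
        raise ValueError("need N > max_lag >= 1")
    cov = np.zeros(max_lag + 1)
    any_var = False
    for j in range(data.n_vars):
        x = data.values[:, j].astype(float)
        ok = ~data.missing_mask[:, j]
        if ok.sum() < 2:
            continue
        mu = x[ok].mean()
        d = np.where(ok, x - mu, 0.0)
        v0 = float((d[ok] ** 2).mean())
        if v0 <= 0:
            continue
        any_var = True
        for lag in range(max_lag + 1):
            if lag == 0:
                cov[0] += v0
                continue
            both = ok[:-lag] & ok[lag:]
            m = int(both.sum())
            if m > 0:
                cov[lag] += float((d[:-lag] * d[lag:])[both].sum()) / m
    if not any_var:
        raise ValueError("all series are constant")
    return cov / cov[0]


def fit_alpha(autocorr: np.ndarray, n_samples: int, floor: float = 0.05,
              max_lags: int = 50) -> AutocorrFit:
    """Least-squares exponential fit of the autocorrelation decay.

    A line is fitted through log c(n) over the lags with c(n) above the
    ``floor`` (default 0.05, at most ``max_lags`` lags); alpha is the
    exponential of the slope, clipped to [0, 1 - 1e-6].
    """
    c = np.asarray(autocorr, dtype=float)
    lags = np.arange(1, min(len(c), max_lags + 1))
    usable = lags[c[lags] > floor]
    if usable.size == 0:
        alpha = 0.0
    elif usable.size == 1:
        alpha = float(c[usable[0]] ** (1.0 / usable[0]))
    else:
        slope = np.polyfit(usable, np.log(c[usable]), 1)[0]
        alpha = float(math.exp(slope))
    alpha = min(max(alpha, 0.0), 1.0 - 1e-6)
    n_eff = effective_n(n_samples, alpha)
    decay = -1.0 / math.log(alpha) if alpha > 0 else 0.0
    return AutocorrFit(c0=float(c[0]), c=c, alpha=alpha, decay_length=decay,
                       n_samples=n_samples, n_eff=n_eff)


def effective_n(n_samples: int, alpha: float) -> int:
    """N_eff = round(N (1 - alpha) / (1 + alpha)), at least 1."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    return max(1, int(round(n_samples * (1.0 - alpha) / (1.0 + alpha))))


def estimate_n_eff(data: DataTable, max_lag: int = 100) -> AutocorrFit:
    """Convenience wrapper: autocorrelation + exponential fit + N_eff."""
    max_lag = min(max_lag, data.n_samples - 1)
    return fit_alpha(autocorrelation(data, max_lag), data.n_samples)
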