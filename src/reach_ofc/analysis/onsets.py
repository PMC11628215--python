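"""Onset-latency estimation via running paired t-tests and bootstrap.

The onset of a difference between two paired trace ensembles is the first
sample at or after a search start where the pointwise paired two-tailed
t-test across participants drops below the significance threshold (0.05)
and stays below it for a configurable number of consecutive samples
(1 by default). Bootstrap distributions resample participants with
replacement and recompute the onset per resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from ..ofc.plant import InvalidParameterError


class UndefinedStatisticError(ValueError):
    """Raised when between-participant variance is zero everywhere."""


@dataclass
class OnsetEstimate:
    onset_s: float                 # NaN if no crossing (sentinel)
    p_values: np.ndarray
    t_values: np.ndarray
    times: np.ndarray
    alpha: float
    bootstrap: np.ndarray | None = None   # onset distribution, s
    ci: tuple[float, float] | None = None

    @property
    def converged(self) -> bool:
        return not np.isnan(self.onset_s)


def _paired_t(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise paired t over axis -2 (participants); diff is (..., n, T).

    A zero between-participant SD with a nonzero mean is treated as a
    perfectly consistent difference (t = +/-inf, p = 0); zero SD with zero
    mean as no evidence (p = 1)."""
    n = diff.shape[-2]
    if n < 2:
        raise InvalidParameterError("need at least two participants")
    mean = diff.mean(axis=-2)
    sd = diff.std(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isnan(t), np.where(mean == 0.0, 1.0, p), p)
    t = np.where(np.isnan(t) & (mean == 0.0), 0.0, t)
    return t, p


def _first_crossing(p: np.ndarray, times: np.ndarray, search_start: float,
                    alpha: float, persistence: int) -> float:
    ok = p < alpha
    start = int(np.searchsorted(times, search_start - 1e-12))
    for i in range(start, len(times) - persistence + 1):
        if ok[i:i + persistence].all():
            return float(times[i])
    return float("nan")


def running_ttest_onset(traces_a: np.ndarray, traces_b: np.ndarray,
                        times: np.ndarray, search_start: float = 0.0,
                        alpha: float = 0.05, persistence: int = 1) -> OnsetEstimate:
    """Onset of the difference between paired trace sets (n_participants, T)."""
    a = np.asarray(traces_a, float)
    b = np.asarray(traces_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidParameterError("paired trace sets must share shape (n, T)")
    diff = a - b
    if np.allclose(diff.std(axis=0, ddof=0), 0.0) and np.allclose(diff, 0.0):
        raise UndefinedStatisticError(
            "zero between-participant variance and zero difference everywhere")
    t, p = _paired_t(diff)
    onset = _first_crossing(p, times, search_start, alpha, persistence)
    return OnsetEstimate(onset_s=onset, p_values=p, t_values=t, times=times, alpha=alpha)


def bootstrap_onset(traces_a: np.ndarray, traces_b: np.ndarray, times: np.ndarray,
                    search_start: float = 0.0, n_iter: int = 10_000,
                    seed: int | np.random.SeedSequence = 0, alpha: float = 0.05,
                    persistence: int = 1,
                    ci_level: float = 0.95) -> OnsetEstimate:
    """Participant-resampling bootstrap of the running-t onset.

    Returns the point estimate plus the bootstrap distribution (NaN entries
    mark resamples that never crossed) and the percentile CI over the
    converged resamples.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    est = running_ttest_onset(traces_a, traces_b, times, search_start, alpha, persistence)
    diff = np.asarray(traces_a, float) - np.asarray(traces_b, float)
    n = diff.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    boot = _resampled_onsets(diff, idx, times, search_start, alpha, persistence)
    est.bootstrap = boot
    good = boot[~np.isnan(boot)]
    if good.size:
        q = (1 - ci_level) / 2
        est.ci = (float(np.quantile(good, q)), float(np.quantile(good, 1 - q)))
    return est


def _resampled_onsets(diff: np.ndarray, idx: np.ndarray, times: np.ndarray,
                      search_start: float, alpha: float,
                      persistence: int) -> np.ndarray:
    """Onset per participant-resample; vectorized t over chunks of resamples.

    Degenerate resamples (zero SD) follow the same convention as `_paired_t`:
    a consistent nonzero difference is immediately significant."""
    n = diff.shape[0]
    n_iter = idx.shape[0]
    boot = np.empty(n_iter)
    chunk = max(1, int(2e7 // max(1, n * diff.shape[1])))
    tcrit = scipy.stats.t.isf(alpha / 2.0, df=n - 1)
    start = int(np.searchsorted(times, search_start - 1e-12))
    for lo in range(0, n_iter, chunk):
        sub = diff[idx[lo:lo + chunk]]          # (c, n, T)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = np.abs(mean / (sd / np.sqrt(n)))
        sig = np.where(np.isnan(tt), np.abs(mean) > 0, tt > tcrit)
        sig[:, :start] = False
        if persistence > 1:
            run = sig.copy()
            for k in range(1, persistence):
                run[:, :-k] &= sig[:, k:]
            sig = run
        has = sig.any(axis=1)
        first = np.argmax(sig, axis=1)
        boot[lo:lo + chunk] = np.where(has, times[np.minimum(first, len(times) - 1)], np.nan)
    return boot


def bootstrap_onset_difference(traces_a1: np.ndarray, traces_b1: np.ndarray,
                               traces_a2: np.ndarray, traces_b2: np.ndarray,
                               times: np.ndarray, search_start: float = 0.0,
                               n_iter: int = 10_000,
                               seed: int | np.random.SeedSequence = 0,
                               alpha: float = 0.05, persistence: int = 1,
                               ci_level: float = 0.95) -> dict:
    """Bootstrap CI for the onset difference between two condition contrasts.

    Participants are resampled once per iteration and both onsets recomputed
    on the same resample (paired design). The difference is the calibrated
    bootstrap quantity: the detection delay of the threshold-crossing onset
    estimator is common to both contrasts and cancels, which it does not in
    a single-onset CI.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    d1 = np.asarray(traces_a1, float) - np.asarray(traces_b1, float)
    d2 = np.asarray(traces_a2, float) - np.asarray(traces_b2, float)
    if d1.shape[0] != d2.shape[0]:
        raise InvalidParameterError("both contrasts need the same participants")
    n = d1.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    o1 = _resampled_onsets(d1, idx, times, search_start, alpha, persistence)
    o2 = _resampled_onsets(d2, idx, times, search_start, alpha, persistence)
    diff = o2 - o1
    good = diff[~np.isnan(diff)]
    point = (running_ttest_onset(traces_a2, traces_b2, times, search_start,
                                 alpha, persistence).onset_s
             - running_ttest_onset(traces_a1, traces_b1, times, search_start,
                                   alpha, persistence).onset_s)
    q = (1 - ci_level) / 2
    ci = ((float(np.quantile(good, q)), float(np.quantile(good, 1 - q)))
          if good.size else (float("nan"), float("nan")))
    return {"difference_s": point, "bootstrap": diff, "ci": ci,
            "n_degenerate": int(np.isnan(diff).sum())}
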