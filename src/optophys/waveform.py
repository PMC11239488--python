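"""Resampling significance procedures for event-aligned trial matrices.

Two procedures, each combined with a minimum-duration consecutive rule at
the 20-Hz grid:

* bootstrap waveform analysis — trials are resampled with replacement and a
  per-timepoint percentile confidence interval on the mean is formed; a
  timepoint is flagged when the CI excludes zero, and flagged runs are
  reported only when they last strictly *more than* ``min_duration``
  (default 0.2 s, i.e. at least 5 samples at 20 Hz);
* permutation comparison between two event types — the per-timepoint
  difference of trial means is compared against a null built by shuffling
  trial labels across the pooled trials; runs of p < alpha lasting *at
  least* ``min_duration`` (>= 4 samples at 20 Hz) are reported.

Run duration is run_length * dt throughout. Both thresholds and both
strict/inclusive conventions are configurable and isolated in
``find_windows`` for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import ConfigError, DataError
from .photometry import TrialMatrix

__all__ = [
    "WaveformResult",
    "PermutationResult",
    "bootstrap_waveform",
    "permutation_compare",
    "find_windows",
]


@dataclass
class WaveformResult:
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    mask: np.ndarray
    windows: list  # [(start_s, end_s)]
    rel_time: np.ndarray
    B: int
    alpha: float
    min_duration: float
    seed: int | None


@dataclass
class PermutationResult:
    diff: np.ndarray  # observed mean(a) - mean(b) per timepoint
    pvalues: np.ndarray
    mask: np.ndarray
    windows: list
    rel_time: np.ndarray
    n_perm: int
    alpha: float
    min_duration: float
    seed: int | None
    exact: bool = False


def find_windows(mask: np.ndarray, min_duration: float, dt: float,
                 strict: bool = False, t0: float = 0.0) -> list[tuple[float, float]]:
    """Maximal contiguous True runs converted to (start, end) seconds.

    A run of n samples has duration n * dt; it is kept when the duration is
    > ``min_duration`` (strict) or >= ``min_duration`` (inclusive). ``t0``
    is the time of the first sample.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ConfigError("mask must be one-dimensional")
    if m.size == 0:
        return []
    padded = np.concatenate([[False], m, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    out = []
    for i0, i1 in zip(starts, ends):
        dur = (i1 - i0) * dt
        ok = dur > min_duration if strict else dur >= min_duration - 1e-12
        if ok:
            out.append((t0 + i0 * dt, t0 + i1 * dt))
    return out


def _as_array(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, TrialMatrix):
        return np.asarray(trials.data, float), np.asarray(trials.rel_time, float)
    a = np.asarray(trials, float)
    if a.ndim != 2:
        raise ConfigError("trials must be a 2-D (trials x timepoints) array")
    return a, None


def bootstrap_waveform(trials, B: int = 1000, alpha: float = 0.05,
                       min_duration: float = 0.2, seed: int | None = None,
                       dt: float | None = None, strict: bool = True
                       ) -> WaveformResult:
    """Percentile bootstrap CI on the per-timepoint mean across trials.

    A timepoint is significant when the (1 - alpha) CI excludes zero;
    windows are runs of significant timepoints lasting more than
    ``min_duration`` (strict by default, honoring the "more than 0.2 s"
    convention).
    """
    data, rel_time = _as_array(trials)
    n, T = data.shape
    if n < 2:
        raise DataError("bootstrap requires at least 2 trials")
    if rel_time is None:
        if dt is None:
            raise ConfigError("dt is required for plain-array input")
        rel_time = np.arange(T) * dt
    dt = float(rel_time[1] - rel_time[0])

    rng = np.random.default_rng(seed)
    boot = np.empty((B, T))
    chunk = max(1, int(5e6 // max(n * T, 1)))
    for b0 in range(0, B, chunk):
        b1 = min(B, b0 + chunk)
        idx = rng.integers(0, n, size=(b1 - b0, n))
        boot[b0:b1] = data[idx].mean(axis=1)
    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    mask = (lo > 0) | (hi < 0)
    windows = find_windows(mask, min_duration, dt, strict=strict, t0=rel_time[0])
    return WaveformResult(mean=data.mean(axis=0), ci_lower=lo, ci_upper=hi,
                          mask=mask, windows=windows, rel_time=rel_time,
                          B=B, alpha=alpha, min_duration=min_duration, seed=seed)


def _perm_null(pooled: np.ndarray, n_a: int, n_perm: int, rng,
               strata: np.ndarray | None) -> np.ndarray:
    n = pooled.shape[0]
    null = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            # within-stratum shuffle: each subject's trials trade labels
            # only among themselves
            perm = np.arange(n)
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                perm[idx] = idx[rng.permutation(len(idx))]
        a = pooled[perm[:n_a]]
        b = pooled[perm[n_a:]]
        null[i] = a.mean(axis=0) - b.mean(axis=0)
    return null


def permutation_compare(trials_a, trials_b, n_perm: int = 1000,
                        alpha: float = 0.05, min_duration: float = 0.2,
                        seed: int | None = None, dt: float | None = None,
                        exact: bool = False, strict: bool = False,
                        stratify: tuple | None = None) -> PermutationResult:
    """Per-timepoint permutation test on the difference of trial means.

    Trial labels are shuffled across the pooled trials; the two-sided
    p-value uses the add-one estimator p = (1 + #{|null| >= |obs|}) /
    (n_perm + 1). With ``exact=True`` all distinct relabelings are
    enumerated instead (the identity is included, so no correction is
    needed). ``stratify=(rats_a, rats_b)`` restricts shuffling to within
    each subject's own trials (off by default).

    Windows are runs of p < alpha lasting at least ``min_duration``
    (inclusive by default, honoring the "at least 0.2 s" convention).
    """
    a, rt_a = _as_array(trials_a)
    b, rt_b = _as_array(trials_b)
    if a.shape[1] != b.shape[1]:
        raise DataError("trial matrices do not share a time axis")
    if rt_a is not None and rt_b is not None and not np.allclose(rt_a, rt_b):
        raise DataError("trial matrices do not share a time axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("permutation test requires >= 2 trials per group")
    rel_time = rt_a
    if rel_time is None:
        if dt is None:
            raise ConfigError("dt is required for plain-array input")
        rel_time = np.arange(a.shape[1]) * dt
    dt = float(rel_time[1] - rel_time[0])

    n_a = a.shape[0]
    pooled = np.vstack([a, b])
    obs = a.mean(axis=0) - b.mean(axis=0)

    if exact:
        if stratify is not None:
            raise ConfigError("exact enumeration does not support stratification")
        n = pooled.shape[0]
        M = comb(n, n_a)
        if M > 500_000:
            raise ConfigError(f"{M} relabelings: too many for exact enumeration")
        count = np.zeros(pooled.shape[1])
        means = pooled.mean(axis=0) * n
        for idx_a in combinations(range(n), n_a):
            sa = pooled[list(idx_a)].sum(axis=0)
            d = sa / n_a - (means - sa) / (n - n_a)
            count += np.abs(d) >= np.abs(obs) - 1e-12
        p = count / M
        n_used = M
    else:
        strata = None
        if stratify is not None:
            strata = np.concatenate([np.asarray(stratify[0]),
                                     np.asarray(stratify[1])])
            if len(strata) != pooled.shape[0]:
                raise ConfigError("stratify labels must match trial counts")
        rng = np.random.default_rng(seed)
        null = _perm_null(pooled, n_a, n_perm, rng, strata)
        exceed = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used = n_perm

    mask = p < alpha
    windows = find_windows(mask, min_duration, dt, strict=strict, t0=rel_time[0])
    return PermutationResult(diff=obs, pvalues=p, mask=mask, windows=windows,
                             rel_time=rel_time, n_perm=n_used, alpha=alpha,
                             min_duration=min_duration, seed=seed, exact=exact)
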