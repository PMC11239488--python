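"""Opto-evoked spike-train metrics.

A pulse is counted as answered when at least one spike falls inside the
half-open response window [onset, onset + 15 ms); each spike is credited to
at most one pulse (the earliest window containing it). Fidelity is the
fraction of answered pulses, summarized per trial, per pulse index across
trials, and over the first five versus last five pulses of the train. The
overall train firing rate (spikes per second over the 1-s train, regardless
of pulse locking) and the latency to the k-th action potential — observed
when at least k spikes occur, otherwise extrapolated by regressing observed
spike latencies on spike ordinal — complete the summary. All latencies are
measured from train onset (t = 0 at the first pulse onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, OverlapError
from .synth import SpikeTrial

__all__ = [
    "FidelitySummary",
    "pulse_responses",
    "fidelity",
    "fidelity_first_last",
    "train_rate",
    "latency_to_kth",
    "summarize_trial",
    "summarize_trials",
    "per_pulse_probability",
]


@dataclass
class FidelitySummary:
    trial_id: int
    fidelity: float
    first5: float
    last5: float
    rate_hz: float
    latency_k: float
    latency_flag: str  # 'observed' | 'extrapolated'
    k: int = 10


def pulse_responses(trial: SpikeTrial, window: float = 0.015) -> np.ndarray:
    """Boolean per pulse: did >= 1 spike land in [onset, onset + window)?

    Each spike is credited to at most one pulse; with window <= the
    inter-pulse interval the windows are disjoint, which is enforced.
    """
    train = trial.train
    if window <= 0:
        raise ConfigError("response window must be > 0")
    if window > train.inter_pulse_interval:
        raise OverlapError(
            f"window {window * 1e3:.1f} ms exceeds the inter-pulse interval "
            f"{train.inter_pulse_interval * 1e3:.1f} ms"
        )
    onsets = train.onsets
    out = np.zeros(len(onsets), dtype=bool)
    used = np.zeros(len(trial.spike_times), dtype=bool)
    for k, on in enumerate(onsets):
        in_win = (trial.spike_times >= on) & (trial.spike_times < on + window) & ~used
        hit = np.flatnonzero(in_win)
        if hit.size:
            out[k] = True
            used[hit[0]] = True  # earliest containing pulse claims the spike
    return out


def fidelity(trial: SpikeTrial, window: float = 0.015) -> float:
    """Fraction of pulses answered within the response window."""
    r = pulse_responses(trial, window)
    return float(r.mean()) if r.size else 0.0


def fidelity_first_last(trial: SpikeTrial, window: float = 0.015
                        ) -> tuple[float, float]:
    """Fidelity over the first five and last five pulses of the train."""
    r = pulse_responses(trial, window)
    if r.size < 10:
        raise DataError("first/last-five split needs a train of >= 10 pulses")
    return float(r[:5].mean()), float(r[-5:].mean())


def train_rate(trial: SpikeTrial, duration: float = 1.0) -> float:
    """Overall firing rate: spikes in [0, duration) per second."""
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    n = int(np.sum((trial.spike_times >= 0) & (trial.spike_times < duration)))
    return n / duration


def latency_to_kth(trial: SpikeTrial, k: int = 10) -> tuple[float, str]:
    """Latency (s from train onset) of the k-th action potential.

    If fewer than k spikes occurred, the expected latency is extrapolated
    by OLS of the observed spike latencies on spike ordinal (1..m),
    evaluated at ordinal k. At least 2 spikes are required to extrapolate.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    st = trial.spike_times
    if len(st) >= k:
        return float(st[k - 1]), "observed"
    if len(st) < 2:
        raise DataError(f"cannot extrapolate latency to spike {k} "
                        f"from {len(st)} spike(s)")
    ordinal = np.arange(1, len(st) + 1, dtype=float)
    slope, intercept = np.polyfit(ordinal, st, 1)
    return float(slope * k + intercept), "extrapolated"


def summarize_trial(trial: SpikeTrial, window: float = 0.015,
                    duration: float = 1.0, k: int = 10) -> FidelitySummary:
    lat, flag = latency_to_kth(trial, k)
    f5, l5 = fidelity_first_last(trial, window)
    return FidelitySummary(trial_id=trial.trial_id,
                           fidelity=fidelity(trial, window),
                           first5=f5, last5=l5,
                           rate_hz=train_rate(trial, duration),
                           latency_k=lat, latency_flag=flag, k=k)


def summarize_trials(trials: list[SpikeTrial], window: float = 0.015,
                     duration: float = 1.0, k: int = 10) -> pd.DataFrame:
    """Per-trial summary table (one row per stimulation trial)."""
    rows = [summarize_trial(tr, window, duration, k) for tr in trials]
    return pd.DataFrame([r.__dict__ for r in rows])


def per_pulse_probability(trials: list[SpikeTrial], window: float = 0.015,
                          neuron_ids=None) -> pd.DataFrame:
    """Response probability per pulse index across trials.

    By default all trials are pooled. With ``neuron_ids`` (one label per
    trial) responses are first averaged within each neuron and then across
    neurons, so every cell carries equal weight regardless of trial count.
    """
    resp = np.array([pulse_responses(tr, window) for tr in trials], dtype=float)
    if resp.size == 0:
        raise DataError("no trials")
    if neuron_ids is not None:
        ids = np.asarray(neuron_ids)
        if len(ids) != len(trials):
            raise ConfigError("neuron_ids must give one label per trial")
        prob = np.mean([resp[ids == u].mean(axis=0) for u in np.unique(ids)],
                       axis=0)
    else:
        prob = resp.mean(axis=0)
    return pd.DataFrame({"pulse_index": np.arange(1, resp.shape[1] + 1),
                         "probability": prob,
                         "n_trials": resp.shape[0]})
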