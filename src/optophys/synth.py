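"""Synthetic-data generators for the three recording modalities.

Every downstream stage of the pipeline (photometry correction, resampling
waveform statistics, spike-fidelity metrics, behavioral scoring) is exercised
against data produced here, so the generators emulate the statistical
structure those analyses assume:

* two-channel fiber photometry (470-nm dopamine-sensor signal plus 415-nm
  isosbestic control at 20 Hz) with shared exponential photobleaching,
  shared multiplicative motion, and event-locked dopamine transients whose
  amplitude and duration depend on the event type (20-Hz stimulation <
  50-Hz stimulation <= food delivery);
* optogenetically evoked spike trains whose per-pulse response probability
  decays along the train, faster at 50 Hz than at 20 Hz;
* operant session event logs (Pavlovian conditioning, FR/RR instrumental
  blocks with a press cap and time-outs, the transfer test with its fixed
  cue order, and self-stimulation sessions).

All generators are deterministic under a fixed integer seed and return the
injected ground truth next to the data so that recovery can be asserted
exactly in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .errors import ConfigError, LayoutError, OverlapError

__all__ = [
    "TransientSpec",
    "PhotomGenParams",
    "FidelityGenParams",
    "SessionSpec",
    "AgentModel",
    "PulseTrain",
    "SpikeTrial",
    "PhotometrySession",
    "EventLog",
    "gen_pulse_train",
    "gen_evoked_spikes",
    "gen_photometry_session",
    "gen_session_log",
    "transient_kernel",
    "DEFAULT_TRANSIENTS",
    "PIT_CUE_ORDER",
    "SCHEDULE_PROBABILITY",
]

# Reinforcement probability per press for each schedule. Random-ratio
# schedules are i.i.d. Bernoulli per press (RR5 => p = 0.2, RR10 => p = 0.1),
# i.e. the defining probability, not a drawn-ratio implementation.
SCHEDULE_PROBABILITY = {"CRF": 1.0, "FR1": 1.0, "RR5": 0.2, "RR10": 0.1}

# Fixed transfer-test cue sequence (never shuffled).
PIT_CUE_ORDER = ("clicker", "noise", "noise", "clicker", "noise", "clicker", "clicker")


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseTrain:
    """Periodic optical stimulation train; onsets at k/frequency."""

    frequency: float
    duration: float
    pulse_width: float = 0.005
    onsets: np.ndarray = field(default=None, repr=False)

    @property
    def n_pulses(self) -> int:
        return len(self.onsets)

    @property
    def inter_pulse_interval(self) -> float:
        return 1.0 / self.frequency


@dataclass
class SpikeTrial:
    """Spike times (s, relative to train onset) for one stimulation trial."""

    trial_id: int
    spike_times: np.ndarray
    train: PulseTrain
    evoked: np.ndarray | None = None  # ground truth: bool per pulse

    def __post_init__(self):
        st = np.asarray(self.spike_times, dtype=float)
        if np.any(st < 0):
            raise ConfigError("spike times must be non-negative")
        self.spike_times = np.sort(st)


@dataclass
class PhotometrySession:
    """Paired 470/415 traces on a uniform grid plus labeled event times."""

    time: np.ndarray
    signal_470: np.ndarray
    control_415: np.ndarray
    events: pd.DataFrame  # columns: time_s, label, rat_id
    rat_id: str = "rat0"
    truth: dict | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if len(t) != len(self.signal_470) or len(t) != len(self.control_415):
            raise ConfigError("channels must match the time grid length")
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ConfigError("time grid must be strictly increasing and uniform")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class EventLog:
    """Timestamped behavioral events for one session.

    ``df`` columns: time_s, event, arg with
    event in {cue_on, cue_off, press_L, press_R, port_in, port_out, reward}.
    """

    df: pd.DataFrame
    rat_id: str = "rat0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.sort_values("time_s", kind="stable").reset_index(drop=True)

    def count(self, event: str) -> int:
        return int((self.df["event"] == event).sum())


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TransientSpec:
    """Event-locked dopamine transient: peak amplitude in dF/F units and
    difference-of-exponentials kinetics (1 - e^(-t/rise)) * e^(-t/decay),
    peak-normalized on the sampling grid."""

    amplitude: float
    rise_tau: float = 0.2
    decay_tau: float = 1.0

    def validate(self):
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ConfigError("transient time constants must be positive")


# Defaults reproduce the qualitative ordering of evoked dopamine release:
# 20-Hz stimulation < 50-Hz stimulation <= food, with food the most prolonged.
DEFAULT_TRANSIENTS: Mapping[str, TransientSpec] = {
    "stim_20hz": TransientSpec(amplitude=0.03, rise_tau=0.2, decay_tau=1.0),
    "stim_50hz": TransientSpec(amplitude=0.08, rise_tau=0.2, decay_tau=1.5),
    "food": TransientSpec(amplitude=0.09, rise_tau=0.2, decay_tau=3.0),
}


@dataclass
class PhotomGenParams:
    """Generator settings for a two-channel photometry session.

    The control channel is a shared component S(t) = bleach(t) * (1 + motion)
    plus sensor noise; the signal channel is an affine function of the same
    component, F0 = slope * S + intercept, modulated by the event transients:
    signal = F0 * (1 + sum of kernels) + noise. Amplitudes are therefore in
    dF/F units by construction.
    """

    sampling_rate: float = 20.0
    session_length: float = 2400.0
    control_baseline: float = 100.0
    bleach_amplitude: float = 30.0
    bleach_tau: float = 600.0
    signal_slope: float = 1.8
    signal_intercept: float = 10.0
    motion_sd: float = 0.005  # relative (multiplicative) units
    motion_smooth_s: float = 0.5
    noise_sd_control: float = 0.3
    noise_sd_signal: float = 0.3
    transients: Mapping[str, TransientSpec] = field(
        default_factory=lambda: dict(DEFAULT_TRANSIENTS)
    )
    event_counts: Mapping[str, int] = field(
        default_factory=lambda: {"stim_20hz": 5, "stim_50hz": 5, "food": 5}
    )
    iti_mean: float = 120.0
    iti_jitter: float = 0.25  # ITIs uniform in mean * [1 - j, 1 + j]
    start_pad: float = 70.0  # >= trim (60 s) + baseline window (5 s)
    end_pad: float = 15.0
    rat_id: str = "rat0"
    seed: int | None = None

    def validate(self):
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.bleach_tau <= 0 or self.motion_smooth_s <= 0:
            raise ConfigError("time constants must be > 0")
        if self.iti_mean <= 0 or not (0 <= self.iti_jitter < 1):
            raise ConfigError("invalid ITI parameters")
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")
        for label in self.event_counts:
            if label not in self.transients:
                raise ConfigError(f"no transient spec for event label {label!r}")
        for spec in self.transients.values():
            spec.validate()


@dataclass
class FidelityGenParams:
    """Generator settings for opto-evoked spike trains.

    Pulse k (0-based) evokes a spike with probability p0 * decay**k; evoked
    latencies are truncated-normal inside [0, 15 ms); background spikes come
    from an independent homogeneous Poisson process (tonic firing).
    """

    frequency: float
    train_duration: float = 1.0
    pulse_width: float = 0.005
    p0: float = 0.9
    decay: float = 0.98
    latency_mean: float = 0.006
    latency_sd: float = 0.002
    latency_window: float = 0.015
    background_rate: float = 2.0
    n_trials: int = 10
    seed: int | None = None

    # Per-pulse fidelity decays faster at 50 Hz than at 20 Hz, but the two
    # trains evoke a similar total number of spikes and the 50-Hz train
    # reaches its 10th spike sooner (burst-like onset).
    _FREQ_DEFAULTS = {20.0: (0.95, 0.99), 50.0: (0.90, 0.95)}

    @classmethod
    def for_frequency(cls, frequency: float, **kw) -> "FidelityGenParams":
        p0, decay = cls._FREQ_DEFAULTS.get(float(frequency), (0.9, 0.97))
        kw.setdefault("p0", p0)
        kw.setdefault("decay", decay)
        return cls(frequency=frequency, **kw)

    def pulse_probabilities(self, n_pulses: int) -> np.ndarray:
        p = self.p0 * self.decay ** np.arange(n_pulses)
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigError("decay produces pulse probabilities outside [0, 1]")
        return p

    def validate(self):
        if not 0 <= self.p0 <= 1:
            raise ConfigError("p0 must lie in [0, 1]")
        if self.decay < 0:
            raise ConfigError("decay must be non-negative")
        if not 0 <= self.latency_mean < self.latency_window:
            raise ConfigError("latency_mean must lie inside the response window")
        if self.latency_sd < 0 or self.background_rate < 0 or self.n_trials < 1:
            raise ConfigError("invalid fidelity generator parameters")
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")


@dataclass
class AgentModel:
    """Generative stand-in for rat behavior.

    Press rates are Poisson (presses/min) per lever, optionally scaled by a
    multiplier during cues; a saturating agent instead presses
    deterministically at a fixed cadence whenever a lever is available.
    """

    base_press_rate: Mapping[str, float] = field(
        default_factory=lambda: {"L": 4.0, "R": 4.0}
    )
    cue_press_multiplier: Mapping[tuple, float] = field(default_factory=dict)
    port_entry_rate: float = 0.0  # entries/min during cues
    port_entry_rate_baseline: float = 0.0
    port_entry_duration: float = 1.5  # mean s per entry
    saturating: bool = False
    press_interval: float = 2.0  # cadence (s) when saturating

    def validate(self):
        if any(r < 0 for r in self.base_press_rate.values()):
            raise ConfigError("press rates must be >= 0")
        if any(m < 0 for m in self.cue_press_multiplier.values()):
            raise ConfigError("cue multipliers must be >= 0")
        if self.port_entry_rate < 0 or self.port_entry_rate_baseline < 0:
            raise ConfigError("port-entry rates must be >= 0")
        if self.press_interval <= 0 or self.port_entry_duration <= 0:
            raise ConfigError("durations must be > 0")

    def press_rate(self, lever: str, cue: str | None) -> float:
        rate = self.base_press_rate.get(lever, 0.0)
        if cue is not None:
            rate *= self.cue_press_multiplier.get((cue, lever), 1.0)
        return rate


@dataclass
class SessionSpec:
    """Structure of one behavioral session.

    phase: 'pavlovian', 'instrumental', 'pit_test' or 'icss'.
    """

    phase: str
    schedule: str = "CRF"
    # instrumental structure: two 10-min blocks per lever, 2.5-min time-outs,
    # lever retracted after 20 presses within a block
    block_duration: float = 600.0
    blocks_per_lever: int = 2
    timeout: float = 150.0
    press_cap: int = 20
    lever_order: Sequence[str] = ("L", "R")
    # associative structure
    cue_outcome: Mapping[str, str] = field(
        default_factory=lambda: {"clicker": "pellet", "noise": "stim"}
    )
    outcome_lever: Mapping[str, str] = field(
        default_factory=lambda: {"pellet": "L", "stim": "R"}
    )
    cue_duration: float = 120.0
    # Pavlovian phase
    pavlovian_trials_per_cue: int = 4
    pavlovian_iti_mean: float = 300.0
    pavlovian_iti_jitter: float = 0.25
    rewards_per_cue: int = 4
    # transfer test: fixed 7-cue order, 8-min extinction, fixed 3-min ITIs
    pit_order: Sequence[str] = PIT_CUE_ORDER
    pit_iti: float = 180.0
    pit_extinction: float = 480.0
    # self-stimulation
    icss_duration: float = 1800.0
    active_lever: str = "L"
    seed: int | None = None

    def validate(self):
        if self.phase not in {"pavlovian", "instrumental", "pit_test", "icss"}:
            raise ConfigError(f"unknown phase {self.phase!r}")
        if self.schedule not in SCHEDULE_PROBABILITY:
            raise ConfigError(f"unknown schedule {self.schedule!r}")
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")
        if self.press_cap < 1 or self.block_duration <= 0 or self.timeout < 0:
            raise ConfigError("invalid instrumental block parameters")


# --------------------------------------------------------------------------
# pulse trains and evoked spikes
# --------------------------------------------------------------------------


def gen_pulse_train(frequency: float, duration: float, pulse_width: float = 0.005) -> PulseTrain:
    """Periodic optical pulse train: onsets at k/frequency, k = 0..n-1.

    Raises OverlapError when frequency * pulse_width >= 1 (pulses would
    overlap their successors).
    """
    if duration <= 0 or frequency <= 0 or pulse_width <= 0:
        raise ConfigError("frequency, duration and pulse_width must be > 0")
    if frequency * pulse_width >= 1:
        raise OverlapError(
            f"duty cycle {frequency * pulse_width:.3f} >= 1: pulses overlap"
        )
    n = int(round(duration * frequency))
    onsets = np.arange(n) / frequency
    return PulseTrain(frequency=frequency, duration=duration,
                      pulse_width=pulse_width, onsets=onsets)


def _truncated_latencies(rng, n, params: FidelityGenParams) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if params.latency_sd == 0:
        return np.full(n, params.latency_mean)
    a = (0.0 - params.latency_mean) / params.latency_sd
    b = (params.latency_window - params.latency_mean) / params.latency_sd
    return truncnorm.rvs(a, b, loc=params.latency_mean, scale=params.latency_sd,
                         size=n, random_state=rng)


def gen_evoked_spikes(train: PulseTrain, params: FidelityGenParams) -> list[SpikeTrial]:
    """Simulate ``params.n_trials`` stimulation trials on ``train``.

    Each pulse independently evokes at most one spike (probability
    p0 * decay**k, latency inside [0, 15 ms)); an independent Poisson
    background is superimposed over the train duration. The injected per-pulse
    outcome is returned as ``SpikeTrial.evoked`` ground truth.
    """
    params.validate()
    probs = params.pulse_probabilities(train.n_pulses)
    rng = np.random.default_rng(params.seed)
    trials = []
    for trial_id in range(params.n_trials):
        evoked = rng.random(train.n_pulses) < probs
        lat = _truncated_latencies(rng, int(evoked.sum()), params)
        spikes = train.onsets[evoked] + lat
        if params.background_rate > 0:
            n_bg = rng.poisson(params.background_rate * params.train_duration)
            spikes = np.concatenate(
                [spikes, rng.uniform(0, params.train_duration, n_bg)]
            )
        trials.append(SpikeTrial(trial_id=trial_id, spike_times=np.sort(spikes),
                                 train=train, evoked=evoked))
    return trials


# --------------------------------------------------------------------------
# photometry sessions
# --------------------------------------------------------------------------


def transient_kernel(spec: TransientSpec, dt: float, n: int) -> np.ndarray:
    """Difference-of-exponentials kernel sampled on the grid, normalized to
    unit peak *on that grid* so an injected amplitude equals the maximum of
    the sampled transient exactly."""
    t = np.arange(n) * dt
    k = (1.0 - np.exp(-t / spec.rise_tau)) * np.exp(-t / spec.decay_tau)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate transient kernel")
    return k / peak


def _kernel_support(spec: TransientSpec, dt: float) -> int:
    return max(2, int(round((5 * spec.rise_tau + 8 * spec.decay_tau) / dt)))


def _layout_events(params: PhotomGenParams, rng) -> pd.DataFrame:
    """Draw event times: balanced label order (no label appearing more than
    twice in a row) with jittered ITIs, snapped to the sampling grid."""
    labels = [lab for lab, c in sorted(params.event_counts.items()) for _ in range(c)]
    if not labels:
        return pd.DataFrame(columns=["time_s", "label", "rat_id"])
    for _ in range(200):
        order = list(labels)
        rng.shuffle(order)
        runs = max(len(list(g)) for _, g in itertools.groupby(order))
        if runs <= 2:
            break
    itis = params.iti_mean * rng.uniform(
        1 - params.iti_jitter, 1 + params.iti_jitter, size=len(order)
    )
    times = params.start_pad + np.cumsum(itis) - itis[0]
    dt = 1.0 / params.sampling_rate
    times = np.round(times / dt) * dt
    # response window: longest transient support after the last event
    max_support = max(
        _kernel_support(params.transients[lab], dt) for lab in params.event_counts
    ) * dt if params.event_counts else 0.0
    end_limit = params.session_length - max(params.end_pad, min(max_support, 15.0))
    if times[0] < params.start_pad - 1e-9 or times[-1] > end_limit:
        raise LayoutError(
            f"events do not fit: last event at {times[-1]:.1f} s exceeds "
            f"{end_limit:.1f} s (session {params.session_length:.0f} s)"
        )
    return pd.DataFrame(
        {"time_s": times, "label": order, "rat_id": params.rat_id}
    )


def gen_photometry_session(params: PhotomGenParams) -> PhotometrySession:
    """Generate a two-channel photometry session with injected transients.

    Ground truth (event table, per-event amplitudes, the affine map between
    channels, and the noise-free components) is attached as ``session.truth``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    dt = 1.0 / fs
    n = int(round(params.session_length * fs))
    t = np.arange(n) * dt

    bleach = params.control_baseline + params.bleach_amplitude * np.exp(
        -t / params.bleach_tau
    )
    if params.motion_sd > 0:
        raw = gaussian_filter1d(rng.standard_normal(n), params.motion_smooth_s * fs)
        sd = raw.std()
        motion = params.motion_sd * raw / sd if sd > 0 else np.zeros(n)
    else:
        motion = np.zeros(n)
    shared = bleach * (1.0 + motion)

    events = _layout_events(params, rng)
    transient = np.zeros(n)
    for _, ev in events.iterrows():
        spec = params.transients[ev["label"]]
        m = _kernel_support(spec, dt)
        i0 = int(round(ev["time_s"] / dt))
        m = min(m, n - i0)
        transient[i0:i0 + m] += spec.amplitude * transient_kernel(spec, dt, m)

    f0 = params.signal_slope * shared + params.signal_intercept
    control = shared + rng.normal(0.0, params.noise_sd_control, n)
    signal = f0 * (1.0 + transient) + rng.normal(0.0, params.noise_sd_signal, n)

    truth = {
        "events": events.copy(),
        "amplitudes": {lab: params.transients[lab].amplitude
                       for lab in params.event_counts},
        "slope": params.signal_slope,
        "intercept": params.signal_intercept,
        "shared": shared,
        "dff": transient,
    }
    return PhotometrySession(time=t, signal_470=signal, control_415=control,
                             events=events, rat_id=params.rat_id, truth=truth)


# --------------------------------------------------------------------------
# behavioral session logs
# --------------------------------------------------------------------------


def _poisson_times(rng, rate_per_min: float, start: float, end: float) -> np.ndarray:
    """Homogeneous Poisson event times in [start, end)."""
    if rate_per_min <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * (end - start))
    return np.sort(rng.uniform(start, end, n))


def _port_entries(rng, rate_per_min, mean_dur, start, end, rows, rat=None):
    """Alternating port_in/port_out pairs inside [start, end)."""
    t = start
    while True:
        if rate_per_min <= 0:
            return
        t += rng.exponential(60.0 / rate_per_min)
        if t >= end:
            return
        out = min(t + rng.exponential(mean_dur), end - 1e-6)
        if out <= t:
            return
        rows.append((t, "port_in", ""))
        rows.append((out, "port_out", ""))
        t = out


def _instrumental_block(rng, rows, lever, start, spec, agent, prob):
    """One lever block: presses until the cap or the block clock runs out.

    Returns (block_end_time, n_rewards)."""
    end = start + spec.block_duration
    if agent.saturating:
        times = start + agent.press_interval * np.arange(1, spec.press_cap * 10)
        times = times[times < end]
    else:
        times = _poisson_times(rng, agent.press_rate(lever, None), start, end)
    times = times[: spec.press_cap]  # lever retracted at the cap
    rewards = 0
    for pt in times:
        rows.append((pt, f"press_{lever}", ""))
        if rng.random() < prob:
            rewards += 1
            rows.append((pt, "reward", lever))
    block_end = times[-1] if len(times) == spec.press_cap else end
    return block_end, rewards


def _gen_instrumental(spec: SessionSpec, agent: AgentModel, rng) -> tuple[list, dict]:
    prob = SCHEDULE_PROBABILITY[spec.schedule]
    rows, blocks, rewards = [], [], {lev: 0 for lev in spec.lever_order}
    t = 0.0
    # blocks alternate levers: L, R, L, R ... (two per lever by default)
    order = list(spec.lever_order) * spec.blocks_per_lever
    for i, lever in enumerate(order):
        block_end, r = _instrumental_block(rng, rows, lever, t, spec, agent, prob)
        blocks.append({"lever": lever, "start": t, "end": block_end})
        rewards[lever] += r
        t = block_end + (spec.timeout if i < len(order) - 1 else 0.0)
    meta = {"blocks": blocks, "rewards_per_lever": rewards,
            "session_end": blocks[-1]["end"]}
    return rows, meta


def _gen_pavlovian(spec: SessionSpec, agent: AgentModel, rng) -> tuple[list, dict]:
    cues = list(spec.cue_outcome)
    labels = [c for c in cues for _ in range(spec.pavlovian_trials_per_cue)]
    rng.shuffle(labels)
    rows, t = [], 0.0
    for cue in labels:
        t += spec.pavlovian_iti_mean * rng.uniform(
            1 - spec.pavlovian_iti_jitter, 1 + spec.pavlovian_iti_jitter
        )
        on, off = t, t + spec.cue_duration
        rows.append((on, "cue_on", cue))
        rows.append((off, "cue_off", cue))
        for rt in np.sort(rng.uniform(on, off, spec.rewards_per_cue)):
            rows.append((rt, "reward", spec.cue_outcome[cue]))
        _port_entries(rng, agent.port_entry_rate, agent.port_entry_duration,
                      on, off, rows)
        t = off
    return rows, {"session_end": t, "cue_order": labels}


def _gen_pit_test(spec: SessionSpec, agent: AgentModel, rng) -> tuple[list, dict]:
    """Transfer test: 8-min extinction, then the fixed 7-cue sequence with
    3-min ITIs; both levers available throughout, no rewards delivered."""
    rows = []
    levers = sorted(agent.base_press_rate)

    def presses(start, end, cue):
        for lever in levers:
            for pt in _poisson_times(rng, agent.press_rate(lever, cue), start, end):
                rows.append((pt, f"press_{lever}", ""))

    presses(0.0, spec.pit_extinction, None)
    _port_entries(rng, agent.port_entry_rate_baseline, agent.port_entry_duration,
                  0.0, spec.pit_extinction, rows)
    t = spec.pit_extinction
    for i, cue in enumerate(spec.pit_order):
        on, off = t, t + spec.cue_duration
        rows.append((on, "cue_on", cue))
        rows.append((off, "cue_off", cue))
        presses(on, off, cue)
        _port_entries(rng, agent.port_entry_rate, agent.port_entry_duration,
                      on, off, rows)
        iti = spec.pit_iti if i < len(spec.pit_order) - 1 else 0.0
        presses(off, off + iti, None)
        _port_entries(rng, agent.port_entry_rate_baseline,
                      agent.port_entry_duration, off, off + iti, rows)
        t = off + iti
    return rows, {"session_end": t, "cue_order": list(spec.pit_order)}


def _gen_icss(spec: SessionSpec, agent: AgentModel, rng) -> tuple[list, dict]:
    """Self-stimulation session: active lever continuously reinforced with
    stimulation, inactive lever produces nothing."""
    rows = []
    for lever in sorted(agent.base_press_rate):
        for pt in _poisson_times(rng, agent.press_rate(lever, None),
                                 0.0, spec.icss_duration):
            rows.append((pt, f"press_{lever}", ""))
            if lever == spec.active_lever:
                rows.append((pt, "reward", "stim"))
    return rows, {"session_end": spec.icss_duration}


def gen_session_log(spec: SessionSpec, agent: AgentModel,
                    rat_id: str = "rat0") -> EventLog:
    """Simulate one behavioral session under ``spec`` with ``agent``."""
    spec.validate()
    agent.validate()
    rng = np.random.default_rng(spec.seed)
    builders = {
        "instrumental": _gen_instrumental,
        "pavlovian": _gen_pavlovian,
        "pit_test": _gen_pit_test,
        "icss": _gen_icss,
    }
    rows, meta = builders[spec.phase](spec, agent, rng)
    df = pd.DataFrame(rows, columns=["time_s", "event", "arg"])
    meta.update(phase=spec.phase, schedule=spec.schedule, seed=spec.seed,
                cue_outcome=dict(spec.cue_outcome),
                outcome_lever=dict(spec.outcome_lever))
    return EventLog(df=df, rat_id=rat_id, meta=meta)
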