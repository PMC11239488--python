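"""CSV schemas, configuration and the reproducible pipeline runner.

All on-disk times are seconds as decimal strings, 0-based from session
start; intervals are half-open. Files are plain CSV with an optional block
of ``# key=value`` provenance comments (config hash, seed, package version)
ahead of the header, so every output records how it was produced.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .synth import (
    AgentModel,
    EventLog,
    FidelityGenParams,
    PhotomGenParams,
    PhotometrySession,
    PulseTrain,
    SessionSpec,
    SpikeTrial,
    gen_evoked_spikes,
    gen_photometry_session,
    gen_pulse_train,
    gen_session_log,
)

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_table",
    "write_table",
    "write_photometry_session",
    "read_photometry_session",
    "write_spike_trials",
    "read_spike_trials",
    "write_event_log",
    "read_event_log",
    "run_pipeline",
]

SCHEMAS = {
    "photometry": ["time_s", "signal_470", "control_415"],
    "events": ["time_s", "label", "rat_id"],
    "spikes": ["trial_id", "spike_time_s"],
    "pulses": ["trial_id", "pulse_onset_s"],
    "behavior": ["time_s", "event", "arg"],
    "trials": ["trial_id", "rat_id", "label", "rel_time_s", "z"],
    "auc": ["trial_id", "label", "rat_id", "auc"],
    "windows": ["label_a", "label_b", "start_s", "end_s", "rule"],
    "scores": ["cue", "same", "different", "baseline_same",
               "baseline_different", "port_s"],
}

_TIME_COLUMN = {"photometry": "time_s", "events": "time_s", "behavior": "time_s"}


# --------------------------------------------------------------------------
# generic CSV layer
# --------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, schema: str,
                provenance: dict | None = None) -> None:
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ConfigError(f"{schema} table is missing columns {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df[cols].to_csv(fh, index=False)


def read_table(path, schema: str) -> tuple[pd.DataFrame, dict]:
    """Read and validate one CSV schema; returns (frame, provenance).

    Malformed rows are reported with their file line number; rows out of
    time order are re-sorted with a warning; duplicate trial rows and
    non-finite numbers are hard errors.
    """
    cols = SCHEMAS[schema]
    path = Path(path)
    lines = path.read_text().splitlines()
    provenance, body, body_line_nos = {}, [], []
    for i, line in enumerate(lines, start=1):
        if line.startswith("#"):
            txt = line.lstrip("# ")
            if "=" in txt:
                k, _, v = txt.partition("=")
                provenance[k.strip()] = v.strip()
            continue
        if line.strip() == "":
            continue
        body.append(line)
        body_line_nos.append(i)
    if not body:
        raise DataError(f"{path}: empty file")
    header = [c.strip() for c in body[0].split(",")]
    if header != cols:
        raise DataError(f"{path}: header {header} does not match schema "
                        f"{schema} {cols}")
    for row, lineno in zip(body[1:], body_line_nos[1:]):
        if len(row.split(",")) != len(cols):
            raise DataError(f"{path}: malformed row at line {lineno}: {row!r}")
    df = pd.read_csv(StringIO("\n".join(body)))
    nullable = {"behavior": ["arg"]}.get(schema, [])
    if "arg" in nullable and "arg" in df:
        df["arg"] = df["arg"].fillna("")
    bad = df.drop(columns=nullable, errors="ignore").isna().any(axis=1)
    if bad.any():
        lineno = body_line_nos[1 + int(np.flatnonzero(bad)[0])]
        raise DataError(f"{path}: missing value at line {lineno}")
    tcol = _TIME_COLUMN.get(schema)
    if tcol is not None and not df[tcol].is_monotonic_increasing:
        warnings.warn(f"{path}: rows out of time order; re-sorting",
                      stacklevel=2)
        df = df.sort_values(tcol, kind="stable").reset_index(drop=True)
    if schema == "trials" and df.duplicated(["trial_id", "rel_time_s"]).any():
        raise DataError(f"{path}: duplicate (trial_id, rel_time_s) rows")
    if schema == "pulses":
        dup = df.duplicated(["trial_id", "pulse_onset_s"]).any()
        if dup:
            raise DataError(f"{path}: duplicate pulse rows")
    return df, provenance


# --------------------------------------------------------------------------
# object-level writers/readers
# --------------------------------------------------------------------------


def write_photometry_session(session: PhotometrySession, out_dir,
                             provenance: dict | None = None) -> dict:
    out = Path(out_dir)
    prov = dict(provenance or {})
    prov.setdefault("rat_id", session.rat_id)
    photo = pd.DataFrame({"time_s": session.time,
                          "signal_470": session.signal_470,
                          "control_415": session.control_415})
    write_table(photo, out / "photometry.csv", "photometry", prov)
    write_table(session.events, out / "events.csv", "events", prov)
    return {"photometry": out / "photometry.csv", "events": out / "events.csv"}


def read_photometry_session(photometry_csv, events_csv) -> PhotometrySession:
    photo, prov = read_table(photometry_csv, "photometry")
    events, _ = read_table(events_csv, "events")
    rat = prov.get("rat_id", str(events["rat_id"].iloc[0]) if len(events) else "rat0")
    return PhotometrySession(time=photo["time_s"].to_numpy(float),
                             signal_470=photo["signal_470"].to_numpy(float),
                             control_415=photo["control_415"].to_numpy(float),
                             events=events, rat_id=rat)


def write_spike_trials(trials: list[SpikeTrial], out_dir,
                       provenance: dict | None = None) -> dict:
    out = Path(out_dir)
    train = trials[0].train
    prov = dict(provenance or {})
    prov.update(frequency_hz=train.frequency, duration_s=train.duration,
                pulse_width_s=train.pulse_width)
    spikes = pd.DataFrame(
        [(tr.trial_id, t) for tr in trials for t in tr.spike_times],
        columns=["trial_id", "spike_time_s"])
    pulses = pd.DataFrame(
        [(tr.trial_id, on) for tr in trials for on in tr.train.onsets],
        columns=["trial_id", "pulse_onset_s"])
    write_table(spikes, out / "spikes.csv", "spikes", prov)
    write_table(pulses, out / "pulses.csv", "pulses", prov)
    return {"spikes": out / "spikes.csv", "pulses": out / "pulses.csv"}


def read_spike_trials(spikes_csv, pulses_csv) -> list[SpikeTrial]:
    spikes, prov = read_table(spikes_csv, "spikes")
    pulses, pprov = read_table(pulses_csv, "pulses")
    prov = {**pprov, **prov}
    trials = []
    for trial_id, pgrp in pulses.groupby("trial_id"):
        onsets = np.sort(pgrp["pulse_onset_s"].to_numpy(float))
        if len(onsets) > 1:
            freq = 1.0 / np.median(np.diff(onsets))
        else:
            freq = float(prov.get("frequency_hz", 1.0))
        duration = float(prov.get("duration_s", onsets[-1] + 1.0 / freq))
        width = float(prov.get("pulse_width_s", 0.005))
        train = PulseTrain(frequency=float(prov.get("frequency_hz", freq)),
                           duration=duration, pulse_width=width, onsets=onsets)
        st = spikes.loc[spikes["trial_id"] == trial_id,
                        "spike_time_s"].to_numpy(float)
        trials.append(SpikeTrial(trial_id=int(trial_id), spike_times=st,
                                 train=train))
    return trials


def write_event_log(log: EventLog, path, provenance: dict | None = None) -> Path:
    prov = dict(provenance or {})
    prov.setdefault("rat_id", log.rat_id)
    meta = {k: v for k, v in log.meta.items()
            if isinstance(v, (str, int, float, dict, list))}
    prov.setdefault("meta", json.dumps(meta, sort_keys=True))
    write_table(log.df, path, "behavior", prov)
    return Path(path)


def read_event_log(path) -> EventLog:
    df, prov = read_table(path, "behavior")
    meta = json.loads(prov["meta"]) if "meta" in prov else {}
    return EventLog(df=df, rat_id=prov.get("rat_id", "rat0"), meta=meta)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_STAGES = {"photometry", "spikes", "behavior"}
_KNOWN_KEYS = {"seed", "stage", "out_dir", "photometry", "waveform",
               "spikes", "behavior"}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``photometry``/``waveform``/``spikes``/``behavior`` hold per-stage
    parameter overrides (defaults are the module defaults). Unknown keys
    are rejected; a seed is mandatory.
    """

    seed: int
    stage: str
    out_dir: str = "results"
    photometry: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)
    spikes: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or raw["seed"] is None:
            raise ConfigError("config must set an explicit integer seed")
        if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
            raise ConfigError("seed must be an integer")
        if raw.get("stage") not in _STAGES:
            raise ConfigError(f"stage must be one of {sorted(_STAGES)}")
        return cls(seed=raw["seed"], stage=raw["stage"],
                   out_dir=raw.get("out_dir", "results"),
                   photometry=dict(raw.get("photometry", {})),
                   waveform=dict(raw.get("waveform", {})),
                   spikes=dict(raw.get("spikes", {})),
                   behavior=dict(raw.get("behavior", {})))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config {path}: {e}") from e
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        return {"seed": self.seed, "stage": self.stage, "out_dir": self.out_dir,
                "photometry": self.photometry, "waveform": self.waveform,
                "spikes": self.spikes, "behavior": self.behavior}

    @property
    def sha256(self) -> str:
        # hash the analysis-relevant fields only: where the bundle lands
        # must not change what it contains
        blob = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def _provenance(config: RunConfig) -> dict:
    return {"config_sha256": config.sha256, "seed": config.seed,
            "optophys_version": __version__}


def _run_photometry(config: RunConfig, out: Path, prov: dict) -> dict:
    from . import photometry as ph
    from . import waveform as wf

    params = PhotomGenParams(seed=config.seed, **config.photometry)
    session = gen_photometry_session(params)
    write_photometry_session(session, out, prov)
    trace = ph.correct_trace(session)
    trials = ph.extract_trials(trace, session.events, pre=5.0, post=10.0)
    write_table(trials.to_frame(), out / "trials.csv", "trials", prov)
    auc = ph.trial_auc(trials)
    write_table(auc, out / "auc.csv", "auc", prov)

    wopts = dict(config.waveform)
    B = int(wopts.pop("B", 1000))
    n_perm = int(wopts.pop("n_perm", 1000))
    alpha = float(wopts.pop("alpha", 0.05))
    min_dur = float(wopts.pop("min_duration", 0.2))
    if wopts:
        raise ConfigError(f"unknown waveform options: {sorted(wopts)}")
    labels = sorted(set(trials.labels))
    win_rows, stats_out = [], {}
    for lab in labels:
        res = wf.bootstrap_waveform(trials.select(lab), B=B, alpha=alpha,
                                    min_duration=min_dur, seed=config.seed)
        for s, e in res.windows:
            win_rows.append({"label_a": lab, "label_b": "baseline",
                             "start_s": s, "end_s": e, "rule": "bootstrap>"})
    for la, lb in zip(labels, labels[1:]):
        res = wf.permutation_compare(trials.select(la), trials.select(lb),
                                     n_perm=n_perm, alpha=alpha,
                                     min_duration=min_dur, seed=config.seed)
        for s, e in res.windows:
            win_rows.append({"label_a": la, "label_b": lb,
                             "start_s": s, "end_s": e, "rule": "permutation>="})
    write_table(pd.DataFrame(win_rows, columns=SCHEMAS["windows"]),
                out / "windows.csv", "windows", prov)
    if len(labels) >= 2:
        mixed = ph.compare_auc_mixed(auc, labels[0], labels[1],
                                     allow_single_subject=True)
        stats_out["mixed_auc"] = {
            "event_a": mixed.event_a, "event_b": mixed.event_b,
            "estimate": mixed.estimate, "se": mixed.se,
            "stat": mixed.stat, "p": mixed.pvalue,
        }
    stats_out["n_trials"] = int(trials.n_trials)
    stats_out["n_windows"] = len(win_rows)
    return stats_out


def _run_spikes(config: RunConfig, out: Path, prov: dict) -> dict:
    from . import spikes as sp

    opts = dict(config.spikes)
    freqs = opts.pop("frequencies", [20.0, 50.0])
    n_trials = int(opts.pop("n_trials", 10))
    if opts:
        raise ConfigError(f"unknown spikes options: {sorted(opts)}")
    result = {}
    for freq in freqs:
        train = gen_pulse_train(freq, 1.0)
        params = FidelityGenParams.for_frequency(freq, n_trials=n_trials,
                                                 seed=config.seed)
        trials = gen_evoked_spikes(train, params)
        sub = out / f"stim_{int(freq)}hz"
        write_spike_trials(trials, sub, prov)
        summary = sp.summarize_trials(trials)
        summary.to_csv(sub / "fidelity.csv", index=False)
        sp.per_pulse_probability(trials).to_csv(sub / "per_pulse.csv", index=False)
        result[f"{int(freq)}hz"] = {
            "mean_fidelity": float(summary["fidelity"].mean()),
            "mean_rate_hz": float(summary["rate_hz"].mean()),
            "mean_latency_k": float(summary["latency_k"].mean()),
        }
    return result


def _run_behavior(config: RunConfig, out: Path, prov: dict) -> dict:
    from . import behavior as bh

    opts = dict(config.behavior)
    schedule = opts.pop("schedule", "CRF")
    if opts:
        raise ConfigError(f"unknown behavior options: {sorted(opts)}")
    spec = SessionSpec(phase="instrumental", schedule=schedule, seed=config.seed)
    agent = AgentModel(saturating=True)
    log = gen_session_log(spec, agent)
    write_event_log(log, out / "behavior.csv", prov)

    pit_spec = SessionSpec(phase="pit_test", seed=config.seed + 1)
    pit_agent = AgentModel(
        base_press_rate={"L": 4.0, "R": 4.0},
        cue_press_multiplier={("clicker", "L"): 3.0, ("noise", "R"): 3.0},
        port_entry_rate=2.0)
    pit_log = gen_session_log(pit_spec, pit_agent)
    write_event_log(pit_log, out / "pit_test.csv", prov)
    scores = bh.pit_score(pit_log)
    write_table(scores.per_cue.reset_index(), out / "scores.csv", "scores", prov)
    power = bh.power_rm_anova(bh.PowerSpec(partial_eta_sq=0.8, alpha=0.05,
                                           n_groups=2, n_total=11))
    return {"rewards_per_lever": log.meta["rewards_per_lever"],
            "pit_same_minus_different": float(
                (scores.per_cue["same"] - scores.per_cue["different"]).mean()),
            "power_post_hoc": power}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured stage end to end; identical configs produce
    identical result bundles. Returns the machine-readable report, which is
    also written to ``<out_dir>/report.json`` next to ``provenance.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    runner = {"photometry": _run_photometry, "spikes": _run_spikes,
              "behavior": _run_behavior}[config.stage]
    report = runner(config, out, prov)
    (out / "provenance.json").write_text(
        json.dumps({**prov, "config": config.to_dict()}, indent=2,
                   sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
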