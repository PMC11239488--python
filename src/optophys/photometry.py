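"""Fiber-photometry preprocessing and trial-level dopamine quantification.

Pipeline: (1) isosbestic correction — after discarding the first 60 s, the
415-nm control channel is fit by ordinary least squares to the 470-nm sensor
channel and the fitted trace serves as the baseline F0, giving
dF/F = (signal - F0) / F0; (2) event alignment — peri-event segments are
z-scored per trial against the 5-s pre-event baseline; (3) the area under
the z-scored curve over the first 3 s after onset summarizes each trial;
(4) trial AUCs are compared between event types with a linear mixed-effects
model carrying a random intercept per subject (auc ~ event + (1 | rat)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DataError,
    DegenerateBaselineError,
    DegenerateFitError,
    NormalizationError,
)
from .synth import PhotometrySession

__all__ = [
    "CorrectedTrace",
    "TrialMatrix",
    "MixedAucResult",
    "correct_trace",
    "extract_trials",
    "trial_auc",
    "compare_auc_mixed",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrectedTrace:
    """Bleaching/motion-corrected dF/F on the trimmed time grid."""

    time: np.ndarray
    dff: np.ndarray
    slope: float
    intercept: float
    rat_id: str = "rat0"

    @property
    def dt(self) -> float:
        return self.time[1] - self.time[0]


@dataclass
class TrialMatrix:
    """Event-aligned, per-trial z-scored dF/F segments on a shared axis."""

    data: np.ndarray  # (n_trials, n_timepoints)
    rel_time: np.ndarray
    labels: np.ndarray
    rat_ids: np.ndarray
    trial_ids: np.ndarray
    baseline: tuple = (-5.0, 0.0)
    dropped: list = field(default_factory=list)  # (event_time, label, reason)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return self.rel_time[1] - self.rel_time[0]

    def select(self, label: str) -> "TrialMatrix":
        m = self.labels == label
        return TrialMatrix(self.data[m], self.rel_time, self.labels[m],
                           self.rat_ids[m], self.trial_ids[m], self.baseline)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_trials):
            rows.append(pd.DataFrame({
                "trial_id": self.trial_ids[i],
                "rat_id": self.rat_ids[i],
                "label": self.labels[i],
                "rel_time_s": self.rel_time,
                "z": self.data[i],
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialMatrix":
        piv = df.pivot(index="trial_id", columns="rel_time_s", values="z")
        meta = df.drop_duplicates("trial_id").set_index("trial_id")
        piv = piv.sort_index()
        meta = meta.loc[piv.index]
        return cls(data=piv.to_numpy(float),
                   rel_time=piv.columns.to_numpy(float),
                   labels=meta["label"].to_numpy(),
                   rat_ids=meta["rat_id"].to_numpy(),
                   trial_ids=piv.index.to_numpy())


def correct_trace(session: PhotometrySession, trim: float = 60.0,
                  exclude_windows: list[tuple[float, float]] | None = None
                  ) -> CorrectedTrace:
    """Isosbestic correction of a two-channel session.

    The first ``trim`` seconds are discarded, the control channel is
    regressed onto the signal channel (OLS) over the remaining span, and
    dF/F = (signal - fitted) / fitted.

    ``exclude_windows`` optionally masks absolute-time windows (e.g. around
    known stimulation events) out of the regression *fit only*; dF/F is
    still computed over the full trimmed trace. By default the whole
    trimmed trace enters the fit.
    """
    t0 = session.time[0]
    keep = session.time >= t0 + trim
    if keep.sum() < 2:
        raise DataError("fewer than 2 samples remain after trimming")
    t = session.time[keep]
    sig = np.asarray(session.signal_470, float)[keep]
    ctl = np.asarray(session.control_415, float)[keep]

    fit_mask = np.ones(len(t), dtype=bool)
    for a, b in exclude_windows or []:
        fit_mask &= ~((t >= a) & (t < b))
    if fit_mask.sum() < 2:
        raise DataError("exclusion windows leave fewer than 2 fit samples")
    c_fit, s_fit = ctl[fit_mask], sig[fit_mask]
    if np.ptp(c_fit) == 0 or np.var(c_fit) == 0:
        raise DegenerateFitError("control channel has zero variance")
    slope, intercept = np.polyfit(c_fit, s_fit, 1)
    fitted = slope * ctl + intercept
    if np.any(fitted <= 0):
        raise NormalizationError("fitted control (F0) is non-positive somewhere")
    dff = (sig - fitted) / fitted
    if not np.all(np.isfinite(dff)):
        raise DataError("non-finite dF/F values")
    return CorrectedTrace(time=t, dff=dff, slope=float(slope),
                          intercept=float(intercept), rat_id=session.rat_id)


def extract_trials(trace: CorrectedTrace, events: pd.DataFrame,
                   pre: float = 5.0, post: float = 10.0,
                   baseline: tuple = (-5.0, 0.0)) -> TrialMatrix:
    """Align dF/F to events and z-score each trial on its baseline window.

    The baseline is half-open [b0, b1) so the event sample itself never
    enters the baseline. Events without full [-pre, +post] support inside
    the trace are rejected with a logged reason and listed in
    ``TrialMatrix.dropped`` (never silently). A zero-s.d. baseline raises
    DegenerateBaselineError naming the trial.
    """
    if baseline[0] < -pre or baseline[1] > post:
        raise ConfigError("baseline window must lie inside [-pre, post]")
    dt = trace.dt
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    k = np.arange(-n_pre, n_post + 1)
    rel_time = k * dt
    # half-open [b0, b1) on the integer grid, immune to float grid error
    bmask = (k >= int(round(baseline[0] / dt))) & (k < int(round(baseline[1] / dt)))
    if bmask.sum() < 2:
        raise ConfigError("baseline window contains fewer than 2 samples")

    rows, labels, rats, ids, dropped = [], [], [], [], []
    for trial_id, (_, ev) in enumerate(events.iterrows()):
        idx = int(round((ev["time_s"] - trace.time[0]) / dt))
        lo, hi = idx - n_pre, idx + n_post + 1
        if lo < 0 or hi > len(trace.dff):
            reason = (f"event at {ev['time_s']:.2f} s lacks full "
                      f"[-{pre:g}, +{post:g}] s support")
            logger.warning("dropping trial %d (%s): %s", trial_id, ev["label"], reason)
            dropped.append((float(ev["time_s"]), ev["label"], reason))
            continue
        seg = trace.dff[lo:hi]
        mu = seg[bmask].mean()
        sd = seg[bmask].std(ddof=0)
        if sd == 0:
            raise DegenerateBaselineError(trial_id)
        rows.append((seg - mu) / sd)
        labels.append(ev["label"])
        rats.append(ev.get("rat_id", trace.rat_id))
        ids.append(trial_id)
    data = np.array(rows) if rows else np.empty((0, len(rel_time)))
    return TrialMatrix(data=data, rel_time=rel_time,
                       labels=np.array(labels), rat_ids=np.array(rats),
                       trial_ids=np.array(ids, dtype=int),
                       baseline=tuple(baseline), dropped=dropped)


def trial_auc(trials: TrialMatrix, span: tuple = (0.0, 3.0)) -> pd.DataFrame:
    """Trapezoidal area under each trial's z-scored curve over ``span`` (z*s)."""
    eps = 1e-9
    if span[0] < trials.rel_time[0] - eps or span[1] > trials.rel_time[-1] + eps:
        raise ConfigError("AUC span lies outside the trial window")
    m = (trials.rel_time >= span[0] - eps) & (trials.rel_time <= span[1] + eps)
    auc = np.trapezoid(trials.data[:, m], trials.rel_time[m], axis=1)
    if not np.all(np.isfinite(auc)):
        raise DataError("non-finite AUC")
    return pd.DataFrame({
        "trial_id": trials.trial_ids,
        "label": trials.labels,
        "rat_id": trials.rat_ids,
        "auc": auc,
    })


@dataclass
class MixedAucResult:
    """Fixed event effect (event_b - event_a) from the mixed model."""

    event_a: str
    event_b: str
    estimate: float
    se: float
    stat: float
    pvalue: float
    n_obs: int
    n_subjects: int
    converged: bool
    model_result: object | None = None

    def summary(self) -> str:
        return (f"AUC ~ event + (1 | rat): {self.event_b} - {self.event_a} = "
                f"{self.estimate:.4f} (s.e. {self.se:.4f}), z = {self.stat:.3f}, "
                f"p = {self.pvalue:.4g} ({self.n_obs} trials, "
                f"{self.n_subjects} subjects)")


def compare_auc_mixed(records: pd.DataFrame, event_a: str, event_b: str,
                      allow_single_subject: bool = False) -> MixedAucResult:
    """Compare per-trial AUCs between two event types with a random
    intercept per subject, fit by maximum likelihood.

    With a single subject the random intercept is unidentifiable; pass
    ``allow_single_subject=True`` to fall back to plain OLS.
    """
    import statsmodels.formula.api as smf

    for lab in (event_a, event_b):
        if lab not in set(records["label"]):
            raise DataError(f"event label {lab!r} absent from AUC records")
    sub = records[records["label"].isin([event_a, event_b])].copy()
    sub["event"] = (sub["label"] == event_b).astype(float)
    n_subj = sub["rat_id"].nunique()

    if np.ptp(sub["auc"].to_numpy()) == 0:
        # all AUCs identical: effect is exactly 0 with no evidence against it
        return MixedAucResult(event_a, event_b, 0.0, 0.0, 0.0, 1.0,
                              len(sub), n_subj, True)
    if n_subj < 2:
        if not allow_single_subject:
            raise DataError("need >= 2 subjects (or allow_single_subject=True)")
        res = smf.ols("auc ~ event", data=sub).fit()
        return MixedAucResult(event_a, event_b, float(res.params["event"]),
                              float(res.bse["event"]), float(res.tvalues["event"]),
                              float(res.pvalues["event"]), len(sub), n_subj,
                              True, res)
    model = smf.mixedlm("auc ~ event", data=sub, groups=sub["rat_id"])
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # a near-zero random-intercept variance legitimately sits on the
        # boundary (singular covariance); the fixed-effect inference stands
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
        out = MixedAucResult(event_a, event_b, float(res.params["event"]),
                             float(res.bse["event"]),
                             float(res.tvalues["event"]),
                             float(res.pvalues["event"]), len(sub), n_subj,
                             bool(res.converged), res)
    return out
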