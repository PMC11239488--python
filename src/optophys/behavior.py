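"""Behavioral scoring and the statistical contracts applied to it.

Covers: response-rate extraction from event logs (lever presses per minute
and food-port occupancy per labeled period), transfer-test scoring
(same-lever / different-lever / pre-cue-baseline press rates resolved
through the cue -> outcome -> lever map), the elevation ratio
(X - baseline) / (X + baseline) used for blocking, the Pearson correlation
between self-stimulation responding (log(x + 1)-transformed presses in the
first 5 min) and the unblocking ratio, a balanced two-way mixed-design
repeated-measures ANOVA with simple-effect follow-ups and one-tailed t
variants, and the post hoc power of an F test from a partial eta-squared
effect size (noncentral F with lambda = f^2 * N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .synth import EventLog

__all__ = [
    "PitScores",
    "ElevationRatio",
    "PowerSpec",
    "AnovaTable",
    "rates",
    "pit_score",
    "elevation_ratio",
    "icss_unblocking_corr",
    "rm_anova",
    "simple_effect",
    "one_tailed_t",
    "power_rm_anova",
]

_EPS = 1e-12


# --------------------------------------------------------------------------
# rate extraction
# --------------------------------------------------------------------------


def _port_intervals(df: pd.DataFrame) -> np.ndarray:
    """(n, 2) array of port in/out intervals; enforces strict alternation."""
    port = df[df["event"].isin(["port_in", "port_out"])]
    kinds = port["event"].to_numpy()
    times = port["time_s"].to_numpy(float)
    if len(kinds) % 2 or np.any(kinds[0::2] != "port_in") or np.any(
            kinds[1::2] != "port_out"):
        raise DataError("port_in/port_out events do not strictly alternate")
    iv = times.reshape(-1, 2)
    if np.any(iv[:, 1] < iv[:, 0]):
        raise DataError("port_out precedes its port_in")
    return iv


def rates(log: EventLog, periods: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Press rates (per min, per lever) and port occupancy (s) per period.

    ``periods`` is a list of (label, start_s, end_s) half-open windows.
    Port time is the summed overlap of in->out intervals with the period.
    """
    df = log.df
    port_iv = _port_intervals(df)
    press_times = {
        lev: df.loc[df["event"] == f"press_{lev}", "time_s"].to_numpy(float)
        for lev in ("L", "R")
    }
    rows = []
    for label, start, end in periods:
        if end <= start:
            raise ConfigError(f"period {label!r} has non-positive duration")
        minutes = (end - start) / 60.0
        row = {"period": label, "start_s": start, "end_s": end}
        for lev, times in press_times.items():
            n = int(np.sum((times >= start) & (times < end)))
            row[f"press_{lev}_per_min"] = n / minutes
        if len(port_iv):
            overlap = np.clip(np.minimum(port_iv[:, 1], end)
                              - np.maximum(port_iv[:, 0], start), 0, None)
            row["port_s"] = float(overlap.sum())
        else:
            row["port_s"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# transfer-test scoring
# --------------------------------------------------------------------------


@dataclass
class PitScores:
    """Press rates on the same / different lever and pre-cue baselines.

    ``per_trial``: one row per cue presentation; ``per_cue``: aggregated
    (mean) rates per cue label.
    """

    per_trial: pd.DataFrame
    per_cue: pd.DataFrame
    baseline_window: float
    aggregate: str


def _cue_presentations(df: pd.DataFrame) -> list[tuple[str, float, float]]:
    cues = df[df["event"].isin(["cue_on", "cue_off"])]
    out, open_cue = [], None
    for _, r in cues.iterrows():
        if r["event"] == "cue_on":
            if open_cue is not None:
                raise DataError("overlapping cue presentations")
            open_cue = (r["arg"], r["time_s"])
        else:
            if open_cue is None or open_cue[0] != r["arg"]:
                raise DataError("cue_off without matching cue_on")
            out.append((open_cue[0], open_cue[1], r["time_s"]))
            open_cue = None
    if open_cue is not None:
        raise DataError("cue_on without matching cue_off")
    return out


def pit_score(logs: EventLog | list[EventLog],
              mapping: dict | None = None,
              baseline_window: float = 120.0,
              aggregate: str = "trials") -> PitScores:
    """Score transfer-test sessions.

    ``mapping`` resolves each cue's same lever: {cue: lever}; when omitted
    it is composed from the log's cue -> outcome and outcome -> lever
    metadata. The baseline is the ``baseline_window`` seconds immediately
    preceding each cue onset. ``aggregate='trials'`` averages across all
    cue presentations of all sessions; ``aggregate='sessions'`` averages
    within each session first.
    """
    if aggregate not in {"trials", "sessions"}:
        raise ConfigError("aggregate must be 'trials' or 'sessions'")
    if isinstance(logs, EventLog):
        logs = [logs]
    rows = []
    for si, log in enumerate(logs):
        if mapping is None:
            co = log.meta.get("cue_outcome")
            ol = log.meta.get("outcome_lever")
            if not co or not ol:
                raise ConfigError("no cue->lever mapping available")
            cue_lever = {c: ol[o] for c, o in co.items()}
        else:
            cue_lever = dict(mapping)
        if (log.df["event"] == "reward").any():
            raise DataError("transfer-test log contains reward deliveries")
        for ti, (cue, on, off) in enumerate(_cue_presentations(log.df)):
            if cue not in cue_lever:
                raise ConfigError(f"cue {cue!r} missing from the mapping")
            same = cue_lever[cue]
            diff = ({"L", "R"} - {same}).pop()
            r = rates(log, [("cue", on, off),
                            ("baseline", max(0.0, on - baseline_window), on)])
            r = r.set_index("period")
            rows.append({
                "session": si, "trial": ti, "cue": cue, "same_lever": same,
                "same": r.loc["cue", f"press_{same}_per_min"],
                "different": r.loc["cue", f"press_{diff}_per_min"],
                "baseline_same": r.loc["baseline", f"press_{same}_per_min"],
                "baseline_different": r.loc["baseline", f"press_{diff}_per_min"],
                "port_s": r.loc["cue", "port_s"],
            })
    per_trial = pd.DataFrame(rows)
    cols = ["same", "different", "baseline_same", "baseline_different", "port_s"]
    if aggregate == "sessions":
        per_session = per_trial.groupby(["session", "cue"])[cols].mean()
        per_cue = per_session.groupby("cue").mean()
    else:
        per_cue = per_trial.groupby("cue")[cols].mean()
    return PitScores(per_trial=per_trial, per_cue=per_cue,
                     baseline_window=baseline_window, aggregate=aggregate)


# --------------------------------------------------------------------------
# elevation ratio and the ICSS correlation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElevationRatio:
    """(X - baseline) / (X + baseline), defined as 0 when both are 0."""

    value: float
    x: float
    baseline: float

    def __float__(self):
        return self.value


def elevation_ratio(x: float, baseline: float) -> ElevationRatio:
    if x < 0 or baseline < 0:
        raise ConfigError("elevation ratio inputs must be non-negative")
    total = x + baseline
    value = 0.0 if total == 0 else (x - baseline) / total
    return ElevationRatio(value=float(value), x=float(x), baseline=float(baseline))


@dataclass(frozen=True)
class CorrResult:
    r: float
    r_squared: float
    pvalue: float
    n: int
    alternative: str

    def summary(self) -> str:
        return (f"Pearson r = {self.r:.3f}, R^2 = {self.r_squared:.3f}, "
                f"one-tailed p = {self.pvalue:.3f} (n = {self.n})")


def icss_unblocking_corr(icss_presses, ratios, alternative: str = "greater"
                         ) -> CorrResult:
    """Pearson correlation of log(x + 1)-transformed self-stimulation
    presses (first 5 min) with per-subject elevation ratios.

    One-tailed by default for the directional hypothesis that stronger
    self-stimulation predicts stronger unblocking.
    """
    x = np.log1p(np.asarray(icss_presses, float))
    y = np.asarray([float(r) for r in ratios], float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrResult(r=float(res.statistic), r_squared=float(res.statistic) ** 2,
                      pvalue=float(res.pvalue), n=len(x), alternative=alternative)


# --------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA
# --------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """F, df and p per effect, plus partial eta-squared."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    def summary(self) -> str:
        lines = []
        for _, r in self.table.iterrows():
            lines.append(f"{r['effect']}: F({r['df1']:g}, {r['df2']:g}) = "
                         f"{r['F']:.3f}, p = {r['p']:.4g}, "
                         f"partial eta^2 = {r['partial_eta_sq']:.3f}")
        return "\n".join(lines)


def _f_p(ss_eff, df1, ss_err, df2):
    if df1 <= 0 or df2 <= 0:
        raise DataError("non-positive degrees of freedom")
    if ss_err <= _EPS:
        if ss_eff <= _EPS:
            return 0.0, 1.0, 0.0
        return np.inf, 0.0, 1.0
    f = (ss_eff / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    peta = ss_eff / (ss_eff + ss_err)
    return float(f), p, float(peta)


def _check_balanced(df, dv, subject, within):
    counts = df.groupby([subject, within], observed=True)[dv].count()
    wide = counts.unstack(within)
    if wide.isna().any().any() or (wide != 1).any().any():
        raise DataError("unbalanced within-subject design is not supported: "
                        "each subject needs exactly one value per within level")


def rm_anova(data: pd.DataFrame, dv: str, subject: str, within: str,
             between: str | None = None) -> AnovaTable:
    """Two-way mixed-design repeated-measures ANOVA (one between-subject
    factor, one within-subject factor), or a one-way repeated-measures
    ANOVA when ``between`` is None.

    The within-subject design must be balanced (exactly one observation per
    subject per within level); group sizes may differ (weighted-means sums
    of squares). The between effect is tested against subjects-within-
    groups, the within effect and the interaction against the within x
    subject residual.
    """
    df = data.dropna(subset=[dv]).copy()
    _check_balanced(df, dv, subject, within)
    wide = df.pivot(index=subject, columns=within, values=dv)
    y = wide.to_numpy(float)
    n_subj, b = y.shape
    if n_subj < 2 or b < 2:
        raise DataError("need >= 2 subjects and >= 2 within levels")
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    level_mean = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = b * ((subj_mean - grand) ** 2).sum()
    ss_within_lev = n_subj * ((level_mean - grand) ** 2).sum()

    rows = []
    if between is not None:
        groups = df.groupby(subject, observed=True)[between].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else None)
        if groups.isna().any():
            raise DataError("between-group label varies within a subject")
        groups = groups.loc[wide.index]
        levels = groups.unique()
        a = len(levels)
        if a < 2:
            raise DataError("between factor needs >= 2 groups")
        if groups.value_counts().min() < 2:
            raise DataError("need >= 2 subjects per group")
        gm = {g: y[groups.to_numpy() == g].mean() for g in levels}
        ng = {g: int((groups.to_numpy() == g).sum()) for g in levels}
        ss_a = b * sum(ng[g] * (gm[g] - grand) ** 2 for g in levels)
        ss_subj_within = ss_between_subj - ss_a
        # cell means: group x within level
        ss_cells = 0.0
        for g in levels:
            cells = y[groups.to_numpy() == g].mean(axis=0)
            ss_cells += ng[g] * ((cells - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_within_lev
        ss_err = ss_total - ss_between_subj - ss_within_lev - ss_ab
        df_err = (n_subj - a) * (b - 1)
        for name, ss_eff, df1, ss_e, df2 in [
            (between, ss_a, a - 1, ss_subj_within, n_subj - a),
            (within, ss_within_lev, b - 1, ss_err, df_err),
            (f"{between} x {within}", ss_ab, (a - 1) * (b - 1), ss_err, df_err),
        ]:
            f, p, peta = _f_p(ss_eff, df1, ss_e, df2)
            rows.append({"effect": name, "SS": ss_eff, "df1": df1, "df2": df2,
                         "F": f, "p": p, "partial_eta_sq": peta})
    else:
        ss_err = ss_total - ss_between_subj - ss_within_lev
        df_err = (n_subj - 1) * (b - 1)
        f, p, peta = _f_p(ss_within_lev, b - 1, ss_err, df_err)
        rows.append({"effect": within, "SS": ss_within_lev, "df1": b - 1,
                     "df2": df_err, "F": f, "p": p, "partial_eta_sq": peta})
    return AnovaTable(table=pd.DataFrame(rows))


def simple_effect(data: pd.DataFrame, dv: str, subject: str, factor: str,
                  at: tuple[str, object]) -> pd.Series:
    """Planned simple-effect analysis: the effect of ``factor`` with the
    other factor fixed at ``at = (column, level)``.

    A within-subject factor is tested with a one-way repeated-measures
    ANOVA; a between-subject factor with a one-way ANOVA on subject means.
    """
    col, level = at
    sub = data[data[col] == level]
    if sub.empty:
        raise DataError(f"no rows at {col} == {level!r}")
    per_level = sub.groupby(subject, observed=True)[factor].nunique()
    if per_level.max() > 1:  # factor varies within subject -> RM
        tab = rm_anova(sub, dv=dv, subject=subject, within=factor)
        return tab.table.iloc[0]
    # between-subject one-way ANOVA
    subj = sub.groupby([subject, factor], observed=True)[dv].mean().reset_index()
    groups = [g[dv].to_numpy() for _, g in subj.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise DataError("simple effect needs >= 2 levels")
    gm = np.concatenate(groups).mean()
    ss_eff = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
    ss_err = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    f, p, peta = _f_p(ss_eff, df1, ss_err, df2)
    return pd.Series({"effect": factor, "SS": ss_eff, "df1": df1, "df2": df2,
                      "F": f, "p": p, "partial_eta_sq": peta})


def one_tailed_t(x, y=None, direction: str = None, paired: bool = False):
    """One-tailed t test; ``direction`` ('greater' or 'less') is required —
    directional tests are never a silent default."""
    if direction not in {"greater", "less"}:
        raise ConfigError("direction must be 'greater' or 'less'")
    x = np.asarray(x, float)
    if y is None:
        res = stats.ttest_1samp(x, 0.0, alternative=direction)
    elif paired:
        res = stats.ttest_rel(x, np.asarray(y, float), alternative=direction)
    else:
        res = stats.ttest_ind(x, np.asarray(y, float), alternative=direction)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# post hoc power
# --------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """Post hoc power of a between-groups F test from partial eta-squared.

    f = sqrt(eta^2 / (1 - eta^2)); noncentrality lambda = f^2 * N with
    numerator df = n_groups - 1 and denominator df = n_total - n_groups.
    """

    partial_eta_sq: float
    alpha: float = 0.05
    n_groups: int = 2
    n_total: int = 11

    @property
    def effect_size_f(self) -> float:
        if not 0 < self.partial_eta_sq < 1:
            raise ConfigError("partial eta-squared must lie in (0, 1)")
        return float(np.sqrt(self.partial_eta_sq / (1 - self.partial_eta_sq)))

    def validate(self):
        if not 0 <= self.partial_eta_sq < 1:
            raise ConfigError("partial eta-squared must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_groups < 2 or self.n_total <= self.n_groups:
            raise ConfigError("need n_total > n_groups >= 2")


def power_rm_anova(spec: PowerSpec) -> float:
    """Achieved power 1 - beta of the noncentral F test under ``spec``.

    With eta^2 -> 0 the noncentrality vanishes and the power equals alpha.
    """
    spec.validate()
    df1 = spec.n_groups - 1
    df2 = spec.n_total - spec.n_groups
    eta = spec.partial_eta_sq
    lam = (eta / (1 - eta)) * spec.n_total
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))
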