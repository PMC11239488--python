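"""Behavioral scoring: rates, transfer-test scores, elevation ratios, the
self-stimulation correlation, the mixed RM-ANOVA contract and post hoc
power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from optophys import behavior as bh
from optophys.errors import ConfigError, DataError
from optophys.synth import AgentModel, EventLog, SessionSpec, gen_session_log


def _log(rows, meta=None):
    df = pd.DataFrame(rows, columns=["time_s", "event", "arg"])
    return EventLog(df=df, meta=meta or {})


class TestRates:
    def test_empty_log_has_zero_rates(self):
        out = bh.rates(_log([]), [("p", 0.0, 60.0)])
        assert out.loc[0, "press_L_per_min"] == 0.0
        assert out.loc[0, "port_s"] == 0.0

    def test_ten_presses_in_two_minutes_is_five_per_minute(self):
        rows = [(10.0 + i, "press_L", "") for i in range(10)]
        out = bh.rates(_log(rows), [("cue", 0.0, 120.0)])
        assert out.loc[0, "press_L_per_min"] == pytest.approx(5.0)

    def test_port_time_apportioned_by_overlap(self):
        # one entry spanning the period boundary at t = 60
        rows = [(55.0, "port_in", ""), (70.0, "port_out", "")]
        out = bh.rates(_log(rows), [("a", 0.0, 60.0), ("b", 60.0, 120.0)])
        assert out.loc[0, "port_s"] == pytest.approx(5.0)
        assert out.loc[1, "port_s"] == pytest.approx(10.0)

    def test_overlap_matches_10ms_occupancy_oracle(self):
        rng = np.random.default_rng(0)
        ins = np.sort(rng.uniform(0, 110, 8))
        outs = ins + rng.uniform(0.5, 6.0, 8)
        # enforce alternation
        keep = [0]
        for i in range(1, 8):
            if ins[i] > outs[keep[-1]]:
                keep.append(i)
        rows = []
        for i in keep:
            rows += [(ins[i], "port_in", ""), (outs[i], "port_out", "")]
        periods = [("a", 0.0, 40.0), ("b", 40.0, 90.0), ("c", 90.0, 130.0)]
        out = bh.rates(_log(rows), periods)
        grid = np.arange(0, 130.0, 0.01) + 0.005
        occupied = np.zeros_like(grid, dtype=bool)
        for i in keep:
            occupied |= (grid >= ins[i]) & (grid < outs[i])
        for j, (_, s, e) in enumerate(periods):
            oracle = occupied[(grid >= s) & (grid < e)].sum() * 0.01
            assert out.loc[j, "port_s"] == pytest.approx(oracle, abs=0.05)

    def test_unmatched_port_events_rejected(self):
        with pytest.raises(DataError):
            bh.rates(_log([(5.0, "port_in", "")]), [("p", 0.0, 10.0)])


class TestPitScore:
    META = {"cue_outcome": {"clicker": "pellet", "noise": "stim"},
            "outcome_lever": {"pellet": "L", "stim": "R"}}

    def test_selective_agent_presses_same_lever_only(self):
        rows = [(480.0, "cue_on", "clicker"), (600.0, "cue_off", "clicker"),
                (900.0, "cue_on", "noise"), (1020.0, "cue_off", "noise")]
        rows += [(500.0 + i, "press_L", "") for i in range(12)]
        scores = bh.pit_score(_log(rows, self.META))
        clicker = scores.per_cue.loc["clicker"]
        noise = scores.per_cue.loc["noise"]
        assert clicker["same"] == pytest.approx(6.0)
        assert clicker["different"] == 0.0
        assert noise["same"] == noise["different"] == 0.0

    def test_symmetric_agent_scores_equal_everywhere(self):
        spec = SessionSpec(phase="pit_test", seed=3)
        agent = AgentModel(base_press_rate={"L": 6.0, "R": 6.0})
        scores = bh.pit_score(gen_session_log(spec, agent))
        per = scores.per_trial
        # same/different partition the two levers; symmetric rates on average
        assert abs(per["same"].mean() - per["different"].mean()) < 2.0

    def test_cue_elevation_multiplier_recovered(self):
        """Agent whose cues triple same-lever pressing: recovered same-lever
        rate is ~3x baseline within 3 s.e. across 100 simulated tests."""
        mult, base_rate = 3.0, 6.0
        same_rates, base_rates = [], []
        for seed in range(100):
            spec = SessionSpec(phase="pit_test", seed=seed)
            agent = AgentModel(
                base_press_rate={"L": base_rate, "R": base_rate},
                cue_press_multiplier={("clicker", "L"): mult,
                                      ("noise", "R"): mult})
            scores = bh.pit_score(gen_session_log(spec, agent))
            same_rates.append(scores.per_trial["same"].mean())
            base_rates.append(scores.per_trial[
                ["baseline_same", "baseline_different"]].to_numpy().mean())
        same = np.asarray(same_rates)
        est = same.mean() / np.mean(base_rates)
        se = same.std(ddof=1) / np.sqrt(len(same)) / np.mean(base_rates)
        assert abs(est - mult) <= 3 * se
        for s in (bh.pit_score(gen_session_log(SessionSpec(phase="pit_test",
                                                           seed=0), agent)),):
            assert (s.per_cue["same"] > s.per_cue["different"]).all()

    def test_lever_relabeling_invariance(self, pit_log):
        swapped = EventLog(
            df=pit_log.df.assign(event=pit_log.df["event"].map(
                {"press_L": "press_R", "press_R": "press_L"}).fillna(
                    pit_log.df["event"])),
            meta={**pit_log.meta,
                  "outcome_lever": {"pellet": "R", "stim": "L"}})
        a = bh.pit_score(pit_log).per_cue
        b = bh.pit_score(swapped).per_cue
        pd.testing.assert_frame_equal(a, b)

    def test_reward_in_test_log_rejected(self):
        rows = [(480.0, "cue_on", "clicker"), (600.0, "cue_off", "clicker"),
                (500.0, "reward", "pellet")]
        with pytest.raises(DataError):
            bh.pit_score(_log(rows, self.META))

    def test_missing_cue_mapping_rejected(self):
        rows = [(480.0, "cue_on", "tone"), (600.0, "cue_off", "tone")]
        with pytest.raises(ConfigError):
            bh.pit_score(_log(rows, self.META))


class TestElevationRatio:
    def test_reference_points(self):
        assert float(bh.elevation_ratio(3.0, 1.0)) == pytest.approx(0.5)
        assert float(bh.elevation_ratio(2.0, 2.0)) == 0.0
        assert float(bh.elevation_ratio(0.0, 0.0)) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigError):
            bh.elevation_ratio(-1.0, 2.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(x=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_bounded_and_antisymmetric(self, x, b):
        r = float(bh.elevation_ratio(x, b))
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(-float(bh.elevation_ratio(b, x)))


class TestIcssCorrelation:
    def test_perfectly_linear_relation_gives_unit_r(self):
        presses = np.array([2.0, 10.0, 40.0, 100.0, 300.0])
        ratios = 0.1 * np.log1p(presses) - 0.2
        res = bh.icss_unblocking_corr(presses, ratios)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pvalue < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            bh.icss_unblocking_corr([5, 5, 5], [0.1, 0.2, 0.3])

    def test_one_tailed_calibration_under_independence(self):
        """Independent pairs (n = 9): one-tailed p < 0.05 in about 5% of
        2,000 replicates (within 1.5 points)."""
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            presses = rng.uniform(0, 200, 9)
            ratios = rng.standard_normal(9)
            if bh.icss_unblocking_corr(presses, ratios).pvalue < 0.05:
                hits += 1
        assert 0.035 <= hits / n_rep <= 0.065

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(a=st.floats(0.1, 5.0), b=st.floats(-3.0, 3.0))
    def test_r_invariant_under_affine_ratio_transforms(self, a, b):
        presses = np.array([2.0, 7.0, 21.0, 55.0, 160.0, 400.0])
        rng = np.random.default_rng(9)
        ratios = 0.3 * np.log1p(presses) + rng.standard_normal(6) * 0.2
        r0 = bh.icss_unblocking_corr(presses, ratios).r
        r1 = bh.icss_unblocking_corr(presses, a * ratios + b).r
        assert r1 == pytest.approx(r0, abs=1e-12)


def _mixed_frame(rng, delta=0.0, n1=4, n2=4, subj_sd=1.0, resid_sd=1.0,
                 within_effect=0.0, interaction=0.0):
    rows = []
    for g, (grp, n, off) in enumerate([("g1", n1, 0.0), ("g2", n2, delta)]):
        for s in range(n):
            u = rng.normal(0, subj_sd)
            for w, lev in enumerate(["w1", "w2"]):
                mu = off + u + within_effect * w + (interaction * w * g)
                rows.append({"subject": f"{grp}_s{s}", "group": grp,
                             "win": lev, "y": mu + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_responses_give_zero_f_unit_p(self):
        df = _mixed_frame(np.random.default_rng(0))
        df["y"] = 7.0
        tab = bh.rm_anova(df, dv="y", subject="subject", within="win",
                          between="group").table
        assert (tab["F"] == 0.0).all() and (tab["p"] == 1.0).all()

    def test_matches_hand_computed_sums_of_squares_on_2x2(self):
        """Balanced 2x2 fixture against an explicit SS decomposition."""
        y = {  # subject: (w1, w2)
            "a1": (3.0, 5.0), "a2": (4.0, 7.0), "a3": (2.0, 4.0),
            "b1": (6.0, 6.0), "b2": (8.0, 7.0), "b3": (7.0, 9.0),
        }
        rows = [{"subject": s, "group": s[0], "win": w, "y": v}
                for s, (v1, v2) in y.items()
                for w, v in [("w1", v1), ("w2", v2)]]
        df = pd.DataFrame(rows)
        tab = bh.rm_anova(df, dv="y", subject="subject", within="win",
                          between="group")
        # oracle: textbook sums of squares computed from first principles
        arr = np.array([list(v) for v in y.values()])  # 6 subjects x 2 levels
        grp = np.array([0, 0, 0, 1, 1, 1])
        grand = arr.mean()
        ss_between_subj = 2 * ((arr.mean(1) - grand) ** 2).sum()
        ss_a = 2 * sum(3 * (arr[grp == g].mean() - grand) ** 2 for g in (0, 1))
        ss_subj = ss_between_subj - ss_a
        ss_b = 6 * ((arr.mean(0) - grand) ** 2).sum()
        ss_cells = sum(3 * ((arr[grp == g].mean(0) - grand) ** 2).sum()
                       for g in (0, 1))
        ss_ab = ss_cells - ss_a - ss_b
        ss_total = ((arr - grand) ** 2).sum()
        ss_err = ss_total - ss_between_subj - ss_b - ss_ab
        f_a = (ss_a / 1) / (ss_subj / 4)
        f_b = (ss_b / 1) / (ss_err / 4)
        f_ab = (ss_ab / 1) / (ss_err / 4)
        got = tab.table.set_index("effect")["F"]
        assert got["group"] == pytest.approx(f_a, abs=1e-12)
        assert got["win"] == pytest.approx(f_b, abs=1e-12)
        assert got["group x win"] == pytest.approx(f_ab, abs=1e-12)

    def test_agrees_with_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        df = _mixed_frame(np.random.default_rng(1), delta=1.0,
                          within_effect=0.5, interaction=0.4)
        mine = bh.rm_anova(df, dv="y", subject="subject", within="win",
                           between="group").table
        theirs = pg.mixed_anova(data=df, dv="y", within="win",
                                subject="subject", between="group")
        np.testing.assert_allclose(mine["F"].to_numpy(),
                                   theirs["F"].to_numpy(), rtol=1e-10)
        np.testing.assert_allclose(mine["p"].to_numpy(),
                                   theirs["p_unc"].to_numpy(), rtol=1e-10)

    def test_between_group_power_with_offset_two(self):
        """Groups offset by d = 2 with subject-level s.d. 1 (n = 6 + 5): the
        between-group F is significant in > 80% of 500 simulations."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(500):
            # residual noise kept small so the subject-level s.d. stays ~1
            df = _mixed_frame(rng, delta=2.0, n1=6, n2=5,
                              subj_sd=1.0, resid_sd=0.1)
            tab = bh.rm_anova(df, dv="y", subject="subject", within="win",
                              between="group")
            hits += tab.effect("group")["p"] < 0.05
        assert hits / 500 > 0.8

    def test_f_invariant_under_shift_and_scale(self):
        df = _mixed_frame(np.random.default_rng(3), delta=1.0,
                          within_effect=0.7)
        f0 = bh.rm_anova(df, dv="y", subject="subject", within="win",
                         between="group").table["F"].to_numpy()
        for tf in (lambda v: v + 100.0, lambda v: v * 3.0):
            df2 = df.assign(y=tf(df["y"]))
            f1 = bh.rm_anova(df2, dv="y", subject="subject", within="win",
                             between="group").table["F"].to_numpy()
            np.testing.assert_allclose(f1, f0, rtol=1e-9)

    def test_unbalanced_within_design_rejected(self):
        df = _mixed_frame(np.random.default_rng(4)).iloc[:-1]
        with pytest.raises(DataError):
            bh.rm_anova(df, dv="y", subject="subject", within="win",
                        between="group")

    def test_simple_effect_of_between_factor_at_one_level(self):
        df = _mixed_frame(np.random.default_rng(5), delta=3.0, resid_sd=0.3,
                          subj_sd=0.3)
        eff = bh.simple_effect(df, dv="y", subject="subject", factor="group",
                               at=("win", "w1"))
        assert eff["p"] < 0.01

    def test_one_tailed_t_requires_direction(self):
        with pytest.raises(ConfigError):
            bh.one_tailed_t([1.0, 2.0], direction=None)
        t, p = bh.one_tailed_t([1.0, 2.0, 3.0, 2.5], direction="greater")
        tref = stats.ttest_1samp([1.0, 2.0, 3.0, 2.5], 0.0,
                                 alternative="greater")
        assert (t, p) == (pytest.approx(tref.statistic),
                          pytest.approx(tref.pvalue))


class TestPower:
    def test_vanishing_effect_recovers_alpha(self):
        spec = bh.PowerSpec(partial_eta_sq=0.0, alpha=0.05, n_groups=2,
                            n_total=11)
        assert bh.power_rm_anova(spec) == pytest.approx(0.05)

    def test_study_sized_design_reaches_point_ninety_nine(self):
        spec = bh.PowerSpec(partial_eta_sq=0.8, alpha=0.05, n_groups=2,
                            n_total=11)
        assert bh.power_rm_anova(spec) >= 0.99
        assert spec.effect_size_f == pytest.approx(2.0)

    def test_monotone_in_sample_size_and_effect(self):
        grid_n = [6, 8, 11, 16, 24]
        grid_eta = [0.05, 0.1, 0.2, 0.4, 0.6, 0.8]
        for eta in grid_eta:
            powers = [bh.power_rm_anova(bh.PowerSpec(partial_eta_sq=eta,
                                                     n_total=n))
                      for n in grid_n]
            assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))
        for n in grid_n:
            powers = [bh.power_rm_anova(bh.PowerSpec(partial_eta_sq=eta,
                                                     n_total=n))
                      for eta in grid_eta]
            assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_invalid_eta_rejected(self):
        with pytest.raises(ConfigError):
            bh.power_rm_anova(bh.PowerSpec(partial_eta_sq=1.2))
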