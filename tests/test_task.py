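"""Tests for schedules, input realization, agent simulation and cohorts."""

import numpy as np
import pandas as pd
import pytest

from hgflearn.task import (CohortSpec, GroupSpec, ScheduleConfig,
                           default_schedule, generate_cohort, make_schedule,
                           realize_inputs, simulate_agent)


class TestMakeSchedule:
    def test_default_anchors(self):
        s = default_schedule()
        assert s.n_trials == 170
        acc = s.advice_accuracy_prob
        # stable phase through trial 67 at 0.85
        assert np.all(acc[:67] == 0.85)
        assert np.all(s.phase_labels[:67] == "stable")
        assert np.all(s.phase_labels[67:] == "volatile")
        # rapid reversals over trials 68-119
        assert set(acc[67:119]) == {0.9, 0.1}
        # noisy stretch spans trials 120-136 (1-based)
        assert np.all(acc[119:136] == 0.55)
        assert set(acc[136:]) == {0.9, 0.1}

    def test_phase_partition_contiguous(self):
        s = default_schedule()
        lab = s.phase_labels
        switch = np.flatnonzero(lab[:-1] != lab[1:])
        assert switch.size == 1  # exactly one stable->volatile boundary

    def test_single_phase_certain_advice(self):
        s = make_schedule(ScheduleConfig(stable_length=25,
                                         stable_accuracy=1.0,
                                         volatile_blocks=()))
        assert np.all(s.advice_accuracy_prob == 1.0)
        assert s.n_trials == 25

    def test_explicit_blocks(self):
        s = make_schedule(ScheduleConfig(
            stable_length=0, volatile_blocks=((10, 0.9), (10, 0.1))))
        expected = [0.9] * 10 + [0.1] * 10
        assert np.array_equal(s.advice_accuracy_prob, expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            make_schedule(ScheduleConfig(stable_length=0, volatile_blocks=()))
        with pytest.raises(ValueError):
            make_schedule(ScheduleConfig(stable_accuracy=1.2))
        with pytest.raises(ValueError):
            make_schedule(ScheduleConfig(volatile_blocks=((0, 0.5),)))


class TestRealizeInputs:
    def test_certain_advice_gives_all_ones(self):
        s = make_schedule(ScheduleConfig(stable_length=50,
                                         stable_accuracy=1.0,
                                         volatile_blocks=()))
        for seed in (0, 1, 99):
            rec = realize_inputs(s, seed)
            assert np.all(rec["u"] == 1)

    def test_seed_determinism(self):
        s = default_schedule()
        a = realize_inputs(s, 42)
        b = realize_inputs(s, 42)
        pd.testing.assert_frame_equal(a, b)
        assert not a["u"].equals(realize_inputs(s, 43)["u"])

    def test_binomial_rate(self):
        s = make_schedule(ScheduleConfig(stable_length=10_000,
                                         stable_accuracy=0.85,
                                         volatile_blocks=()))
        u = realize_inputs(s, 7)["u"].to_numpy()
        se = np.sqrt(0.85 * 0.15 / u.size)
        assert abs(u.mean() - 0.85) < 3 * se

    def test_cues_from_configured_levels(self):
        rec = realize_inputs(default_schedule(), 3)
        # advice-congruent cue probability: a configured level or its
        # complement, depending on whether the advice agrees with the cue
        levels = {0.55, 0.65, 0.75, 0.85}
        assert set(np.round(rec["c"], 10)).issubset(
            levels | {round(1 - c, 10) for c in levels})
        assert rec["y"].isna().all()


class TestSimulateAgent:
    def test_cue_only_agent_thresholds_cue(self, table1_params):
        """zeta=0 with near-infinite beta: the agent follows the cue."""
        rec = realize_inputs(default_schedule(), 5)
        r = dict(zeta=0.0, nu=1e9)
        out, traj = simulate_agent(rec, table1_params, r, seed=0)
        assert np.array_equal(out["y"].to_numpy(),
                              (rec["c"] > 0.5).astype(int).to_numpy())
        assert len(traj) == 170

    def test_first_trial_chance_with_flat_prior(self, table1_params):
        """zeta=1, mu2_0=0: b on trial 1 is exactly 0.5."""
        rec = realize_inputs(default_schedule(), 5)
        n1 = []
        for seed in range(200):
            out, _ = simulate_agent(rec, table1_params,
                                    dict(zeta=1.0, nu=48.0), seed=seed)
            n1.append(out["y"].iloc[0])
        assert abs(np.mean(n1) - 0.5) < 3 * np.sqrt(0.25 / 200)

    def test_cue_only_agent_ignores_advice_stream(self, table1_params, rng):
        """A zeta=0 agent's advice-taking is invariant to permuting u.

        kappa2=0 pins the volatility belief, so the advice stream cannot
        leak into the decision temperature either."""
        rec = realize_inputs(default_schedule(), 5)
        r = dict(zeta=0.0, nu=48.0)
        table1_params = dict(table1_params, kappa2=0.0)
        out1, _ = simulate_agent(rec, table1_params, r, seed=3)
        shuffled = rec.copy()
        shuffled["u"] = rng.permutation(rec["u"].to_numpy())
        out2, _ = simulate_agent(shuffled, table1_params, r, seed=3)
        assert np.array_equal(out1["y"].to_numpy(), out2["y"].to_numpy())

    def test_high_m3_updates_beliefs_more_in_volatile_phase(self,
                                                            table1_params):
        """Raising the drift equilibrium m3 amplifies trial-to-trial change
        in the predicted advice accuracy during the volatile phase."""
        rec = realize_inputs(default_schedule(), 11)
        deltas = {}
        for m3 in (-4.0, 4.0):
            p = dict(table1_params, kappa2=0.2, m3=m3, phi3=0.1)
            _, traj = simulate_agent(rec, p, dict(zeta=0.5, nu=48.0),
                                     variant="mean_reverting", seed=0)
            vol = slice(67, 170)
            deltas[m3] = np.abs(np.diff(traj.muhat1[vol])).mean()
        assert deltas[4.0] > deltas[-4.0]


class TestGenerateCohort:
    def test_empty_group_is_fine(self):
        cohort = generate_cohort(CohortSpec(
            groups=(GroupSpec(name="none", n_subjects=0),), seed=1))
        assert len(cohort.truths) == 0
        assert cohort.trials.empty

    def test_zero_spread_shares_parameters(self):
        sds = {n: 0.0 for n in
               ("kappa2", "omega2", "mu2_0", "mu3_0", "zeta", "nu")}
        cohort = generate_cohort(CohortSpec(
            groups=(GroupSpec(name="clones", n_subjects=4, model="HI",
                              param_sds=sds),), seed=1))
        assert cohort.truths["omega2"].nunique() == 1
        assert cohort.truths["nu"].nunique() == 1

    def test_group_labels_and_models_recorded(self, small_cohort):
        assert set(small_cohort.truths["model"]) == {"HII"}
        assert len(small_cohort.truths) == 10
        # 10 subjects x 170 trials
        assert len(small_cohort.trials) == 1700
        assert set(small_cohort.trials.columns) == {
            "subject_id", "group", "trial", "phase", "u", "c", "y"}

    def test_two_group_bookkeeping(self):
        cohort = generate_cohort(CohortSpec(groups=(
            GroupSpec(name="hc_like", n_subjects=2, model="HI"),
            GroupSpec(name="fep_like", n_subjects=2, model="HII",
                      param_means={"m3": 2.5, "kappa2": 0.3}),
        ), seed=5))
        by_group = cohort.truths.groupby("group")["model"].first()
        assert by_group["hc_like"] == "HI"
        assert by_group["fep_like"] == "HII"

    def test_seed_determinism(self):
        spec = CohortSpec(groups=(GroupSpec(name="g", n_subjects=3),), seed=9)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.truths, b.truths)

    def test_draws_respect_native_bounds(self, small_cohort):
        t = small_cohort.truths
        assert ((t["kappa2"] > 0) & (t["kappa2"] < 1)).all()
        assert ((t["zeta"] > 0) & (t["zeta"] < 1)).all()
        assert (t["nu"] > 0).all()
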