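"""Synthetic social-learning task: schedules, inputs, agents, cohorts.

The task asks an agent to predict a binary lottery outcome on every trial
using two sources: a non-social cue ``c`` (the probability the cue assigns
to the advice-congruent outcome) and a binary recommendation from an adviser
whose intentions change over time. The schedule has a *stable* phase of
mostly helpful advice followed by a *volatile* phase with block reversals of
advice accuracy and a noisy stretch near chance.

The default schedule has 170 trials: stable trials 1-67 at accuracy 0.85,
reversal blocks alternating 0.9/0.1 over trials 68-119, a noisy stretch at
0.55 for trials 120-136, and alternating blocks again for trials 137-170.
Everything is configurable. Latent generative states are not simulated
explicitly; the per-trial advice accuracy probability plays their role.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perceptual import BeliefTrajectory, InvalidTrajectoryError, \
    filter_trajectory
from .priors import default_priors, get_model
from .response import sample_responses

__all__ = [
    "ScheduleConfig",
    "TrialSchedule",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "make_schedule",
    "default_schedule",
    "realize_inputs",
    "simulate_agent",
    "generate_cohort",
]

DEFAULT_CUE_LEVELS = (0.55, 0.65, 0.75, 0.85)

DEFAULT_VOLATILE_BLOCKS = (
    (13, 0.9), (13, 0.1), (13, 0.9), (13, 0.1),  # rapid reversals, 68-119
    (17, 0.55),                                  # noisy stretch, 120-136
    (11, 0.9), (11, 0.1), (12, 0.9),             # reversals resume, 137-170
)


@dataclass(frozen=True)
class ScheduleConfig:
    """Generative layout of the task.

    ``volatile_blocks`` is a sequence of (length, advice_accuracy) pairs
    appended after the stable phase.
    """

    stable_length: int = 67
    stable_accuracy: float = 0.85
    volatile_blocks: tuple = DEFAULT_VOLATILE_BLOCKS
    cue_levels: tuple = DEFAULT_CUE_LEVELS


@dataclass(frozen=True)
class TrialSchedule:
    """Per-trial generative probabilities and phase labels."""

    advice_accuracy_prob: np.ndarray
    phase_labels: np.ndarray  # "stable" | "volatile"
    cue_levels: tuple = DEFAULT_CUE_LEVELS

    @property
    def n_trials(self) -> int:
        return self.advice_accuracy_prob.size


def make_schedule(config: ScheduleConfig | dict | None = None) -> TrialSchedule:
    """Build a deterministic :class:`TrialSchedule` from a config."""
    if config is None:
        config = ScheduleConfig()
    elif isinstance(config, dict):
        config = ScheduleConfig(**config)
    if config.stable_length < 0:
        raise ValueError("stable_length must be non-negative")
    acc = [config.stable_accuracy] * config.stable_length
    phase = ["stable"] * config.stable_length
    for length, a in config.volatile_blocks:
        if length <= 0:
            raise ValueError("block lengths must be positive")
        acc += [a] * int(length)
        phase += ["volatile"] * int(length)
    acc = np.asarray(acc, dtype=float)
    if acc.size == 0:
        raise ValueError("schedule has no trials")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("advice accuracies must lie in [0, 1]")
    for c in config.cue_levels:
        if not 0.0 < c < 1.0:
            raise ValueError("cue levels must lie in (0, 1)")
    return TrialSchedule(advice_accuracy_prob=acc,
                         phase_labels=np.asarray(phase, dtype=object),
                         cue_levels=tuple(config.cue_levels))


def default_schedule() -> TrialSchedule:
    return make_schedule(None)


def realize_inputs(schedule: TrialSchedule, seed: int) -> pd.DataFrame:
    """Draw one concrete input stream from the schedule.

    Returns a trial table with columns ``trial`` (1-based), ``phase``,
    ``u`` (advice correctness ~ Bernoulli(advice_accuracy_prob)), ``c``
    (cue probability drawn uniformly from the schedule's cue levels) and an
    empty ``y``. Identical seeds give identical realizations.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    u = (rng.random(n) < schedule.advice_accuracy_prob).astype(int)
    # the pie-chart cue concerns the lottery outcome, not the advice; the
    # advice agrees with the cue-favoured option only about half the time,
    # so the advice-congruent cue probability is c or 1-c symmetrically
    level = rng.choice(np.asarray(schedule.cue_levels, dtype=float), size=n)
    c = np.where(rng.random(n) < 0.5, level, 1.0 - level)
    return pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "phase": schedule.phase_labels,
        "u": u,
        "c": c,
        "y": np.full(n, np.nan),
    })


def simulate_agent(records: pd.DataFrame, pparams: dict, rparams: dict,
                   variant: str = "standard", seed: int = 0):
    """Simulate one agent's responses on a realized input stream.

    Runs the perceptual filter over ``records.u``, converts predictions to
    per-trial choice probabilities and samples responses.

    Returns
    -------
    (records, trajectory)
        A copy of ``records`` with ``y`` filled, and the
        :class:`~hgflearn.perceptual.BeliefTrajectory`.
    """
    u = records["u"].to_numpy(dtype=float)
    c = records["c"].to_numpy(dtype=float)
    traj = filter_trajectory(u, pparams, variant)
    y = sample_responses(traj, c, rparams["zeta"], rparams["nu"], seed)
    out = records.copy()
    out["y"] = y
    return out, traj


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic group: generating model and parameter distribution.

    ``param_means`` overrides native-space means (defaults: prior means).
    ``param_sds`` gives estimation-space standard deviations per free
    parameter (default: 0.5 x the prior sd), so draws always respect native
    bounds through the logit/log transforms.
    """

    name: str
    n_subjects: int
    model: str = "HI"
    param_means: dict = field(default_factory=dict)
    param_sds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    seed: int = 0
    schedule: ScheduleConfig | None = None
    share_inputs: bool = False  # one input realization for all subjects?


@dataclass
class Cohort:
    """Labeled synthetic cohort: trial tables plus ground truth."""

    trials: pd.DataFrame  # subject_id, group, trial, phase, u, c, y
    truths: pd.DataFrame  # subject_id, group, model, one column per param
    schedule: TrialSchedule

    def subject_table(self, subject_id: str) -> pd.DataFrame:
        return self.trials[self.trials.subject_id == subject_id].reset_index(
            drop=True)


def _draw_params(model_def, group: GroupSpec, rng) -> dict:
    """Draw one subject's native parameters in estimation space."""
    pri = model_def.priors
    params = model_def.default_params()
    for name in model_def.free_names:
        p = pri[name]
        mean = float(group.param_means.get(name, p.mean))
        sd = float(group.param_sds.get(name, 0.5 * np.sqrt(p.variance)))
        z = p.to_est(mean) + sd * rng.standard_normal()
        params[name] = p.to_native(z)
    for name, v in group.param_means.items():  # fixed-param overrides
        if name not in model_def.free_names:
            params[name] = float(v)
    return params


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate labeled per-subject datasets from group specifications.

    Every subject gets its own input realization (unless
    ``spec.share_inputs``), its own generative parameter draw, and its
    responses simulated under the group's generating model. Ground-truth
    parameters and model labels are recorded for recovery analyses.
    Deterministic given ``spec.seed``.
    """
    schedule = make_schedule(spec.schedule)
    priors = default_priors()
    trial_frames, truth_rows = [], []
    ss = np.random.SeedSequence(spec.seed)
    for g in spec.groups:
        if g.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        model_def = get_model(g.model, priors)
        for i in range(g.n_subjects):
            gkey = zlib.crc32(g.name.encode())  # stable across processes
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(gkey, i))
            rng = np.random.default_rng(child)
            sid = f"{g.name}_{i + 1:03d}"
            input_seed = (spec.seed if spec.share_inputs
                          else int(rng.integers(2**31)))
            rec = realize_inputs(schedule, input_seed)
            # rejection-sample parameter draws whose trajectory the filter
            # rejects (non-positive precisions), mirroring the fitting
            # contract: such vectors are outside the model's support
            for _ in range(100):
                params = _draw_params(model_def, g, rng)
                if g.model in ("CI", "CII"):
                    # control models: perceptual side frozen at
                    # input-optimized values, only the response parameters
                    # vary across subjects
                    from .fitting import fit_bayes_optimal

                    params.update(fit_bayes_optimal(
                        rec["u"].to_numpy(dtype=float), model_def.variant,
                        priors))
                try:
                    rec, _ = simulate_agent(
                        rec, params, params, variant=model_def.variant,
                        seed=int(rng.integers(2**31)))
                    break
                except InvalidTrajectoryError:
                    continue
            else:
                raise RuntimeError(
                    f"could not draw valid parameters for group {g.name}")
            rec.insert(0, "group", g.name)
            rec.insert(0, "subject_id", sid)
            trial_frames.append(rec)
            truth_rows.append({"subject_id": sid, "group": g.name,
                               "model": g.model, **params})
    cols = ["subject_id", "group", "trial", "phase", "u", "c", "y"]
    trials = (pd.concat(trial_frames, ignore_index=True)[cols]
              if trial_frames else pd.DataFrame(columns=cols))
    truths = pd.DataFrame(truth_rows)
    return Cohort(trials=trials, truths=truths, schedule=schedule)
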