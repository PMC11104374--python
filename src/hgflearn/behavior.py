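"""Behavioral summaries and posterior predictive checks.

The behavioral quantity of interest is the advice-taking frequency: the
fraction of trials in which a subject went with the advice, computed per
task phase (stable vs volatile). Healthy-control-like agents typically take
advice more during the stable phase than the volatile one; agents that
perceive the environment as increasingly volatile (elevated m3) show a
reduced stable-minus-volatile contrast.

Posterior predictive checks re-simulate responses from each subject's fitted
model and repeat the same summary, to verify the fitted model reproduces the
phase effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .perceptual import filter_trajectory
from .response import sample_responses

__all__ = [
    "advice_taking_frequency",
    "phase_contrast",
    "group_summary",
    "posterior_predictive",
]


def advice_taking_frequency(trials: pd.DataFrame) -> pd.DataFrame:
    """Advice-taking frequency per subject and phase.

    ``trials`` needs columns subject_id, phase, y (binary; group optional).
    Returns one row per subject x phase with ``n_trials`` and ``frequency``.
    """
    if trials["y"].isna().any():
        raise ValueError("y must be defined on all trials")
    y = trials["y"].to_numpy(dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary")
    keys = ["subject_id"]
    if "group" in trials.columns:
        keys.append("group")
    out = (trials.groupby(keys + ["phase"], observed=True)["y"]
           .agg(n_trials="size", frequency="mean").reset_index())
    if (out["n_trials"] == 0).any():
        raise ValueError("empty phase")
    return out


def phase_contrast(summary: pd.DataFrame) -> pd.DataFrame:
    """Stable-minus-volatile contrast per subject from a phase summary."""
    keys = [k for k in ("subject_id", "group") if k in summary.columns]
    wide = summary.pivot_table(index=keys, columns="phase",
                               values="frequency", observed=True).reset_index()
    wide["contrast"] = wide["stable"] - wide["volatile"]
    return wide


def group_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and dispersion of advice-taking per group x phase."""
    return (summary.groupby(["group", "phase"], observed=True)["frequency"]
            .agg(["mean", "std", "count"]).reset_index())


def posterior_predictive(fits: dict, trials: pd.DataFrame, n_reps: int,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate the behavioral summary from fitted models.

    Parameters
    ----------
    fits : dict
        subject_id -> object with ``params`` (native dict) and a model
        ``variant`` attribute, or a (params, variant) tuple.
        :class:`~hgflearn.fitting.FitResult` works via its ``model`` name.
    trials : DataFrame
        Observed trial tables (provides each subject's u, c, phase, group).
    n_reps : int
        Number of simulated response sets per subject.

    Returns a tidy ensemble: rep, subject_id, [group,] phase, frequency.
    """
    from .priors import get_model  # local: avoids import cycle at module load

    out = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        frames = []
        for sid, fit in fits.items():
            if isinstance(fit, tuple):
                params, variant = fit
            else:
                params = fit.params
                variant = get_model(fit.model).variant
            tab = trials[trials.subject_id == sid]
            u = tab["u"].to_numpy(dtype=float)
            c = tab["c"].to_numpy(dtype=float)
            traj = filter_trajectory(u, params, variant)
            y = sample_responses(traj, c, params["zeta"], params["nu"],
                                 int(rng.integers(2**31)))
            sim = tab.copy()
            sim["y"] = y
            frames.append(sim)
        summ = advice_taking_frequency(pd.concat(frames, ignore_index=True))
        summ.insert(0, "rep", rep)
        out.append(summ)
    if not out:
        cols = ["rep", "subject_id", "phase", "n_trials", "frequency"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)
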