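"""End-to-end pipeline: simulate -> fit -> compare -> recover -> ppc.

A run is fully reproducible from its config plus seed; artifacts (JSON for
structured results, CSV for tables) land in one directory per run together
with a manifest recording the config hash, package versions, seeds and stage
runtimes.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import advice_taking_frequency, group_summary, \
    posterior_predictive
from .estimators import HGFMAPEstimator
from .io import config_hash, read_trials, save_json, write_trials
from .priors import MODEL_NAMES, get_model
from .recovery import model_recovery, parameter_recovery_study
from .selection import bms_report
from .task import CohortSpec, GroupSpec, generate_cohort

__all__ = ["run_pipeline"]

_STAGES = ("simulate", "fit", "compare", "recover", "ppc")


def _validate(config: dict) -> dict:
    config = dict(config)
    config.setdefault("seed", 0)
    config.setdefault("stages", list(_STAGES))
    for st in config["stages"]:
        if st not in _STAGES:
            raise ValueError(f"unknown stage {st!r}")
    for m in config.get("models", ["HI", "HII"]):
        get_model(m)  # raises on unknown names before any compute
    for g in config.get("cohort", {}).get("groups", []):
        if g.get("model", "HI") not in MODEL_NAMES:
            raise ValueError(f"unknown model {g.get('model')!r} in cohort")
    return config


def _simulate(config, outdir):
    cc = config.get("cohort", {})
    groups = tuple(GroupSpec(**g) for g in cc.get("groups", []))
    spec = CohortSpec(groups=groups, seed=config["seed"],
                      schedule=cc.get("schedule"))
    cohort = generate_cohort(spec)
    write_trials(cohort.trials, outdir / "trials.csv")
    cohort.truths.to_csv(outdir / "ground_truth.csv", index=False)
    return cohort


def _fit(config, outdir):
    models = config.get("models", ["HI", "HII"])
    opts = config.get("fit", {})
    subjects = read_trials(outdir / "trials.csv")
    lme = pd.DataFrame(index=list(subjects), columns=models, dtype=float)
    fits = {}
    for sid, tab in subjects.items():
        fits[sid] = {}
        for m in models:
            est = HGFMAPEstimator(
                model=m, restarts=opts.get("restarts", 5),
                seed=config["seed"], tol=opts.get("tol", 1e-6),
            ).fit(tab, tab["y"].to_numpy(dtype=float))
            lme.loc[sid, m] = est.lme_
            fits[sid][m] = est.result_.to_dict()
    lme.rename_axis("subject_id").to_csv(outdir / "lme.csv")
    save_json(fits, outdir / "fits.json")
    return lme, fits


def _compare(config, outdir):
    opts = config.get("bms", {})
    lme = pd.read_csv(outdir / "lme.csv", index_col="subject_id")
    subjects = read_trials(outdir / "trials.csv")
    group_of = {sid: tab["group"].iloc[0] for sid, tab in subjects.items()}
    reports = {"all": _one_bms(lme, opts, config["seed"])}
    groups = sorted(set(group_of.values()))
    if len(groups) > 1:
        for g in groups:
            sub = lme.loc[[s for s in lme.index if group_of[s] == g]]
            reports[g] = _one_bms(sub, opts, config["seed"])
    save_json(reports, outdir / "bms.json")
    return reports


def _one_bms(lme, opts, seed):
    res = bms_report(lme.to_numpy(dtype=float),
                     n_samples=opts.get("n_samples", 100_000),
                     seed=seed, model_names=list(lme.columns))
    return res.to_dict()


def _recover(config, outdir):
    opts = dict(config.get("recovery", {}))
    opts.setdefault("seed", config["seed"])
    conf = model_recovery(
        models=opts.get("models", ["HI", "HII"]),
        n_subjects=opts.get("n_subjects", 10),
        n_seeds=opts.get("n_seeds", 2),
        seed=opts["seed"], restarts=opts.get("restarts", 5))
    conf.rename_axis("generating").to_csv(outdir / "model_confusion.csv")
    rep = parameter_recovery_study(
        model=opts.get("parameter_model", "HII"),
        n_subjects=opts.get("n_subjects", 10),
        n_seeds=opts.get("n_seeds", 2),
        seed=opts["seed"], restarts=opts.get("restarts", 5))
    save_json(rep.to_dict(), outdir / "parameter_recovery.json")
    return conf, rep


def _ppc(config, outdir):
    import json

    opts = config.get("ppc", {})
    fits = json.loads((outdir / "fits.json").read_text())
    subjects = read_trials(outdir / "trials.csv")
    trials = pd.concat(subjects.values(), ignore_index=True)
    model = opts.get("model", config.get("models", ["HI", "HII"])[-1])
    fitmap = {sid: (fits[sid][model]["params"],
                    get_model(model).variant) for sid in subjects}
    ens = posterior_predictive(fitmap, trials, opts.get("n_reps", 20),
                               seed=config["seed"])
    ens.to_csv(outdir / "ppc.csv", index=False)
    observed = advice_taking_frequency(trials)
    observed.to_csv(outdir / "behavior_observed.csv", index=False)
    if "group" in observed.columns:
        group_summary(observed).to_csv(outdir / "behavior_groups.csv",
                                       index=False)
    return ens


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages in order; returns a manifest dict.

    Stage failures abort the run; the manifest written so far is saved as
    ``manifest.json`` with a ``failed_stage`` entry.
    """
    config = _validate(config)
    outdir = Path(outdir or config.get("output_dir", "hgflearn_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "versions": {"hgflearn": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    runners = {"simulate": _simulate, "fit": _fit, "compare": _compare,
               "recover": _recover, "ppc": _ppc}
    try:
        for st in config["stages"]:
            t0 = time.perf_counter()
            runners[st](config, outdir)
            manifest["stages"][st] = {
                "runtime_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        manifest["failed_stage"] = {"stage": st, "error": str(exc)}
        save_json(manifest, outdir / "manifest.json")
        raise
    save_json(manifest, outdir / "manifest.json")
    return manifest
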