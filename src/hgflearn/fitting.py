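"""MAP estimation of subject-level parameters and Laplace log model evidence.

Free parameters are optimized in estimation space (logit/log/identity per the
prior table) under independent Gaussian priors. The objective is the log
joint

    log p(y | params) + sum_i log N(z_i; z_prior_i, var_i),

with the response likelihood from :mod:`hgflearn.response` evaluated on the
trajectory produced by :mod:`hgflearn.perceptual`. Parameter vectors whose
trajectory is invalid (non-positive precisions) score -inf; the optimizer
never sees them clamped.

Evidence for model comparison is the Laplace approximation

    LME = log_joint(MAP) + (d/2) log(2*pi) - (1/2) log det H,

where H is the central-difference Hessian of the negative log joint at the
MAP. A non-positive-definite H is projected to the nearest positive-definite
matrix (eigenvalue flooring) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .perceptual import InvalidTrajectoryError, filter_trajectory
from .priors import ModelDef, default_priors, get_model, to_native_space
from .response import response_loglik

__all__ = [
    "FitResult",
    "log_joint",
    "fit_map",
    "laplace_lme",
    "fit_bayes_optimal",
]

_PENALTY = 1e12  # finite stand-in for -inf handed to the optimizer


@dataclass
class FitResult:
    """Outcome of a subject-level MAP fit.

    Attributes
    ----------
    model : str
        Model identifier (HI, HII, CI, CII).
    params : dict
        MAP estimates in native space (fixed parameters included).
    x_est : ndarray
        MAP estimates of the free parameters in estimation space.
    log_joint : float
        Log joint at the MAP.
    lme : float
        Laplace log model evidence (NaN until :func:`laplace_lme` is run).
    """

    model: str
    params: dict
    x_est: np.ndarray
    log_joint: float
    lme: float = np.nan
    free_names: tuple = ()
    restarts_used: int = 0
    grad_norm: float = np.nan
    hessian_projected: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "x_est": [float(v) for v in self.x_est],
            "free_names": list(self.free_names),
            "log_joint": float(self.log_joint),
            "lme": float(self.lme),
            "restarts_used": int(self.restarts_used),
            "grad_norm": float(self.grad_norm),
            "hessian_projected": bool(self.hessian_projected),
        }


def _log_prior(x, model: ModelDef) -> float:
    x = np.asarray(x, dtype=float)
    mu = np.array([model.priors[n].est_mean for n in model.free_names])
    var = np.array([model.priors[n].variance for n in model.free_names])
    if x.size == 0:
        return 0.0
    return float(
        -0.5 * np.sum((x - mu) ** 2 / var)
        - 0.5 * np.sum(np.log(2.0 * np.pi * var))
    )


def log_joint(x_est, data, model: ModelDef) -> float:
    """Log joint of estimation-space vector ``x_est`` for one subject.

    ``data`` is anything with ``u``, ``c``, ``y`` array attributes or keys
    (a DataFrame with those columns works). Returns -inf for parameter
    vectors that produce an invalid trajectory.
    """
    u, c, y = (np.asarray(_get(data, k), dtype=float) for k in "ucy")
    params = to_native_space(x_est, model)
    if params["nu"] <= 0:  # exp() underflow at extreme estimation values
        return -np.inf
    try:
        traj = filter_trajectory(u, params, model.variant)
        ll = response_loglik(traj, c, y, params["zeta"], params["nu"])
    except InvalidTrajectoryError:
        return -np.inf
    except ValueError:
        # degenerate beliefs (b saturated to exactly 0/1 in float) are
        # outside the response model's support: reject like the filter does
        return -np.inf
    return ll + _log_prior(x_est, model)


def _get(data, key):
    if hasattr(data, "columns"):
        return data[key].to_numpy()
    try:
        return data[key]
    except (KeyError, TypeError, IndexError):
        return getattr(data, key)


class _Recorder:
    """Track the best point an optimizer visits.

    The rejection contract puts a large-penalty cliff in the objective;
    a quasi-Newton line search can end on the wrong side of it, so the
    best visited iterate — not the final one — is the estimate.
    """

    def __init__(self, fun):
        self.fun = fun
        self.best_f = np.inf
        self.best_x = None

    def __call__(self, x):
        f = self.fun(x)
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        return f


def _minimize(fun, x0, tol):
    rec = _Recorder(fun)
    res = optimize.minimize(rec, x0, method="L-BFGS-B",
                            options={"gtol": tol, "maxiter": 500})
    if rec.best_f < res.fun:
        res.x, res.fun = rec.best_x, rec.best_f
    return res


def fit_map(data, model, *, restarts: int = 5, seed: int = 0,
            tol: float = 1e-6) -> FitResult:
    """MAP fit by quasi-Newton multistart.

    Starts from the prior mean plus ``restarts - 1`` seeded standard-normal
    perturbations in estimation space; returns the best optimum.
    Deterministic given ``seed``.
    """
    if isinstance(model, str):
        model = get_model(model)

    def neg(x):
        lj = log_joint(x, data, model)
        return _PENALTY if not np.isfinite(lj) else -lj

    x0 = np.array([model.priors[n_].est_mean for n_ in model.free_names])
    if x0.size == 0:  # nothing to optimize: evidence is the log joint itself
        lj = log_joint(x0, data, model)
        fr = FitResult(model=model.name, params=to_native_space(x0, model),
                       x_est=x0, log_joint=lj, lme=lj,
                       free_names=(), restarts_used=0, grad_norm=0.0)
        return fr
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.standard_normal(x0.size)
                     for _ in range(max(0, restarts - 1))]
    best, best_val, used = None, np.inf, 0
    for i, s in enumerate(starts):
        res = _minimize(neg, s, tol)
        if np.isfinite(res.fun) and res.fun < best_val and res.fun < _PENALTY:
            best, best_val, used = res, res.fun, i + 1
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} restarts failed for model {model.name}")
    gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    fr = FitResult(
        model=model.name,
        params=to_native_space(best.x, model),
        x_est=np.asarray(best.x, dtype=float),
        log_joint=-best_val,
        free_names=tuple(model.free_names),
        restarts_used=used,
        grad_norm=gnorm,
    )
    fr.lme = laplace_lme(fr, data, model)
    return fr


def _hessian_cd(fun, x, h=1e-4):
    """Central-difference Hessian of scalar ``fun`` at ``x``."""
    d = x.size
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def laplace_lme(fitresult: FitResult, data, model) -> float:
    """Laplace log model evidence at the MAP.

    With zero free parameters the evidence is the log joint itself (which is
    then the log-likelihood at the fixed parameter values plus an empty
    prior term).
    """
    if isinstance(model, str):
        model = get_model(model)
    x = np.asarray(fitresult.x_est, dtype=float)
    d = x.size
    if d == 0:
        return float(fitresult.log_joint)

    def neg(z):
        lj = log_joint(z, data, model)
        return _PENALTY if not np.isfinite(lj) else -lj

    H = _hessian_cd(neg, x)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        # nearest-PD projection: floor eigenvalues of the symmetrized Hessian
        w, V = np.linalg.eigh(0.5 * (H + H.T))
        w = np.maximum(w, 1e-8)
        logdet = float(np.sum(np.log(w)))
        fitresult.hessian_projected = True
    return float(fitresult.log_joint + 0.5 * d * np.log(2.0 * np.pi)
                 - 0.5 * logdet)


# ---------------------------------------------------------------------------
# Input-only ("Bayes optimal") perceptual fit for the control models
# ---------------------------------------------------------------------------

_BO_FREE = {
    "standard": ("kappa2", "omega2", "mu2_0", "mu3_0"),
    "mean_reverting": ("kappa2", "omega2", "mu2_0", "mu3_0", "m3"),
}


def fit_bayes_optimal(u, variant: str = "standard", priors=None, *,
                      restarts: int = 5, seed: int = 0,
                      tol: float = 1e-6) -> dict:
    """Optimize perceptual parameters on the input stream alone.

    Maximizes sum_k [u_k log muhat1_k + (1-u_k) log(1-muhat1_k)] plus the
    estimation-space log-prior — the accuracy of one-step-ahead input
    predictions, no responses involved. The result freezes the perceptual
    parameters of the control models CI (standard) and CII (mean-reverting).

    Returns the full native-space perceptual parameter dict.
    """
    pri = priors or default_priors()
    free = _BO_FREE[variant]
    model = ModelDef(f"BO-{variant}", variant, free, pri)
    u = np.asarray(u, dtype=float)

    def objective(x):
        params = to_native_space(x, model)
        try:
            traj = filter_trajectory(u, params, variant)
        except InvalidTrajectoryError:
            return -np.inf
        p = np.clip(traj.muhat1, 1e-12, 1.0 - 1e-12)
        ll = float(np.sum(u * np.log(p) + (1.0 - u) * np.log1p(-p)))
        return ll + _log_prior(x, model)

    def neg(x):
        v = objective(x)
        return _PENALTY if not np.isfinite(v) else -v

    x0 = np.array([pri[n].est_mean for n in free])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.standard_normal(x0.size)
                     for _ in range(max(0, restarts - 1))]
    best = None
    for s in starts:
        res = _minimize(neg, s, tol)
        if np.isfinite(res.fun) and res.fun < _PENALTY and \
                (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("input-only optimization failed on all restarts")
    out = to_native_space(best.x, model)
    return {k: out[k] for k in model.relevant_names()
            if k not in ("zeta", "nu")}
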