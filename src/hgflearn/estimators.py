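"""Scikit-learn style estimators wrapping the fitting and selection layers.

:class:`HGFMAPEstimator` is a per-subject probabilistic classifier of
advice-taking: ``fit(X, y)`` MAP-estimates the free parameters of one
candidate model from a subject's trial table, after which ``predict_proba``
returns per-trial probabilities of going with the advice and ``lme_`` holds
the Laplace log model evidence consumed by group-level selection.

:class:`RandomEffectsBMS` is the group-level step: ``fit(L)`` on a
subjects-by-models log-evidence matrix infers Dirichlet model frequencies,
exceedance probabilities, the Bayesian omnibus risk and protected exceedance
probabilities.

Both compose with sklearn tooling (``get_params``/``set_params``/``clone``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import fitting, selection
from .perceptual import filter_trajectory
from .priors import default_priors, get_model
from .response import (choice_probability, integrate_belief, response_loglik,
                       sample_responses)

__all__ = ["HGFMAPEstimator", "BayesOptimalHGF", "RandomEffectsBMS"]


def _split_X(X):
    """Accept a DataFrame with u/c columns or an (n, 2) array [u, c]."""
    if isinstance(X, pd.DataFrame):
        return X["u"].to_numpy(dtype=float), X["c"].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be a trial table with columns u, c")
    return X[:, 0], X[:, 1]


class HGFMAPEstimator(BaseEstimator):
    """MAP-fitted HGF observer for one subject.

    Parameters
    ----------
    model : {"HI", "HII", "CI", "CII"}
        Candidate model. HI = standard 3-level HGF; HII = mean-reverting
        variant with free drift equilibrium m3; CI/CII fix all perceptual
        parameters at input-optimized values and only estimate the response
        parameters.
    restarts : int
        Multistart count for the quasi-Newton optimizer.
    seed : int
        Seed for the restart perturbations (fit is deterministic given it).
    tol : float
        Gradient-norm tolerance.
    priors : PriorSpec, optional
        Override the default prior table.

    Attributes
    ----------
    params_ : dict
        Native-space MAP estimates (fixed parameters included).
    x_est_ : ndarray
        Free-parameter MAP in estimation space.
    lme_ : float
        Laplace log model evidence.
    result_ : FitResult
        Full fit record.
    """

    def __init__(self, model: str = "HI", restarts: int = 5, seed: int = 0,
                 tol: float = 1e-6, priors=None):
        self.model = model
        self.restarts = restarts
        self.seed = seed
        self.tol = tol
        self.priors = priors

    def _model_def(self, u):
        priors = self.priors or default_priors()
        mdef = get_model(self.model, priors)
        if self.model in ("CI", "CII"):
            bo = fitting.fit_bayes_optimal(
                u, mdef.variant, priors, restarts=self.restarts,
                seed=self.seed, tol=self.tol)
            mdef = mdef.with_fixed_perceptual(bo)
        return mdef

    def fit(self, X, y):
        """MAP-fit the model to one subject's trials.

        ``X`` carries the inputs (advice correctness ``u`` and cue ``c``),
        ``y`` the binary responses (1 = went with the advice).
        """
        u, c = _split_X(X)
        y = np.asarray(y, dtype=float)
        mdef = self._model_def(u)
        data = {"u": u, "c": c, "y": y}
        res = fitting.fit_map(data, mdef, restarts=self.restarts,
                              seed=self.seed, tol=self.tol)
        self.model_def_ = mdef
        self.result_ = res
        self.params_ = res.params
        self.x_est_ = res.x_est
        self.lme_ = res.lme
        self.classes_ = np.array([0, 1])
        return self

    def _proba(self, X):
        u, c = _split_X(X)
        p = self.params_
        traj = filter_trajectory(u, p, self.model_def_.variant)
        b = integrate_belief(traj.muhat1, c, p["zeta"])
        return traj, choice_probability(b, traj.muhat3, p["nu"])

    def predict_proba(self, X):
        """Per-trial [P(y=0), P(y=1)] under the fitted parameters."""
        check_is_fitted(self, "params_")
        _, p = self._proba(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def sample(self, X, seed: int = 0):
        """Draw a simulated response sequence from the fitted model."""
        check_is_fitted(self, "params_")
        u, c = _split_X(X)
        p = self.params_
        traj = filter_trajectory(u, p, self.model_def_.variant)
        return sample_responses(traj, c, p["zeta"], p["nu"], seed)

    def score(self, X, y):
        """Response log-likelihood of ``y`` under the fitted parameters."""
        check_is_fitted(self, "params_")
        u, c = _split_X(X)
        p = self.params_
        traj = filter_trajectory(u, p, self.model_def_.variant)
        return response_loglik(traj, c, np.asarray(y, float),
                               p["zeta"], p["nu"])


class BayesOptimalHGF(BaseEstimator):
    """Input-only ("Bayes optimal") perceptual fit.

    ``fit(u)`` maximizes the one-step-ahead predictive likelihood of the
    input stream plus the estimation-space prior; no responses are involved.
    Used to freeze the perceptual parameters of the control models.
    """

    def __init__(self, variant: str = "standard", restarts: int = 5,
                 seed: int = 0, tol: float = 1e-6, priors=None):
        self.variant = variant
        self.restarts = restarts
        self.seed = seed
        self.tol = tol
        self.priors = priors

    def fit(self, X, y=None):
        u = np.asarray(X, dtype=float).ravel()
        self.params_ = fitting.fit_bayes_optimal(
            u, self.variant, self.priors, restarts=self.restarts,
            seed=self.seed, tol=self.tol)
        return self

    def transform(self, X):
        """Belief trajectory table for an input stream under the fit."""
        check_is_fitted(self, "params_")
        u = np.asarray(X, dtype=float).ravel()
        return filter_trajectory(u, self.params_, self.variant).to_frame()


class RandomEffectsBMS(BaseEstimator):
    """Random-effects Bayesian model selection over a cohort.

    ``fit(L)`` consumes a subjects-by-models matrix of log model evidences.

    Attributes
    ----------
    alpha_ : ndarray
        Dirichlet posterior parameters.
    frequencies_ : ndarray
        Expected model frequencies f = alpha / sum(alpha).
    xp_, bor_, pxp_ :
        Exceedance probabilities, Bayesian omnibus risk, protected
        exceedance probabilities.
    attributions_ : ndarray
        Per-subject posterior model probabilities (rows on the simplex).
    """

    def __init__(self, alpha0: float = 1.0, tol: float = 1e-8,
                 n_samples: int = 1_000_000, seed: int = 0):
        self.alpha0 = alpha0
        self.tol = tol
        self.n_samples = n_samples
        self.seed = seed

    def fit(self, X, y=None):
        res = selection.bms_report(X, alpha0=self.alpha0, tol=self.tol,
                                   n_samples=self.n_samples, seed=self.seed)
        self.result_ = res
        self.alpha_ = res.alpha
        self.frequencies_ = res.frequencies
        self.xp_ = res.xp
        self.bor_ = res.bor
        self.pxp_ = res.pxp
        self.attributions_ = res.attributions
        return self
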