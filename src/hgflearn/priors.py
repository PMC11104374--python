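"""Parameter tables, estimation-space transforms, and model definitions.

The model space comprises four candidates:

* ``HI``  — standard 3-level binary HGF (free: kappa2, omega2, mu2_0, mu3_0,
  zeta, nu).
* ``HII`` — mean-reverting HGF with a level-3 drift toward an equilibrium
  ``m3`` (free: the above plus m3).
* ``CI``/``CII`` — control models in which all perceptual parameters are
  frozen at input-optimized ("Bayes optimal") values and only the response
  parameters (zeta, nu) are estimated.

Prior means are stated in native space; prior variances apply in estimation
space (logit for [0,1]-bounded parameters, log for positive ones, identity
otherwise), matching the convention of the reference HGF toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit as sp_expit

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "ModelDef",
    "default_priors",
    "get_model",
    "MODEL_NAMES",
    "to_estimation_space",
    "to_native_space",
]

IDENTITY, LOG, LOGIT = "identity", "log", "logit"


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _expit(z):
    return sp_expit(np.asarray(z, dtype=float))


_FWD = {IDENTITY: lambda x: np.asarray(x, float), LOG: np.log, LOGIT: _logit}
_INV = {IDENTITY: lambda x: np.asarray(x, float), LOG: np.exp, LOGIT: _expit}


@dataclass(frozen=True)
class ParamPrior:
    """Prior for a single parameter.

    Attributes
    ----------
    name : str
        Canonical parameter name (``kappa2``, ``omega2``, ``theta``,
        ``mu2_0``, ``sigma2_0``, ``mu3_0``, ``sigma3_0``, ``m3``, ``phi3``,
        ``zeta``, ``nu``).
    mean : float
        Prior mean in native space.
    variance : float
        Prior variance in estimation space; 0 marks the parameter as fixed.
    transform : str
        One of ``identity``, ``log``, ``logit``.
    bounds : tuple
        Native-space support (open at transformed-out endpoints).
    """

    name: str
    mean: float
    variance: float
    transform: str = IDENTITY
    bounds: tuple = (-np.inf, np.inf)

    @property
    def fixed(self) -> bool:
        return self.variance == 0.0

    @property
    def est_mean(self) -> float:
        return float(_FWD[self.transform](self.mean))

    def to_est(self, x: float) -> float:
        lo, hi = self.bounds
        if not (lo <= x <= hi):
            raise ValueError(f"{self.name}={x} outside bounds {self.bounds}")
        return float(_FWD[self.transform](x))

    def to_native(self, z: float) -> float:
        return float(_INV[self.transform](z))


# Canonical priors. Perceptual: coupling strength kappa2, level-2 evolution
# rate omega2, meta-volatility theta (fixed 0.5), initial means/variances of
# levels 2 and 3, drift equilibrium m3 and drift rate phi3 (fixed 0.1,
# mean-reverting variant only). Response: advice weight zeta, noise nu.
_TABLE = [
    ParamPrior("kappa2", 0.5, 1.0, LOGIT, (0.0, 1.0)),
    ParamPrior("omega2", -2.0, 4.0, IDENTITY),
    ParamPrior("theta", 0.5, 0.0, LOGIT, (0.0, 1.0)),
    ParamPrior("mu2_0", 0.0, 1.0, IDENTITY),
    ParamPrior("sigma2_0", 1.0, 0.0, LOG, (0.0, np.inf)),
    ParamPrior("mu3_0", 1.0, 1.0, IDENTITY),
    ParamPrior("sigma3_0", 1.0, 0.0, LOG, (0.0, np.inf)),
    ParamPrior("m3", 1.0, 1.0, IDENTITY),
    ParamPrior("phi3", 0.1, 0.0, LOGIT, (0.0, 1.0)),
    ParamPrior("zeta", 0.5, 1.0, LOGIT, (0.0, 1.0)),
    ParamPrior("nu", 48.0, 1.0, LOG, (0.0, np.inf)),
]

PERCEPTUAL_NAMES = (
    "kappa2", "omega2", "theta", "mu2_0", "sigma2_0", "mu3_0", "sigma3_0",
    "m3", "phi3",
)
RESPONSE_NAMES = ("zeta", "nu")


@dataclass(frozen=True)
class PriorSpec:
    """Collection of :class:`ParamPrior` objects keyed by name."""

    params: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> ParamPrior:
        return self.params[name]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def names(self):
        return list(self.params)

    def with_overrides(self, **overrides) -> "PriorSpec":
        """Return a copy with ``name=(mean, variance)`` or ``name=mean``
        overrides applied."""
        new = dict(self.params)
        for name, val in overrides.items():
            p = new[name]
            if np.isscalar(val):
                new[name] = replace(p, mean=float(val))
            else:
                m, v = val
                new[name] = replace(p, mean=float(m), variance=float(v))
        return PriorSpec(new)


def default_priors() -> PriorSpec:
    return PriorSpec({p.name: p for p in _TABLE})


@dataclass(frozen=True)
class ModelDef:
    """A candidate model: variant + which parameters are free.

    ``fixed_values`` holds native-space values for every non-free parameter
    relevant to the variant (for the control models the perceptual entries
    are replaced per subject by input-optimized values).
    """

    name: str
    variant: str  # "standard" | "mean_reverting"
    free_names: tuple
    priors: PriorSpec

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def relevant_names(self):
        base = ["kappa2", "omega2", "theta", "mu2_0", "sigma2_0",
                "mu3_0", "sigma3_0"]
        if self.variant == "mean_reverting":
            base += ["m3", "phi3"]
        return base + list(RESPONSE_NAMES)

    def default_params(self) -> dict:
        """Native-space parameter dict at the prior means."""
        return {n: self.priors[n].mean for n in self.relevant_names()}

    def with_fixed_perceptual(self, values: dict) -> "ModelDef":
        """Freeze perceptual parameters at ``values`` (native space),
        leaving only the response parameters free. Used for CI/CII."""
        pri = self.priors
        for n, v in values.items():
            p = pri[n]
            pri = pri.with_overrides(**{n: (v, 0.0)})
        return ModelDef(self.name, self.variant, tuple(RESPONSE_NAMES), pri)


MODEL_NAMES = ("HI", "HII", "CI", "CII")

_HI_FREE = ("kappa2", "omega2", "mu2_0", "mu3_0", "zeta", "nu")
_HII_FREE = ("kappa2", "omega2", "mu2_0", "mu3_0", "m3", "zeta", "nu")


def get_model(name: str, priors: PriorSpec | None = None) -> ModelDef:
    """Return the :class:`ModelDef` for one of ``HI, HII, CI, CII``.

    ``CI``/``CII`` are returned with perceptual parameters still at prior
    means; callers freeze them per subject via
    :meth:`ModelDef.with_fixed_perceptual` after input-only optimization.
    """
    pri = priors or default_priors()
    if name == "HI":
        return ModelDef("HI", "standard", _HI_FREE, pri)
    if name == "HII":
        return ModelDef("HII", "mean_reverting", _HII_FREE, pri)
    if name == "CI":
        return ModelDef("CI", "standard", tuple(RESPONSE_NAMES), pri)
    if name == "CII":
        return ModelDef("CII", "mean_reverting", tuple(RESPONSE_NAMES), pri)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def to_estimation_space(params: dict, model: ModelDef) -> np.ndarray:
    """Map native free-parameter values to the estimation-space vector."""
    return np.array([model.priors[n].to_est(params[n])
                     for n in model.free_names])


def to_native_space(vec: np.ndarray, model: ModelDef) -> dict:
    """Map an estimation-space vector back to a full native parameter dict
    (fixed parameters filled from the prior means)."""
    params = model.default_params()
    for n, z in zip(model.free_names, np.asarray(vec, float)):
        params[n] = model.priors[n].to_native(z)
    return params
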