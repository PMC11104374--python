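"""Binary 3-level Hierarchical Gaussian Filter (HGF) and its mean-reverting
variant.

The perceptual model tracks three coupled states: level 1 is the binary
accuracy of the advice on each trial, level 2 the unbounded tendency of the
adviser to be helpful (the adviser's fidelity), and level 3 the log-volatility
of the adviser's intentions. Beliefs are Gaussian at levels 2 and 3 and are
updated once per trial with precision-weighted prediction errors: the change
in the mean at level i is proportional to (pihat_{i-1} / pi_i) * delta_{i-1}.

One-step updates, with v2 = exp(kappa2 * mu3^{k-1} + omega2):

    predictions:  muhat2 = mu2^{k-1}
                  muhat3 = mu3^{k-1}                       (standard)
                  muhat3 = mu3^{k-1} + phi3*(m3 - mu3^{k-1})  (mean-reverting)
                  muhat1 = sigmoid(muhat2);  pihat1 = 1/(muhat1*(1-muhat1))
    level 2:      delta1 = u_k - muhat1
                  pihat2 = 1/(sigma2^{k-1} + v2)
                  pi2    = pihat2 + muhat1*(1-muhat1)
                  mu2    = muhat2 + delta1/pi2
    level 3:      pihat3 = 1/(sigma3^{k-1} + theta)
                  w2     = v2*pihat2
                  delta2 = (sigma2 + (mu2-muhat2)^2)*pihat2 - 1
                  pi3    = pihat3 + (kappa2^2/2)*w2*(w2 + (2*w2-1)*delta2)
                  mu3    = muhat3 + (kappa2/2)*(w2/pi3)*delta2

The mean-reverting variant relaxes level 3 toward an equilibrium m3 at rate
phi3 (a discrete-time Ornstein-Uhlenbeck drift); m3 above the initial belief
mu3_0 means the agent comes to perceive the environment as increasingly
volatile, amplifying belief updates at every level.

Parameter vectors that drive any posterior precision non-positive (or any
state non-finite) are rejected: :func:`filter_trajectory` raises
:class:`InvalidTrajectoryError` naming the failing trial. During fitting this
is treated as log-joint = -inf rather than being clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "sigmoid",
    "update_step",
    "filter_trajectory",
    "BeliefTrajectory",
    "InvalidTrajectoryError",
    "PARAM_ORDER",
    "params_to_vector",
]

# Layout of the packed parameter vector consumed by the jitted kernel.
PARAM_ORDER = ("kappa2", "omega2", "theta", "mu2_0", "sigma2_0",
               "mu3_0", "sigma3_0", "m3", "phi3")

VARIANT_CODES = {"standard": 0, "mean_reverting": 1}

# Column order of the trajectory table produced by the filter.
_COLS = ("muhat1", "pihat1", "mu2", "sigma2", "muhat2", "pihat2", "pi2",
         "mu3", "sigma3", "muhat3", "pihat3", "pi3", "delta1", "delta2",
         "v2", "w2", "lr1")


class InvalidTrajectoryError(ValueError):
    """Raised when a parameter set produces non-positive precisions.

    Attributes
    ----------
    trial : int
        1-based index of the first failing trial.
    """

    def __init__(self, trial: int):
        self.trial = trial
        super().__init__(
            f"invalid trajectory: non-positive precision or non-finite "
            f"state at trial {trial}"
        )


def sigmoid(z):
    """Numerically stable unit sigmoid s(z) = 1/(1+exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def params_to_vector(params: dict) -> np.ndarray:
    """Pack a native-space parameter dict into the kernel's vector layout.

    Parameters absent from the dict (e.g. ``m3`` for the standard variant)
    default to values that make them inert (m3=0, phi3=0).
    """
    defaults = {"m3": 0.0, "phi3": 0.0}
    return np.array([float(params.get(n, defaults.get(n, np.nan)))
                     for n in PARAM_ORDER])


@njit(cache=True)
def _filter_kernel(u, p, variant, v2_drifted):  # pragma: no cover - jitted
    ka2, om2, th = p[0], p[1], p[2]
    mu2, s2 = p[3], p[4]
    mu3, s3 = p[5], p[6]
    m3, ph3 = p[7], p[8]
    n = u.shape[0]
    out = np.empty((n, 17))
    for k in range(n):
        muhat2 = mu2
        if variant == 1:
            muhat3 = mu3 + ph3 * (m3 - mu3)
        else:
            muhat3 = mu3
        # level-1 prediction
        if muhat2 >= 0.0:
            muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        else:
            e = np.exp(muhat2)
            muhat1 = e / (1.0 + e)
        q1 = muhat1 * (1.0 - muhat1)
        if q1 <= 0.0:
            return out, k + 1
        pihat1 = 1.0 / q1
        # level 2: variance inflation at the previous posterior volatility
        # by default; optionally at the drifted prediction (AR1 variant)
        if v2_drifted == 1:
            v2 = np.exp(ka2 * muhat3 + om2)
        else:
            v2 = np.exp(ka2 * mu3 + om2)
        delta1 = u[k] - muhat1
        pihat2 = 1.0 / (s2 + v2)
        pi2 = pihat2 + q1
        if not (pi2 > 0.0 and np.isfinite(pi2)):
            return out, k + 1
        mu2_new = muhat2 + delta1 / pi2
        s2_new = 1.0 / pi2
        # level 3
        pihat3 = 1.0 / (s3 + th)
        w2 = v2 * pihat2
        delta2 = (s2_new + (mu2_new - muhat2) ** 2) * pihat2 - 1.0
        pi3 = pihat3 + 0.5 * ka2 * ka2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if not (pi3 > 0.0 and np.isfinite(pi3)):
            return out, k + 1
        mu3_new = muhat3 + 0.5 * ka2 * (w2 / pi3) * delta2
        s3_new = 1.0 / pi3
        if not (np.isfinite(mu2_new) and np.isfinite(mu3_new)):
            return out, k + 1
        out[k, 0] = muhat1
        out[k, 1] = pihat1
        out[k, 2] = mu2_new
        out[k, 3] = s2_new
        out[k, 4] = muhat2
        out[k, 5] = pihat2
        out[k, 6] = pi2
        out[k, 7] = mu3_new
        out[k, 8] = s3_new
        out[k, 9] = muhat3
        out[k, 10] = pihat3
        out[k, 11] = pi3
        out[k, 12] = delta1
        out[k, 13] = delta2
        out[k, 14] = v2
        out[k, 15] = w2
        out[k, 16] = pihat1 / pi2  # level-1 learning rate
        mu2, s2, mu3, s3 = mu2_new, s2_new, mu3_new, s3_new
    return out, 0


@dataclass
class BeliefTrajectory:
    """Per-trial belief states of an HGF run.

    ``states`` has one row per trial and the columns listed in
    :meth:`to_frame`. ``muhat1`` is the prediction of advice accuracy before
    the outcome is seen; ``muhat3`` the corresponding volatility prediction
    (these feed the response model). ``lr1`` is the level-1 learning rate
    pihat1/pi2.
    """

    states: np.ndarray
    params: dict
    variant: str

    def __len__(self):
        return self.states.shape[0]

    def __getattr__(self, name):
        if name in _COLS:
            return self.states[:, _COLS.index(name)]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame (one row per trial), exportable to CSV."""
        df = pd.DataFrame(self.states, columns=list(_COLS))
        df.insert(0, "trial", np.arange(1, len(self) + 1))
        return df


def update_step(state: tuple, u_k: int, params: dict,
                variant: str = "standard") -> dict:
    """Single HGF update from ``state = (mu2, sigma2, mu3, sigma3)``.

    Returns a dict of all post-update quantities for trial k. Mainly a
    readable single-step surface; :func:`filter_trajectory` is the workhorse.
    """
    mu2, s2, mu3, s3 = state
    p = dict(params)
    p.update(mu2_0=mu2, sigma2_0=s2, mu3_0=mu3, sigma3_0=s3)
    traj = filter_trajectory(np.array([u_k], dtype=float), p, variant)
    return {c: float(traj.states[0, i]) for i, c in enumerate(_COLS)}


def filter_trajectory(u, params: dict, variant: str = "standard",
                      v2_at_drifted: bool = False) -> BeliefTrajectory:
    """Run the HGF over a binary input sequence ``u``.

    Parameters
    ----------
    u : array-like of {0, 1}
        Advice-correctness stream.
    params : dict
        Native-space perceptual parameters (see :data:`PARAM_ORDER`).
    variant : {"standard", "mean_reverting"}
    v2_at_drifted : bool
        Evaluate the level-2 variance inflation ``v2`` at the drifted
        volatility prediction instead of the previous posterior
        (mean-reverting variant only; default follows the reference
        convention of using the previous posterior).

    Raises
    ------
    InvalidTrajectoryError
        If any posterior precision is non-positive or a state diverges;
        the exception carries the 1-based failing trial index.
    """
    if variant not in VARIANT_CODES:
        raise ValueError(f"unknown variant {variant!r}")
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("u must be a 1-D sequence")
    if u.size and not np.all((u == 0) | (u == 1)):
        raise ValueError("u must be binary")
    pvec = params_to_vector(params)
    if pvec[4] <= 0 or pvec[6] <= 0:
        raise ValueError("initial variances must be positive")
    states, fail = _filter_kernel(u, pvec, VARIANT_CODES[variant],
                                  int(v2_at_drifted))
    if fail:
        raise InvalidTrajectoryError(fail)
    return BeliefTrajectory(states=states, params=dict(params),
                            variant=variant)
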