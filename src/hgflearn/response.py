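"""Response model: from beliefs to choice probabilities.

On each trial the agent blends its predicted advice accuracy ``muhat1`` with
the non-social cue ``c`` (the probability the cue assigns to the
advice-congruent outcome) using the advice weight zeta:

    b = zeta * muhat1 + (1 - zeta) * c

and follows the advice (y = 1) with probability

    p(y=1 | b) = b**beta / (b**beta + (1-b)**beta),
    beta = nu * exp(-muhat3),

so choices become more deterministic (exploitative) when the environment is
currently perceived as stable (low predicted volatility muhat3) and more
stochastic (exploratory) when perceived as volatile. nu > 0 is a
volatility-independent noise parameter; larger nu means less noise. All
power/Bernoulli computations run in log space; probabilities are clipped at
1e-12 for likelihood evaluation only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "integrate_belief",
    "inverse_temperature",
    "choice_probability",
    "response_loglik",
    "sample_responses",
]

_CLIP = 1e-12


def integrate_belief(muhat1, c, zeta):
    """Blend advice-accuracy prediction and cue: b = zeta*muhat1 + (1-zeta)*c."""
    muhat1 = np.asarray(muhat1, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any((muhat1 <= 0) | (muhat1 >= 1)) or np.any((c <= 0) | (c >= 1)):
        raise ValueError("muhat1 and c must lie strictly in (0, 1)")
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    b = zeta * muhat1 + (1.0 - zeta) * c
    return b if b.ndim else float(b)

def inverse_temperature(muhat3, nu):
    """beta = nu * exp(-muhat3): volatility-dependent decision temperature."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    with np.errstate(over="ignore"):  # inf beta = deterministic limit
        return nu * np.exp(-np.asarray(muhat3, dtype=float))


def choice_probability(b, muhat3, nu):
    """P(take advice) under the softmax-on-odds rule, computed in log space.

    ``p = b^beta / (b^beta + (1-b)^beta)`` equals a logistic in
    ``beta * log(b/(1-b))``, which is how it is evaluated here (stable for
    large beta).
    """
    b = np.asarray(b, dtype=float)
    if np.any((b <= 0) | (b >= 1)):
        raise ValueError("integrated belief b must lie strictly in (0, 1)")
    beta = inverse_temperature(muhat3, nu)
    logodds = beta * (np.log(b) - np.log1p(-b))
    p = expit(logodds)
    return p if np.ndim(p) else float(p)


def _choice_probs(trajectory, c, zeta, nu):
    b = integrate_belief(trajectory.muhat1, c, zeta)
    return choice_probability(b, trajectory.muhat3, nu)


def response_loglik(trajectory, c, y, zeta, nu):
    """Bernoulli log-likelihood of observed choices y given the trajectory.

    Probabilities are clipped to [1e-12, 1 - 1e-12] so a single surprising
    choice cannot produce -inf during optimization.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(trajectory) == c.size == y.size):
        raise ValueError("trajectory, c and y must have equal length")
    if y.size and not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary")
    p = np.clip(_choice_probs(trajectory, c, zeta, nu), _CLIP, 1.0 - _CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def sample_responses(trajectory, c, zeta, nu, seed):
    """Draw a binary response sequence from the per-trial choice
    probabilities; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    p = _choice_probs(trajectory, np.asarray(c, dtype=float), zeta, nu)
    return (rng.random(len(trajectory)) < p).astype(int)
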