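"""Decision kernel for the LTPA intention/behavior dynamics.

Persons carry a continuous *intention* toward leisure-time physical
activity (LTPA) stored on the log-odds scale, and a discrete weekly
*behavior* (practiced / did not practice).  The kernel follows the
Continuous Opinions and Discrete Actions (CODA) framework: observing a
discrete action shifts the continuous internal opinion by a Bayesian
log-odds increment ``ln(alpha / (1 - alpha))``, where ``alpha`` is the
confidence that the observed behavior reflects the best option.

Four influences enter the weekly update:

* the proximal network's last-week behaviors (weight ``alpha_p``),
* the perceived community's last-week behaviors (weight ``alpha_c``),
* the person's own last-week behavior (weight ``alpha_b``),
* the built environment, via the log-odds of the highest perceived
  site utility, damped by a scaling factor ``r``.

The sum of increments is modulated by the intention *strength*
``w = 1 - |i| / L``: persons with extreme intentions are set in their
ways and barely move, persons near indifference are maximally plastic.
Intention is kept inside ``[-L, L]`` with ``L = ln(0.97 / 0.03)`` so
the logistic transform of intention — the probability of practicing —
stays inside ``[0.03, 0.97]``, leaving room for off-intention behavior
(illness, vacation) at both extremes.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "IntentionScale",
    "AlphaWeights",
    "DEFAULT_SCALE",
    "alpha_logodds",
    "site_utility",
    "social_increment",
    "self_increment",
    "intention_strength",
    "environment_term",
    "update_intention",
    "practice_probability",
    "prob_to_logodds",
]

#: numerical slack when checking the |i| <= L precondition
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class IntentionScale:
    """Probability bounds of behavior and the induced log-odds bound.

    ``prob_floor`` and ``prob_ceil`` bound the weekly probability of
    practicing; they must be complementary (``floor = 1 - ceil``) so the
    log-odds bound ``L = ln(ceil / floor)`` is symmetric about zero.
    """

    prob_floor: float = 0.03
    prob_ceil: float = 0.97

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_floor < self.prob_ceil < 1.0):
            raise ValueError("require 0 < prob_floor < prob_ceil < 1")
        if abs(self.prob_floor + self.prob_ceil - 1.0) > 1e-12:
            raise ValueError("prob_floor must equal 1 - prob_ceil")

    @property
    def L(self) -> float:
        """Log-odds bound: intention is confined to ``[-L, L]``."""
        return math.log(self.prob_ceil / self.prob_floor)


DEFAULT_SCALE = IntentionScale()


@dataclass(frozen=True)
class AlphaWeights:
    """Conditional likelihoods weighting the three behavioral influences.

    Each ``alpha`` is the probability that the observed behavior (of the
    proximal network, the perceived community, or the person himself)
    is the best option.  ``alpha = 0.5`` means the observation carries
    no information and the corresponding increment vanishes.
    """

    alpha_p: float
    alpha_c: float
    alpha_b: float

    def __post_init__(self) -> None:
        for name in ("alpha_p", "alpha_c", "alpha_b"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {a!r}")

    @property
    def logodds(self) -> tuple[float, float, float]:
        return (
            alpha_logodds(self.alpha_p),
            alpha_logodds(self.alpha_c),
            alpha_logodds(self.alpha_b),
        )


def _check_alpha(alpha: float) -> None:
    if not np.isfinite(alpha) or not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie strictly inside (0, 1), got {alpha!r}")


def alpha_logodds(alpha: float) -> float:
    """Log-odds ``ln(alpha / (1 - alpha))`` of a confidence weight."""
    _check_alpha(alpha)
    return math.log(alpha / (1.0 - alpha))


def site_utility(v, q, z, m, scale: IntentionScale = DEFAULT_SCALE):
    """Perceived utility of an LTPA site.

    ``u = v * (q/3 + 1/(3 z) + m/3)`` combines, with equal thirds,
    site quality ``q`` in [0, 1], access ``z`` (Euclidean distance in
    patch units, floored at 1 so the access share never exceeds 1/3),
    and ``m`` in {0, 1}, whether the person's favorite activity is
    offered.  ``v > 0`` is the person-site subjective assessment
    scaling factor.  The raw utility is clamped to
    ``[prob_floor, prob_ceil]`` so its log-odds stays finite.
    """
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    z = np.asarray(z, dtype=float)
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v <= 0.0):
        raise ValueError("subjective assessment v must be finite and positive")
    if np.any(z < 1.0):
        raise ValueError("access distance z must be >= 1 patch unit")
    if np.any((q < 0.0) | (q > 1.0)):
        raise ValueError("site quality q must lie in [0, 1]")
    if np.any((m != 0.0) & (m != 1.0)):
        raise ValueError("favorite-activity indicator m must be 0 or 1")
    raw = v * (q / 3.0 + 1.0 / (3.0 * z) + m / 3.0)
    return np.clip(raw, scale.prob_floor, scale.prob_ceil)


def social_increment(behaviors, alpha: float) -> float:
    """Intention increment from observed behaviors of a social group.

    ``(1/n) * sum_x b_x * ln(alpha / (1 - alpha))`` over the group's
    last-week behavior codes (+1 practiced / -1 did not).  An empty
    group contributes nothing.
    """
    _check_alpha(alpha)
    b = np.asarray(behaviors, dtype=float)
    if b.size == 0:
        return 0.0
    if not np.all(np.isfinite(b)):
        raise ValueError("behavior codes must be finite")
    return float(np.mean(b) * math.log(alpha / (1.0 - alpha)))


def self_increment(behavior: float, alpha_b: float) -> float:
    """Intention increment from the person's own last-week behavior."""
    _check_alpha(alpha_b)
    if not np.isfinite(behavior):
        raise ValueError("behavior code must be finite")
    return float(behavior * math.log(alpha_b / (1.0 - alpha_b)))


def intention_strength(i_prev, scale: IntentionScale = DEFAULT_SCALE):
    """Plasticity weight ``w = 1 - |i| / L`` in [0, 1].

    Neutral intention (``i = 0``) is maximally plastic (``w = 1``);
    intention at either bound is frozen (``w = 0``).  Values outside
    ``[-L, L]`` are rejected: clamping is the caller's job.
    """
    i_prev = np.asarray(i_prev, dtype=float)
    L = scale.L
    if np.any(np.abs(i_prev) > L + _EDGE_TOL):
        raise ValueError(f"intention outside [-L, L] with L={L:.6f}")
    return np.clip(1.0 - np.abs(i_prev) / L, 0.0, 1.0)


def environment_term(u_max, r: float, scale: IntentionScale = DEFAULT_SCALE):
    """Built-environment influence ``ln(u/(1-u)) / r``.

    ``u_max`` is the highest perceived site utility; ``r > 0`` rescales
    the magnitude of the built environment's weekly pull (100 by
    default in the shipped scenarios).  Callers supply the no-site
    convention (term 0) for persons who perceive no site.
    """
    u_max = np.asarray(u_max, dtype=float)
    if not np.isfinite(r) or r <= 0.0:
        raise ValueError("scaling factor r must be positive")
    if np.any((u_max <= 0.0) | (u_max >= 1.0)):
        raise ValueError("u_max must lie strictly inside (0, 1)")
    return logit(u_max) / r


def update_intention(i_prev, p, c, l, y, scale: IntentionScale = DEFAULT_SCALE):
    """One weekly intention update, clamped to ``[-L, L]``.

    ``i_t = clamp(i_{t-1} + w * (p + c + l + y))`` where ``w`` is the
    intention strength computed from ``i_{t-1}`` and ``p, c, l, y`` are
    the proximal-network, community, own-behavior, and environment
    terms.
    """
    i_prev = np.asarray(i_prev, dtype=float)
    terms = []
    for name, t in (("p", p), ("c", c), ("l", l), ("y", y)):
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError(f"influence term {name} must be finite")
        terms.append(t)
    w = intention_strength(i_prev, scale)
    total = terms[0] + terms[1] + terms[2] + terms[3]
    return np.clip(i_prev + w * total, -scale.L, scale.L)


def practice_probability(i, scale: IntentionScale = DEFAULT_SCALE):
    """Probability of practicing this week: logistic transform of intention.

    With intention clamped to ``[-L, L]`` the result lies in
    ``[prob_floor, prob_ceil]``.
    """
    i = np.asarray(i, dtype=float)
    if np.any(np.abs(i) > scale.L + _EDGE_TOL):
        raise ValueError("intention outside [-L, L]")
    return expit(i)


def prob_to_logodds(p):
    """Inverse of :func:`practice_probability`: ``ln(p / (1 - p))``.

    Used to initialize intention drawn on the probability scale.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probability must lie strictly inside (0, 1)")
    return logit(p)
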