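"""Learning and choice rules of individual agents.

The asocial core is Rescorla-Wagner value updating with softmax choice.
Social influence enters either as a mixture on choice probabilities
(decision biasing),

    P_i = (1 - sigma) * softmax_i(beta * Q) + sigma * S_i,
    S_i = (N_i + 0.1)^theta / sum_j (N_j + 0.1)^theta,

where N_i are the option choice counts observed from the previous trial,
or as a conformity-weighted additive term in the value update itself
(value shaping), with choice by plain softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARIANTS",
    "AgentParams",
    "rescorla_wagner_update",
    "softmax_probs",
    "conformity_weights",
    "net_choice_probs",
    "value_shaping_update",
    "hot_stove_index",
    "asocial_boundary_beta",
    "COUNT_SMOOTHING",
]

VARIANTS = ("asocial", "decision_biasing", "value_shaping")

# small constant added to choice counts so an option chosen by nobody still
# carries (maximal, for theta < 0) social weight
COUNT_SMOOTHING = 0.1


@dataclass(frozen=True)
class AgentParams:
    """Learning-model parameters of one agent.

    alpha: learning rate in [0, 1]; beta: softmax inverse temperature >= 0;
    sigma: copying weight in [0, 1]; theta: conformity exponent (any real).
    The asocial variant forces sigma = 0.
    """

    alpha: float
    beta: float
    sigma: float = 0.0
    theta: float = 0.0
    variant: str = "decision_biasing"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "asocial" and self.sigma != 0.0:
            object.__setattr__(self, "sigma", 0.0)

    @property
    def hot_stove_index(self) -> float:
        return hot_stove_index(self.alpha, self.beta)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma": self.sigma,
            "theta": self.theta,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**d)


def rescorla_wagner_update(q, payoff, alpha):
    """One Rescorla-Wagner step: (1 - alpha) * q + alpha * payoff.

    Values of unchosen options are the caller's responsibility (left
    untouched). Broadcasts over array inputs.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must be in [0, 1]")
    return (1.0 - alpha) * np.asarray(q, dtype=float) + alpha * np.asarray(payoff, dtype=float)


def softmax_probs(q, beta):
    """Softmax choice probabilities over the last axis of `q`.

    Computed with max subtraction so large beta*q cannot overflow.
    beta broadcasts against q[..., None] semantics: scalar or shape
    matching q's leading axes.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] == 0:
        raise ValueError("need at least one option value")
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be >= 0")
    if beta.ndim > 0 and beta.ndim == q.ndim - 1:
        beta = beta[..., None]
    x = beta * q
    x = x - x.max(axis=-1, keepdims=True)
    ex = np.exp(x)
    return ex / ex.sum(axis=-1, keepdims=True)


def conformity_weights(counts, theta):
    """Conformist social weights over the last axis of `counts`.

    weight_i = (count_i + 0.1)^theta / sum_j (count_j + 0.1)^theta,
    evaluated in log space for robustness at large |theta|. theta = 0
    gives uniform weights; theta < 0 favours the rarest option.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    theta = np.asarray(theta, dtype=float)
    if theta.ndim > 0 and theta.ndim == counts.ndim - 1:
        theta = theta[..., None]
    x = theta * np.log(counts + COUNT_SMOOTHING)
    x = x - x.max(axis=-1, keepdims=True)
    ex = np.exp(x)
    return ex / ex.sum(axis=-1, keepdims=True)


def net_choice_probs(q, counts, params: AgentParams, first_trial: bool = False):
    """Net choice probabilities mixing softmax and conformist weights.

    On the first trial (or when no lagged social counts are available,
    i.e. the counts sum to zero) the choice is purely asocial softmax.
    """
    a = softmax_probs(q, params.beta)
    if first_trial or params.sigma == 0.0 or params.variant != "decision_biasing":
        return a
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        return a
    s = conformity_weights(counts, params.theta)
    return (1.0 - params.sigma) * a + params.sigma * s


def value_shaping_update(q, payoff, chosen: int, counts, params: AgentParams):
    """Value-shaping update: RW step on the chosen option, then every
    option's value moved by sigma * (conformity_weight - 1/K).

    The social increment is zero-mean across options and vanishes for
    uniform counts or sigma = 0. Returns a new value array.
    """
    q = np.array(q, dtype=float)
    k = q.shape[-1]
    q[chosen] = rescorla_wagner_update(q[chosen], payoff, params.alpha)
    counts = np.asarray(counts, dtype=float)
    if params.sigma > 0.0 and counts.sum() > 0:
        w = conformity_weights(counts, params.theta)
        q = q + params.sigma * (w - 1.0 / k)
    return q


def hot_stove_index(alpha, beta):
    """Susceptibility to the hot stove effect, alpha * (beta + 1)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return alpha * (beta + 1.0)


def asocial_boundary_beta(alpha):
    """Inverse temperature at which an asocial learner with learning rate
    `alpha` is indifferent between safe and risky in the long run:
    beta = (2 - alpha) / alpha, i.e. alpha * (beta + 1) = 2."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValueError("alpha must be in (0, 1]")
    return (2.0 - alpha) / alpha
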