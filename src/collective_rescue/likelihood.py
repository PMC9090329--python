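"""Choice log-likelihoods by replaying observed sessions.

Beliefs are reconstructed by replaying each subject's own choices and
realised payoffs through the Rescorla-Wagner rule; the probability of the
observed choice at each trial comes from the decision rule of the model
variant (asocial softmax, decision biasing with the displayed lagged
counts, or value shaping). Trial 1 — and any trial with no displayed
social information — uses the asocial softmax term only.

The hot inner loop is compiled with numba; a pure-numpy replica is kept
for cross-checking.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .agents import COUNT_SMOOTHING, VARIANTS, AgentParams
from .tasks import TaskConfig

__all__ = ["replay_loglik", "subject_loglik"]

_VARIANT_CODES = {"asocial": 0, "decision_biasing": 1, "value_shaping": 2}


@njit(cache=False)
def _replay_kernel(choices, payoffs, counts, alpha, beta, sigma, theta, variant):
    n, T = choices.shape
    K = counts.shape[2]
    out = np.zeros((n, T))
    w = np.empty(K)
    for i in range(n):
        Q = np.zeros(K)
        a, b, s, th = alpha[i], beta[i], sigma[i], theta[i]
        for t in range(T):
            c = choices[i, t]
            # softmax with max subtraction
            m = b * Q[0]
            for k in range(1, K):
                x = b * Q[k]
                if x > m:
                    m = x
            Z = 0.0
            for k in range(K):
                Z += math.exp(b * Q[k] - m)
            # conformity weights of the lagged displayed counts
            tot = 0.0
            for k in range(K):
                tot += counts[i, t, k]
            social = variant != 0 and s > 0.0 and tot > 0.0
            if social:
                mw = th * math.log(counts[i, t, 0] + COUNT_SMOOTHING)
                for k in range(1, K):
                    xw = th * math.log(counts[i, t, k] + COUNT_SMOOTHING)
                    if xw > mw:
                        mw = xw
                Zw = 0.0
                for k in range(K):
                    w[k] = math.exp(th * math.log(counts[i, t, k] + COUNT_SMOOTHING) - mw)
                    Zw += w[k]
                for k in range(K):
                    w[k] /= Zw
            if c >= 0:
                p = math.exp(b * Q[c] - m) / Z
                if social and variant == 1:
                    p = (1.0 - s) * p + s * w[c]
                out[i, t] = math.log(p) if p > 0.0 else -np.inf
                Q[c] = (1.0 - a) * Q[c] + a * payoffs[i, t]
                if social and variant == 2:
                    for k in range(K):
                        Q[k] += s * (w[k] - 1.0 / K)
    return out


def _replay_numpy(choices, payoffs, counts, alpha, beta, sigma, theta, variant):
    """Reference numpy implementation of the replay (used in tests to
    cross-check the compiled kernel)."""
    n, T = choices.shape
    K = counts.shape[2]
    Q = np.zeros((n, K))
    rows = np.arange(n)
    out = np.zeros((n, T))
    for t in range(T):
        c = choices[:, t]
        obs = c >= 0
        cc = np.clip(c, 0, K - 1)
        x = beta[:, None] * Q
        x = x - x.max(axis=-1, keepdims=True)
        ex = np.exp(x)
        probs = ex / ex.sum(axis=-1, keepdims=True)
        ct = counts[:, t, :]
        has = ct.sum(axis=-1) > 0
        sw = None
        if variant != "asocial" and np.any(has) and np.any(sigma > 0):
            xw = theta[:, None] * np.log(ct + COUNT_SMOOTHING)
            xw -= xw.max(axis=-1, keepdims=True)
            exw = np.exp(xw)
            sw = exw / exw.sum(axis=-1, keepdims=True)
        if variant == "decision_biasing" and sw is not None:
            mix = np.where(has, sigma, 0.0)[:, None]
            probs = (1.0 - mix) * probs + mix * sw
        p_obs = probs[rows, cc]
        with np.errstate(divide="ignore"):
            out[:, t] = np.where(obs, np.log(p_obs), 0.0)
        qc = Q[rows, cc]
        Q[rows, cc] = np.where(obs, (1.0 - alpha) * qc + alpha * payoffs[:, t], qc)
        if variant == "value_shaping" and sw is not None:
            inc = np.where(obs & has, sigma, 0.0)[:, None]
            Q = Q + inc * (sw - 1.0 / K)
    return out


def replay_loglik(
    choices: np.ndarray,
    payoffs: np.ndarray,
    counts: np.ndarray,
    alpha,
    beta,
    sigma=0.0,
    theta=0.0,
    *,
    variant: str = "decision_biasing",
    pointwise: bool = False,
    backend: str = "numba",
) -> np.ndarray:
    """Log-likelihood of observed choices for a batch of subjects.

    choices: (n, T) option indices, -1 where the trial is missing;
    payoffs: (n, T) realised payoffs on the learning scale (already
    multiplied by the task's payoff_scale); counts: (n, T, K) lagged
    displayed counts. Parameters are scalars or length-n vectors.

    Returns total log-likelihood per subject (n,), or the per-trial
    matrix (n, T) when `pointwise` (missing trials contribute 0).
    Probabilities are never clipped: an impossible choice yields -inf,
    and a non-finite probability (a parameter bug) raises.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    n, T = choices.shape
    counts = np.ascontiguousarray(counts, dtype=float)
    payoffs = np.ascontiguousarray(payoffs, dtype=float)
    alpha = np.ascontiguousarray(np.broadcast_to(np.asarray(alpha, dtype=float), (n,)))
    beta = np.ascontiguousarray(np.broadcast_to(np.asarray(beta, dtype=float), (n,)))
    sigma = np.ascontiguousarray(np.broadcast_to(np.asarray(sigma, dtype=float), (n,)))
    theta = np.ascontiguousarray(np.broadcast_to(np.asarray(theta, dtype=float), (n,)))
    if np.any(~np.isfinite(alpha)) or np.any(~np.isfinite(beta)):
        raise FloatingPointError("non-finite parameters in replay")
    if backend == "numba":
        out = _replay_kernel(
            choices, payoffs, counts, alpha, beta, sigma, theta, _VARIANT_CODES[variant]
        )
    else:
        out = _replay_numpy(choices, payoffs, counts, alpha, beta, sigma, theta, variant)
    if np.any(np.isnan(out)):
        raise FloatingPointError("non-finite choice probability in replay")
    return out if pointwise else out.sum(axis=1)


def subject_loglik(
    data,
    params: AgentParams,
    task: TaskConfig,
    variant: str | None = None,
) -> float:
    """Total log-likelihood of one subject's rows under `params`.

    `data` is a long-format frame for a single subject with columns
    trial, choice, payoff (raw points) and count_option_1..K; rows must
    be ordered by trial. Payoffs are scaled by task.payoff_scale before
    replay.
    """
    variant = variant or params.variant
    df = data.sort_values("trial")
    K = task.n_options
    count_cols = [f"count_option_{k + 1}" for k in range(K)]
    T = int(df["trial"].max())
    choices = np.full((1, T), -1, dtype=int)
    payoffs = np.zeros((1, T))
    counts = np.zeros((1, T, K))
    t = df["trial"].to_numpy(dtype=int) - 1
    choices[0, t] = df["choice"].to_numpy(dtype=int)
    payoffs[0, t] = df["payoff"].to_numpy(dtype=float) * task.payoff_scale
    counts[0, t, :] = df[count_cols].to_numpy(dtype=float)
    ll = replay_loglik(
        choices, payoffs, counts,
        params.alpha, params.beta, params.sigma, params.theta,
        variant=variant,
    )
    return float(ll[0])
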