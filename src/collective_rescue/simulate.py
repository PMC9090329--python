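"""Synchronous group sessions of learning agents.

The engine advances all replicate groups and all agents in lockstep:
at trial t each agent mixes its softmax preference with the conformist
weight of the choice counts it observed at t-1 (decision biasing), or
applies the social term inside the value update (value shaping), draws a
payoff from its chosen option only, and updates its value estimate.

Everything is vectorised over (replicate, agent), so parameter sweeps at
thousands of replicates per cell run in seconds. A session is fully
reproducible from (task, composition, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import COUNT_SMOOTHING, VARIANTS, AgentParams
from .tasks import TaskConfig

__all__ = [
    "SimResult",
    "simulate_groups",
    "run_session",
    "session_table",
    "prop_risky_second_half",
    "prop_risky_last_trials",
    "sweep_parameter_grid",
    "run_heterogeneous",
    "compare_horizons",
    "indifference_crossing",
    "example_compositions",
]


@dataclass
class SimResult:
    """Raw arrays of a batch of simulated sessions.

    choices: (R, N, T) int16, option index or -1 where the agent had
    dropped out; payoffs: (R, N, T) float raw payoff points (0 where
    inactive); counts_seen: (R, N, T, K) int16 lagged counts displayed to
    each agent, or None when not recorded.
    """

    task: TaskConfig
    choices: np.ndarray
    payoffs: np.ndarray
    counts_seen: np.ndarray | None
    include_self: bool


def _broadcast_param(value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    return np.broadcast_to(arr, shape).copy() if arr.shape != shape else arr.astype(float)


def _conformity_weights_batch(counts: np.ndarray, theta: np.ndarray) -> np.ndarray:
    # counts (R, N, K), theta (R, N); log-space softmax over K
    x = theta[..., None] * np.log(counts + COUNT_SMOOTHING)
    x -= x.max(axis=-1, keepdims=True)
    ex = np.exp(x)
    return ex / ex.sum(axis=-1, keepdims=True)


def simulate_groups(
    task: TaskConfig,
    alpha,
    beta,
    sigma=0.0,
    theta=0.0,
    *,
    variant: str = "decision_biasing",
    n_replicates: int = 1,
    group_size: int = 1,
    horizon: int | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
    include_self: bool = False,
    completed: np.ndarray | None = None,
    record_counts: bool = True,
) -> SimResult:
    """Simulate `n_replicates` independent groups of `group_size` agents.

    Parameters alpha/beta/sigma/theta may be scalars, length-`group_size`
    vectors, or (n_replicates, group_size) arrays. `completed` optionally
    gives the number of trials each agent completes (dropout); agents
    contribute to displayed counts only for trials they completed.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    T = int(horizon if horizon is not None else task.horizon)
    if T < 1:
        raise ValueError(f"horizon must be >= 1, got {T}")
    R, N, K = int(n_replicates), int(group_size), task.n_options
    if R < 1 or N < 1:
        raise ValueError("n_replicates and group_size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    shape = (R, N)
    alpha = _broadcast_param(alpha, shape)
    beta = _broadcast_param(beta, shape)
    sigma = _broadcast_param(sigma, shape)
    theta = _broadcast_param(theta, shape)
    if variant == "asocial":
        sigma = np.zeros(shape)
    if completed is None:
        completed = np.full(shape, T, dtype=int)
    else:
        completed = np.broadcast_to(np.asarray(completed, dtype=int), shape)

    scale = task.payoff_scale
    Q = np.zeros((R, N, K))
    choices = np.full((R, N, T), -1, dtype=np.int16)
    payoffs = np.zeros((R, N, T), dtype=float)
    counts_seen = np.zeros((R, N, T, K), dtype=np.int16) if record_counts else None
    onehot_eye = np.eye(K, dtype=np.int32)
    social_variant = variant == "decision_biasing"

    for t in range(T):
        active = t < completed  # (R, N)
        # lagged counts: choices at t-1 of members who completed t-1
        if t == 0:
            counts = np.zeros((R, N, K))
        else:
            prev = choices[:, :, t - 1]
            prev_oh = np.where(prev[..., None] >= 0, onehot_eye[np.clip(prev, 0, K - 1)], 0)
            group_counts = prev_oh.sum(axis=1)  # (R, K)
            counts = np.broadcast_to(group_counts[:, None, :], (R, N, K)).astype(np.int32)
            if include_self:
                counts = counts.copy()
            else:
                counts = counts - prev_oh
        if record_counts:
            counts_seen[:, :, t, :] = counts

        # choice probabilities
        x = beta[..., None] * Q
        x = x - x.max(axis=-1, keepdims=True)
        ex = np.exp(x)
        probs = ex / ex.sum(axis=-1, keepdims=True)
        has_social = counts.sum(axis=-1) > 0  # (R, N)
        if social_variant and np.any(sigma > 0) and np.any(has_social):
            sweights = _conformity_weights_batch(np.asarray(counts, dtype=float), theta)
            mix = np.where(has_social, sigma, 0.0)[..., None]
            probs = (1.0 - mix) * probs + mix * sweights

        # sample choices
        u = rng.random((R, N))
        cum = np.cumsum(probs, axis=-1)
        choice = (u[..., None] > cum).sum(axis=-1).astype(np.int16)
        np.clip(choice, 0, K - 1, out=choice)
        choice[~active] = -1
        choices[:, :, t] = choice

        # payoffs for chosen options only (drawn per option, assigned to choosers)
        pay = np.zeros((R, N))
        for k, opt in enumerate(task.options):
            draw = opt.spec.draw(rng, (R, N))
            pay = np.where(choice == k, draw, pay)
        pay = np.where(active, pay, 0.0)
        payoffs[:, :, t] = pay

        # learning update
        idx = np.clip(choice, 0, K - 1)[..., None].astype(np.intp)
        qc = np.take_along_axis(Q, idx, axis=-1)[..., 0]
        new_qc = (1.0 - alpha) * qc + alpha * (pay * scale)
        new_qc = np.where(active, new_qc, qc)
        np.put_along_axis(Q, idx, new_qc[..., None], axis=-1)
        if variant == "value_shaping" and np.any(sigma > 0) and np.any(has_social):
            sweights = _conformity_weights_batch(np.asarray(counts, dtype=float), theta)
            inc = np.where(active & has_social, sigma, 0.0)[..., None]
            Q = Q + inc * (sweights - 1.0 / K)

    return SimResult(
        task=task, choices=choices, payoffs=payoffs,
        counts_seen=counts_seen, include_self=include_self,
    )


def _composition_arrays(comp: Sequence[AgentParams]):
    variants = {p.variant for p in comp}
    if len(variants) > 1:
        raise ValueError("all members of a composition must share the model variant")
    return (
        np.array([p.alpha for p in comp]),
        np.array([p.beta for p in comp]),
        np.array([p.sigma for p in comp]),
        np.array([p.theta for p in comp]),
        variants.pop(),
    )


def run_session(
    task: TaskConfig,
    comp: Sequence[AgentParams],
    seed=None,
    *,
    include_self: bool = False,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Run one synchronous group session; returns the long-format table."""
    alpha, beta, sigma, theta, variant = _composition_arrays(comp)
    res = simulate_groups(
        task, alpha, beta, sigma, theta, variant=variant,
        n_replicates=1, group_size=len(comp), seed=seed,
        include_self=include_self, horizon=horizon,
    )
    return session_table(res)


def session_table(res: SimResult, replicate_offset: int = 0) -> pd.DataFrame:
    """Long-format record of a SimResult: one row per agent x trial.

    Columns: replicate, group_id, individual, trial (1-based), choice
    (0-based option index), option label, payoff (raw points), and
    count_option_1..K, the lagged counts displayed to the agent at that
    trial (zero on trial 1).
    """
    if res.counts_seen is None:
        raise ValueError("session_table requires counts_seen (record_counts=True)")
    R, N, T = res.choices.shape
    K = res.task.n_options
    rep, ind, tri = np.meshgrid(
        np.arange(R), np.arange(N), np.arange(1, T + 1), indexing="ij"
    )
    flat_choice = res.choices.reshape(-1)
    mask = flat_choice >= 0
    labels = np.array([o.label for o in res.task.options] + ["<none>"])
    df = pd.DataFrame(
        {
            "replicate": rep.reshape(-1)[mask] + replicate_offset,
            "group_id": rep.reshape(-1)[mask] + replicate_offset,
            "individual": ind.reshape(-1)[mask],
            "trial": tri.reshape(-1)[mask],
            "choice": flat_choice[mask].astype(int),
            "option": labels[flat_choice[mask]],
            "payoff": res.payoffs.reshape(-1)[mask],
        }
    )
    counts = res.counts_seen.reshape(-1, K)[mask]
    for k in range(K):
        df[f"count_option_{k + 1}"] = counts[:, k].astype(int)
    return df


def _second_half_slice(T: int) -> slice:
    # trials t > floor(T/2), 1-based: indices floor(T/2)..T-1
    return slice(T // 2, T)


def prop_risky_second_half(session, task: TaskConfig, horizon: int | None = None) -> float:
    """Mean proportion of choices of the focal (highest-EV) risky option
    over individuals and trials t > floor(T/2)."""
    target = task.target_risky_index
    if isinstance(session, SimResult):
        T = session.choices.shape[-1]
        sl = _second_half_slice(T)
        c = session.choices[..., sl]
        valid = c >= 0
        if not valid.any():
            raise ValueError("empty session: no completed second-half trials")
        return float((c[valid] == target).mean())
    df = session
    if len(df) == 0:
        raise ValueError("empty session table")
    T = int(horizon if horizon is not None else df["trial"].max())
    sub = df[df["trial"] > T // 2]
    if len(sub) == 0:
        raise ValueError("no second-half trials in session table")
    return float((sub["choice"] == target).mean())


def prop_risky_last_trials(res: SimResult, window: int) -> float:
    """Mean risky-choice proportion over the final `window` trials."""
    target = res.task.target_risky_index
    c = res.choices[..., -window:]
    valid = c >= 0
    return float((c[valid] == target).mean())


def sweep_parameter_grid(
    task: TaskConfig,
    alphas: Iterable[float],
    betas: Iterable[float],
    sigmas: Iterable[float] = (0.0,),
    thetas: Iterable[float] = (0.0,),
    *,
    group_size: int = 10,
    horizon: int | None = None,
    n_replicates: int = 1000,
    variant: str = "decision_biasing",
    seed=None,
) -> pd.DataFrame:
    """Mean second-half risky proportion over a parameter grid.

    One homogeneous cell per (alpha, beta, sigma, theta) combination,
    `n_replicates` independent groups per cell.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sg in np.atleast_1d(list(sigmas)):
        for th in np.atleast_1d(list(thetas)):
            for a in np.atleast_1d(list(alphas)):
                for b in np.atleast_1d(list(betas)):
                    res = simulate_groups(
                        task, a, b, sg, th, variant=variant,
                        n_replicates=n_replicates, group_size=group_size,
                        horizon=horizon, rng=rng, record_counts=False,
                    )
                    rows.append(
                        {
                            "alpha": a, "beta": b, "sigma": sg, "theta": th,
                            "group_size": group_size,
                            "prop_risky_second_half": prop_risky_second_half(res, task),
                        }
                    )
    return pd.DataFrame(rows)


def run_heterogeneous(
    task: TaskConfig,
    compositions: Mapping[str, Sequence[AgentParams]],
    *,
    n_replicates: int = 20000,
    horizon: int | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate each named group composition `n_replicates` times.

    Returns (per-member table, per-group table) of mean second-half risky
    proportions. All compositions must share the same group size.
    """
    sizes = {len(c) for c in compositions.values()}
    if len(sizes) > 1:
        raise ValueError(f"compositions must share one group size, got sizes {sorted(sizes)}")
    rng = np.random.default_rng(seed)
    member_rows, group_rows = [], []
    for name, comp in compositions.items():
        alpha, beta, sigma, theta, variant = _composition_arrays(comp)
        res = simulate_groups(
            task, alpha, beta, sigma, theta, variant=variant,
            n_replicates=n_replicates, group_size=len(comp),
            horizon=horizon, rng=rng, record_counts=False,
        )
        T = res.choices.shape[-1]
        sl = _second_half_slice(T)
        target = task.target_risky_index
        c = res.choices[..., sl]
        valid = c >= 0
        per_member = np.where(
            valid.any(axis=(0, 2)),
            (np.where(valid, c == target, False)).sum(axis=(0, 2))
            / np.maximum(valid.sum(axis=(0, 2)), 1),
            np.nan,
        )
        for m, p in enumerate(comp):
            member_rows.append(
                {
                    "composition": name, "member": m,
                    "alpha": p.alpha, "beta": p.beta, "sigma": p.sigma, "theta": p.theta,
                    "mean_prop_risky": float(per_member[m]),
                }
            )
        group_rows.append(
            {
                "composition": name,
                "mean_prop_risky": float(np.nanmean(per_member)),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(member_rows), pd.DataFrame(group_rows)


def indifference_crossing(
    task: TaskConfig,
    beta: float,
    alphas,
    *,
    n_replicates: int = 2000,
    horizon: int = 5000,
    window: int = 500,
    seed=None,
) -> tuple[float, pd.DataFrame]:
    """Locate the hot-stove indifference point of asocial learners.

    Scans `alphas` at fixed `beta`, estimating the late-trial (final
    `window` trials) risky-choice proportion from `n_replicates`
    independent learners per point, then linearly interpolates the alpha
    at which the proportion crosses one half. Returns
    (alpha_cross * (beta + 1), per-alpha table); the crossing is NaN if
    the scan never brackets one half.
    """
    rng = np.random.default_rng(seed)
    alphas = np.sort(np.asarray(list(alphas), dtype=float))
    props = []
    for a in alphas:
        res = simulate_groups(
            task, a, beta, variant="asocial", n_replicates=n_replicates,
            group_size=1, horizon=horizon, rng=rng, record_counts=False,
        )
        props.append(prop_risky_last_trials(res, window))
    props = np.asarray(props)
    table = pd.DataFrame({"alpha": alphas, "prop_risky_late": props})
    crossing = np.nan
    for i in range(len(alphas) - 1):
        lo, hi = props[i], props[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            a_cross = alphas[i] + (0.5 - lo) * (alphas[i + 1] - alphas[i]) / (hi - lo)
            crossing = a_cross * (beta + 1.0)
            break
    return float(crossing), table


def compare_horizons(
    task: TaskConfig,
    params: AgentParams,
    horizons: Iterable[int],
    *,
    n_replicates: int = 1000,
    group_size: int = 1,
    seed=None,
) -> pd.DataFrame:
    """Second-half risky proportion per time horizon for one parameter set."""
    rng = np.random.default_rng(seed)
    rows = []
    for T in horizons:
        res = simulate_groups(
            task, params.alpha, params.beta, params.sigma, params.theta,
            variant=params.variant, n_replicates=n_replicates,
            group_size=group_size, horizon=int(T), rng=rng, record_counts=False,
        )
        rows.append(
            {"horizon": int(T), "prop_risky_second_half": prop_risky_second_half(res, task)}
        )
    return pd.DataFrame(rows)


# documented example compositions for heterogeneous groups of five, each
# mean-matched to the homogeneous baseline alpha=0.5, beta=7, sigma=0.3,
# theta=2 (exact member values are a package choice; only the majority
# structure and the mean-matching are constrained)
_BASE = dict(alpha=0.5, beta=7.0, sigma=0.3, theta=2.0)
_FOCAL_SETS = {
    "alpha": {
        "homogeneous": [0.5] * 5,
        "majority_susceptible": [0.1, 0.2, 0.6, 0.8, 0.8],
        "majority_resistant": [0.15, 0.2, 0.2, 0.95, 1.0],
        "all_susceptible_small_spread": [0.3, 0.4, 0.5, 0.6, 0.7],
    },
    "beta": {
        "homogeneous": [7.0] * 5,
        "majority_susceptible": [1.0, 2.0, 10.0, 12.0, 10.0],
        "majority_resistant": [1.0, 2.0, 3.0, 14.0, 15.0],
        "all_susceptible_small_spread": [5.0, 6.0, 7.0, 8.0, 9.0],
    },
    "sigma": {
        "homogeneous": [0.3] * 5,
        "highest_diversity": [0.0, 0.15, 0.3, 0.45, 0.6],
        "moderate_heterogeneity": [0.15, 0.225, 0.3, 0.375, 0.45],
        "small_spread": [0.24, 0.27, 0.3, 0.33, 0.36],
    },
    "theta": {
        "homogeneous": [2.0] * 5,
        "highest_diversity": [-1.0, 0.0, 1.0, 2.0, 8.0],
        "moderate_heterogeneity": [0.0, 1.0, 2.0, 3.0, 4.0],
        "small_spread": [1.0, 1.5, 2.0, 2.5, 3.0],
    },
}


def example_compositions(focal: str) -> dict[str, list[AgentParams]]:
    """Example five-member compositions varying one focal parameter.

    Non-focal parameters are held at alpha=0.5, beta=7, sigma=0.3,
    theta=2; the focal parameter's group mean matches that baseline.
    """
    if focal not in _FOCAL_SETS:
        raise ValueError(f"focal must be one of {sorted(_FOCAL_SETS)}")
    out = {}
    for name, values in _FOCAL_SETS[focal].items():
        out[name] = [AgentParams(**{**_BASE, focal: v}) for v in values]
    return out
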