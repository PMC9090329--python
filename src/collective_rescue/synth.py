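"""Synthetic experiment-like datasets.

Emulates the statistical structure of the online study design: group
sessions of 2-8 players plus a solo condition, 70 trials, optional
per-trial dropout hazard, and the inclusion rule that keeps only subjects
who completed at least 35 rounds. Individual learning-model parameters
are drawn from a hierarchical generative model (logit-normal alpha and
sigma, log-normal beta, normal theta); solo subjects have sigma = 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .simulate import session_table, simulate_groups
from .tasks import TaskConfig, make_preset_task

__all__ = [
    "HierGlobals",
    "ExperimentDesign",
    "TABLE3_1R1S_POS_GROUP",
    "generate_experiment",
    "draw_individual_params",
    "apply_inclusion_filter",
    "write_dataset",
    "read_dataset",
    "stack_dataset",
    "DATA_COLUMNS",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class HierGlobals:
    """Global (population-level) parameters of the generative hierarchy.

    Locations are on the transformed scales (logit for alpha and sigma,
    log for beta, identity for theta); scales are the transformed-scale
    standard deviations.
    """

    mu_logit_alpha: float
    mu_log_beta: float
    mu_logit_sigma: float = -np.inf  # logistic(-inf) = 0: asocial
    mu_theta: float = 0.0
    s_alpha: float = 1.0
    s_beta: float = 1.0
    s_sigma: float = 1.0
    s_theta: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)


# group-condition fit for the positive-RP 1-risky-1-safe task (global
# means mu_logit_alpha=-2.2, mu_log_beta=1.4, mu_logit_sigma=-2.4,
# mu_theta=1.4); the population spreads are not reported, so unit
# spreads on the transformed scales (the conventional weakly
# informative individual-difference magnitude) are the package default
TABLE3_1R1S_POS_GROUP = HierGlobals(
    mu_logit_alpha=-2.2,
    mu_log_beta=1.4,
    mu_logit_sigma=-2.4,
    mu_theta=1.4,
)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def draw_individual_params(
    globals_: HierGlobals,
    n: int,
    rng: np.random.Generator,
    *,
    social: bool = True,
) -> pd.DataFrame:
    """Draw n subjects' (alpha, beta, sigma, theta) from the hierarchy.

    With social=False (solo condition) sigma is fixed at 0 and theta at 0.
    """
    z = rng.standard_normal((n, 4))
    alpha = _logistic(globals_.mu_logit_alpha + globals_.s_alpha * z[:, 0])
    beta = np.exp(globals_.mu_log_beta + globals_.s_beta * z[:, 1])
    if social and np.isfinite(globals_.mu_logit_sigma):
        sigma = _logistic(globals_.mu_logit_sigma + globals_.s_sigma * z[:, 2])
        theta = globals_.mu_theta + globals_.s_theta * z[:, 3]
    else:
        sigma = np.zeros(n)
        theta = np.zeros(n)
    return pd.DataFrame({"alpha": alpha, "beta": beta, "sigma": sigma, "theta": theta})


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic experiment session batch."""

    task_name: str = "exp_1r1s_pos"
    n_groups: int = 10
    group_sizes: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)  # sampled uniformly
    n_individual: int = 0
    trials: int = 70
    dropout_hazard: float = 0.0
    seed: int = 0
    variant: str = "decision_biasing"
    globals_: HierGlobals = field(default_factory=lambda: TABLE3_1R1S_POS_GROUP)
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if any(g < 1 or g > 8 for g in self.group_sizes):
            raise ValueError("group sizes must lie in {1, ..., 8}")
        if not 0.0 <= self.dropout_hazard < 1.0:
            raise ValueError("dropout hazard must be in [0, 1)")
        if self.n_groups < 0 or self.n_individual < 0:
            raise ValueError("counts must be >= 0")

    @property
    def task(self) -> TaskConfig:
        return make_preset_task(self.task_name)


def _draw_completed(n: int, trials: int, hazard: float, rng: np.random.Generator) -> np.ndarray:
    """Number of completed trials per subject under a per-trial dropout
    hazard (independent of behaviour)."""
    if hazard <= 0:
        return np.full(n, trials, dtype=int)
    u = rng.random((n, trials))
    dropped = u < hazard
    # subject completes trials up to (excluding) the first dropout event
    first = np.where(dropped.any(axis=1), dropped.argmax(axis=1), trials)
    return first.astype(int)


def generate_experiment(design: ExperimentDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic dataset mirroring the study design.

    Returns (data, truth): `data` is one row per subject x completed
    trial with displayed lagged social counts; `truth` is one row per
    subject with the generating parameter values and completion counts.
    """
    task = design.task
    rng = np.random.default_rng(design.seed)
    frames, truth_rows = [], []
    subject_counter = 0
    group_counter = 0

    sizes = [int(rng.choice(design.group_sizes)) for _ in range(design.n_groups)]
    for gsize in sizes:
        params = draw_individual_params(design.globals_, gsize, rng, social=True)
        completed = _draw_completed(gsize, design.trials, design.dropout_hazard, rng)
        res = simulate_groups(
            task,
            params["alpha"].to_numpy(),
            params["beta"].to_numpy(),
            params["sigma"].to_numpy(),
            params["theta"].to_numpy(),
            variant=design.variant,
            n_replicates=1,
            group_size=gsize,
            horizon=design.trials,
            rng=rng,
            include_self=design.include_self,
            completed=completed[None, :],
        )
        df = session_table(res)
        df["subject_id"] = df["individual"] + subject_counter
        df["group_id"] = group_counter
        df["condition"] = "group"
        df["task"] = task.name
        frames.append(df)
        for m in range(gsize):
            truth_rows.append(
                {
                    "subject_id": subject_counter + m,
                    "group_id": group_counter,
                    "condition": "group",
                    "alpha": params["alpha"].iloc[m],
                    "beta": params["beta"].iloc[m],
                    "sigma": params["sigma"].iloc[m],
                    "theta": params["theta"].iloc[m],
                    "completed": int(completed[m]),
                }
            )
        subject_counter += gsize
        group_counter += 1

    if design.n_individual > 0:
        params = draw_individual_params(
            design.globals_, design.n_individual, rng, social=False
        )
        completed = _draw_completed(
            design.n_individual, design.trials, design.dropout_hazard, rng
        )
        res = simulate_groups(
            task,
            params["alpha"].to_numpy()[:, None],
            params["beta"].to_numpy()[:, None],
            0.0,
            0.0,
            variant=design.variant,
            n_replicates=design.n_individual,
            group_size=1,
            horizon=design.trials,
            rng=rng,
            completed=completed[:, None],
        )
        df = session_table(res)
        df["subject_id"] = df["replicate"] + subject_counter
        df["group_id"] = df["replicate"] + group_counter
        df["condition"] = "individual"
        df["task"] = task.name
        frames.append(df)
        for m in range(design.n_individual):
            truth_rows.append(
                {
                    "subject_id": subject_counter + m,
                    "group_id": group_counter + m,
                    "condition": "individual",
                    "alpha": params["alpha"].iloc[m],
                    "beta": params["beta"].iloc[m],
                    "sigma": 0.0,
                    "theta": 0.0,
                    "completed": int(completed[m]),
                }
            )

    if not frames:
        data = pd.DataFrame(columns=DATA_COLUMNS + ["count_option_1", "count_option_2"])
    else:
        data = pd.concat(frames, ignore_index=True)
        count_cols = [c for c in data.columns if c.startswith("count_option_")]
        data = data[DATA_COLUMNS + count_cols]
    truth = pd.DataFrame(truth_rows)
    return data, truth


DATA_COLUMNS = ["subject_id", "group_id", "condition", "task", "trial", "choice", "payoff"]


def apply_inclusion_filter(
    data: pd.DataFrame, min_rounds: int = 35
) -> tuple[pd.DataFrame, list[int]]:
    """Drop subjects who completed fewer than `min_rounds` trials.

    Returns (filtered data, sorted ids of removed subjects). Emits a
    warning-free empty frame if nobody qualifies.
    """
    if len(data) == 0:
        return data.copy(), []
    counts = data.groupby("subject_id")["trial"].count()
    keep = counts[counts >= min_rounds].index
    removed = sorted(set(counts.index) - set(keep))
    if len(keep) == 0:
        import warnings

        warnings.warn("inclusion filter removed every subject", stacklevel=2)
    return data[data["subject_id"].isin(keep)].copy(), removed


def write_dataset(path: str, data: pd.DataFrame, truth: pd.DataFrame | None = None) -> None:
    """Write the dataset (and optional truth table) as CSV files.

    `path` is the data CSV path; the truth table goes next to it with a
    `_truth` suffix. A schema version column is embedded.
    """
    out = data.copy()
    out["schema_version"] = SCHEMA_VERSION
    out.to_csv(path, index=False)
    if truth is not None:
        truth.to_csv(_truth_path(path), index=False)


def _truth_path(path: str) -> str:
    root, ext = os.path.splitext(path)
    return f"{root}_truth{ext or '.csv'}"


def read_dataset(path: str) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a dataset written by `write_dataset`; validates the schema."""
    data = pd.read_csv(path)
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dataset at {path} is missing required column(s): {missing}")
    if not any(c.startswith("count_option_") for c in data.columns):
        raise ValueError(f"dataset at {path} is missing count_option_* columns")
    data = data.drop(columns=["schema_version"], errors="ignore")
    tp = _truth_path(path)
    truth = pd.read_csv(tp) if os.path.exists(tp) else None
    return data, truth


def stack_dataset(data: pd.DataFrame, task: TaskConfig) -> dict:
    """Stack a long-format dataset into padded per-subject arrays.

    Returns dict with `subject_ids` (n,), `choices` (n, T) int (-1 where
    missing), `payoffs` (n, T) scaled by task.payoff_scale, `counts`
    (n, T, K) lagged displayed counts, and `condition` (n,) strings.
    Trials are 1-based in the table; row t-1 of the arrays is trial t.
    """
    K = task.n_options
    count_cols = [f"count_option_{k + 1}" for k in range(K)]
    for c in count_cols:
        if c not in data.columns:
            raise ValueError(f"dataset is missing required column(s): ['{c}']")
    subject_ids = np.array(sorted(data["subject_id"].unique()))
    n = len(subject_ids)
    T = int(data["trial"].max())
    choices = np.full((n, T), -1, dtype=int)
    payoffs = np.zeros((n, T))
    counts = np.zeros((n, T, K))
    condition = np.empty(n, dtype=object)
    index = {s: i for i, s in enumerate(subject_ids)}
    for sid, sub in data.groupby("subject_id"):
        i = index[sid]
        t = sub["trial"].to_numpy(dtype=int) - 1
        choices[i, t] = sub["choice"].to_numpy(dtype=int)
        payoffs[i, t] = sub["payoff"].to_numpy(dtype=float) * task.payoff_scale
        counts[i, t, :] = sub[count_cols].to_numpy(dtype=float)
        condition[i] = sub["condition"].iloc[0] if "condition" in sub.columns else "group"
    return {
        "subject_ids": subject_ids,
        "choices": choices,
        "payoffs": payoffs,
        "counts": counts,
        "condition": condition,
        "task": task,
    }
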