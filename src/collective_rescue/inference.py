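"""Model fitting, comparison, recovery and posterior prediction.

Per-subject WAIC (deviance scale) is computed from the pointwise
log-likelihood draws; models are compared with the random-effects
Bayesian model selection of Stephan et al. (variational Dirichlet fixed
point over model frequencies, exceedance probabilities by Monte Carlo),
with per-subject log model evidence approximated as -WAIC/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .mcmc import HierarchicalFitter, McmcSettings, PosteriorFit, PriorSpec
from .simulate import simulate_groups
from .synth import (
    ExperimentDesign,
    HierGlobals,
    apply_inclusion_filter,
    generate_experiment,
    stack_dataset,
)
from .tasks import TaskConfig

__all__ = [
    "fit_hierarchical",
    "compute_waic",
    "bayesian_model_selection",
    "ModelComparisonResult",
    "compare_models",
    "parameter_recovery",
    "RecoveryReport",
    "posthoc_simulate",
]


def fit_hierarchical(
    data: pd.DataFrame | dict,
    task: TaskConfig,
    *,
    variant: str = "decision_biasing",
    condition: str = "group",
    settings: McmcSettings | None = None,
    prior: PriorSpec | None = None,
) -> PosteriorFit:
    """Fit one model variant to one condition of a dataset.

    `data` is a long-format table (or an already-stacked dict); group and
    solo conditions are fitted separately, and the solo condition carries
    no (sigma, theta) block since sigma = 0 is assumed there.
    """
    if isinstance(data, pd.DataFrame):
        if "condition" in data.columns:
            data = data[data["condition"] == condition]
        stacked = stack_dataset(data, task)
    else:
        stacked = data
        sel = np.asarray(stacked["condition"]) == condition
        if not sel.all():
            stacked = {
                k: (v[sel] if isinstance(v, np.ndarray) and v.shape[:1] == sel.shape else v)
                for k, v in stacked.items()
            }
    social = condition == "group" and variant != "asocial"
    fitter = HierarchicalFitter(stacked, variant=variant, social=social, prior=prior)
    return fitter.fit(settings)


def compute_waic(fit: PosteriorFit) -> pd.DataFrame:
    """Per-subject WAIC on the deviance scale (lower is better).

    WAIC_i = -2 (sum_t lppd_it - sum_t var_draws(loglik_it)), with the
    pointwise terms taken over all posterior draws of all chains.
    """
    if fit.pointwise is None:
        raise ValueError("fit has no pointwise log-likelihood draws")
    C, D, n, T = fit.pointwise.shape
    if C * D < 2:
        raise ValueError("need at least 2 posterior draws for WAIC")
    ll = fit.pointwise.reshape(C * D, n, T)
    lppd = logsumexp(ll, axis=0) - np.log(C * D)  # (n, T)
    p_waic = ll.var(axis=0, ddof=1)  # (n, T)
    waic = -2.0 * (lppd.sum(axis=1) - p_waic.sum(axis=1))
    return pd.DataFrame(
        {"subject_id": fit.subject_ids, "waic": waic, "p_waic": p_waic.sum(axis=1)}
    )


@dataclass
class ModelComparisonResult:
    models: list[str]
    frequencies: np.ndarray  # expected model frequencies, sum to 1
    exceedance: np.ndarray  # exceedance probabilities, sum to 1
    dirichlet_alpha: np.ndarray
    waic: pd.DataFrame  # subjects x models

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "frequency": self.frequencies,
                "exceedance": self.exceedance,
                "dirichlet_alpha": self.dirichlet_alpha,
                "mean_waic": [self.waic[m].mean() for m in self.models],
            }
        )


def bayesian_model_selection(
    waic_table: pd.DataFrame,
    *,
    alpha0: float = 1.0,
    n_mc: int = 100_000,
    seed=None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ModelComparisonResult:
    """Random-effects Bayesian model selection over a subjects x models
    WAIC table (columns = model names, one row per subject).

    Per-subject log evidence is -WAIC/2. The Dirichlet posterior over
    model frequencies is estimated by the standard variational fixed
    point; exceedance probabilities by Monte Carlo over that Dirichlet.
    """
    models = list(waic_table.columns)
    waic = waic_table.to_numpy(dtype=float)
    n, M = waic.shape
    if n < 1 or M < 1:
        raise ValueError("need at least one subject and one model")
    log_ev = -waic / 2.0
    alpha = np.full(M, alpha0, dtype=float)
    for _ in range(max_iter):
        log_u = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        new_alpha = alpha0 + np.exp(log_u).sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    freq = alpha / alpha.sum()
    if M == 1:
        xp = np.array([1.0])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_mc)
        best = draws.argmax(axis=1)
        xp = np.bincount(best, minlength=M) / n_mc
    return ModelComparisonResult(
        models=models,
        frequencies=freq,
        exceedance=xp,
        dirichlet_alpha=alpha,
        waic=waic_table.copy(),
    )


def compare_models(
    data: pd.DataFrame,
    task: TaskConfig,
    variants=("asocial", "decision_biasing", "value_shaping"),
    *,
    condition: str = "group",
    settings: McmcSettings | None = None,
    seed=None,
) -> tuple[ModelComparisonResult, dict[str, PosteriorFit]]:
    """Fit each variant to the data and run Bayesian model selection."""
    fits, waics = {}, {}
    for v in variants:
        fit = fit_hierarchical(data, task, variant=v, condition=condition, settings=settings)
        fits[v] = fit
        waics[v] = compute_waic(fit).set_index("subject_id")["waic"]
    table = pd.DataFrame(waics)
    return bayesian_model_selection(table, seed=seed), fits


@dataclass
class RecoveryReport:
    correlations: dict  # per natural parameter, true vs posterior mean
    coverage: float  # fraction of true globals inside 95% CIs
    n_globals_covered: int
    n_globals: int
    truth: pd.DataFrame
    recovered: pd.DataFrame
    fit: PosteriorFit

    @property
    def min_correlation(self) -> float:
        return float(min(self.correlations.values()))


def parameter_recovery(
    globals_: HierGlobals,
    design: ExperimentDesign,
    *,
    seed: int = 0,
    settings: McmcSettings | None = None,
    min_rounds: int = 35,
) -> RecoveryReport:
    """Generate synthetic data from known globals, refit, and report
    true-vs-recovered Pearson correlations of the individual parameters
    plus 95%-interval coverage of the true global values."""
    design = ExperimentDesign(
        **{**design.__dict__, "globals_": globals_, "seed": seed}
    )
    data, truth = generate_experiment(design)
    data, _removed = apply_inclusion_filter(data, min_rounds=min_rounds)
    condition = "group" if design.n_groups > 0 else "individual"
    fit = fit_hierarchical(
        data, design.task, variant=design.variant, condition=condition, settings=settings
    )
    est = fit.subject_means()
    merged = truth.merge(est, on="subject_id", suffixes=("_true", "_hat"))
    correlations = {}
    for name in fit.names:
        x = merged[f"{name}_true"].to_numpy()
        y = merged[f"{name}_hat"].to_numpy()
        correlations[name] = float(np.corrcoef(x, y)[0, 1])
    # coverage of the generating global values by the 95% intervals
    true_globals = {
        "mu_alpha": globals_.mu_logit_alpha,
        "mu_beta": globals_.mu_log_beta,
        "scale_alpha": globals_.s_alpha,
        "scale_beta": globals_.s_beta,
    }
    if fit.social:
        true_globals.update(
            {
                "mu_sigma": globals_.mu_logit_sigma,
                "mu_theta": globals_.mu_theta,
                "scale_sigma": globals_.s_sigma,
                "scale_theta": globals_.s_theta,
            }
        )
    summary = fit.global_summary().set_index("param")
    covered = 0
    for gname, gval in true_globals.items():
        row = summary.loc[gname]
        if row["q2.5"] <= gval <= row["q97.5"]:
            covered += 1
    return RecoveryReport(
        correlations=correlations,
        coverage=covered / len(true_globals),
        n_globals_covered=covered,
        n_globals=len(true_globals),
        truth=truth,
        recovered=est,
        fit=fit,
    )


def posthoc_simulate(
    fit: PosteriorFit,
    task: TaskConfig,
    *,
    n_replicates: int = 1000,
    group_size: int = 6,
    horizon: int | None = None,
    seed=None,
    band: float = 0.8,
    return_replicates: bool = False,
):
    """Posterior-predictive risky-choice trajectories.

    For each replicate a posterior draw of the globals is selected, a
    fresh group of `group_size` agents is sampled from that draw's
    hierarchy, and a session is simulated; reported per trial are the
    mean risky-choice proportion and the central `band` interval
    (80% by default) across replicates.
    """
    rng = np.random.default_rng(seed)
    C, D, P = fit.mu.shape
    idx = rng.integers(0, C * D, size=n_replicates)
    mu = fit.mu.reshape(C * D, P)[idx]  # (R, P)
    sc = fit.scale.reshape(C * D, P)[idx]
    R, N = n_replicates, group_size
    z = rng.standard_normal((R, N, P))
    eta = mu[:, None, :] + sc[:, None, :] * z
    from scipy.special import expit

    cols = {name: j for j, name in enumerate(fit.names)}
    alpha = expit(eta[:, :, cols["alpha"]])
    beta = np.exp(eta[:, :, cols["beta"]])
    if fit.social:
        sigma = expit(eta[:, :, cols["sigma"]])
        theta = eta[:, :, cols["theta"]]
        variant = fit.variant
    else:
        sigma = np.zeros((R, N))
        theta = np.zeros((R, N))
        variant = "asocial"
    res = simulate_groups(
        task, alpha, beta, sigma, theta, variant=variant,
        n_replicates=R, group_size=N, horizon=horizon, rng=rng,
        record_counts=False,
    )
    target = task.target_risky_index
    risky = (res.choices == target).mean(axis=1)  # (R, T)
    lo, hi = (1.0 - band) / 2.0, 1.0 - (1.0 - band) / 2.0
    T = risky.shape[1]
    summary = pd.DataFrame(
        {
            "trial": np.arange(1, T + 1),
            "mean": risky.mean(axis=0),
            f"q{lo:.2f}": np.quantile(risky, lo, axis=0),
            f"q{hi:.2f}": np.quantile(risky, hi, axis=0),
        }
    )
    if return_replicates:
        return summary, risky
    return summary
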