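"""Hierarchical Bayesian fitting of the learning models by MCMC.

The hierarchy is non-centred: each subject i has a standard-normal vector
z_i, and the natural-scale parameters are

    alpha_i = logistic(mu_alpha + s_alpha z_i1)
    beta_i  = exp(mu_beta  + s_beta  z_i2)
    sigma_i = logistic(mu_sigma + s_sigma z_i3)
    theta_i = mu_theta + s_theta z_i4   (unbounded)

with weakly informative priors Normal(0, 2) on the locations and
half-Student-t(4, 0, 1) on the scales. Sampling is adaptive random-walk
Metropolis within Gibbs: per-subject joint proposals on z (vectorised
across subjects, valid because subjects are conditionally independent
given the globals) and component-wise proposals on the global locations
and log-scales, with Robbins-Monro step-size adaptation during warmup.
Each sweep ends with an interweaving step in the centred
parameterisation (holding the subject-level effects eta_i = mu + s z_i
fixed): mu is redrawn exactly from its conjugate conditional and the
scales by a likelihood-free Metropolis step, which decouples the globals
from z and removes the slow random-walk drift the non-centred moves
alone would suffer.
Convergence is summarised by rank-normalised R-hat and effective sample
size (via arviz); a fit is flagged converged only when all R-hat < 1.01
and all global ESS >= 500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import t as student_t

from .likelihood import replay_loglik

__all__ = ["McmcSettings", "PriorSpec", "PosteriorFit", "HierarchicalFitter"]


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int | None = None
    store_pointwise: bool = True
    z_updates_per_sweep: int = 2
    rhat_threshold: float = 1.01
    ess_threshold: float = 500.0


@dataclass(frozen=True)
class PriorSpec:
    """Priors on the transformed-scale global parameters."""

    mu_loc: float = 0.0
    mu_sd: float = 2.0
    scale_df: float = 4.0
    scale_scale: float = 1.0

    def logp_mu(self, mu: np.ndarray) -> float:
        return float(-0.5 * np.sum(((mu - self.mu_loc) / self.mu_sd) ** 2))

    def logp_scale(self, log_v: np.ndarray) -> float:
        # half-t prior on v, sampled on log v (Jacobian: + log v)
        v = np.exp(log_v)
        lp = student_t.logpdf(v, df=self.scale_df, scale=self.scale_scale)
        return float(np.sum(lp + np.log(2.0) + log_v))

    def logp_scale_scalar(self, log_v: float) -> float:
        v = np.exp(log_v)
        return float(
            student_t.logpdf(v, df=self.scale_df, scale=self.scale_scale)
            + np.log(2.0)
            + log_v
        )


_TRANSFORMS = {
    "alpha": expit,
    "beta": np.exp,
    "sigma": expit,
    "theta": lambda x: x,
}


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics of one hierarchical fit.

    mu, scale: (chains, draws, P) global locations / scales per block;
    subject: (chains, draws, n, P) natural-scale individual parameters;
    pointwise: (chains, draws, n, T) per-trial log-likelihoods or None.
    """

    names: list[str]
    variant: str
    social: bool
    subject_ids: np.ndarray
    mu: np.ndarray
    scale: np.ndarray
    subject: np.ndarray
    pointwise: np.ndarray | None
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool = False
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.subject.shape[2]

    def subject_means(self):
        """Posterior-mean natural-scale parameters per subject."""
        import pandas as pd

        m = self.subject.mean(axis=(0, 1))  # (n, P)
        df = pd.DataFrame(m, columns=self.names)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def global_summary(self):
        """Posterior mean and central 95% interval for globals."""
        import pandas as pd

        rows = []
        for j, name in enumerate(self.names):
            for kind, arr in (("mu", self.mu[..., j]), ("scale", self.scale[..., j])):
                flat = arr.reshape(-1)
                rows.append(
                    {
                        "param": f"{kind}_{name}",
                        "mean": float(flat.mean()),
                        "q2.5": float(np.quantile(flat, 0.025)),
                        "q97.5": float(np.quantile(flat, 0.975)),
                        "rhat": self.rhat.get(f"{kind}_{name}", np.nan),
                        "ess": self.ess.get(f"{kind}_{name}", np.nan),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, path: str) -> None:
        np.savez_compressed(
            path,
            names=np.array(self.names),
            variant=self.variant,
            social=self.social,
            subject_ids=self.subject_ids,
            mu=self.mu,
            scale=self.scale,
            subject=self.subject,
            pointwise=self.pointwise if self.pointwise is not None else np.empty(0),
            converged=self.converged,
        )

    @classmethod
    def load(cls, path: str) -> "PosteriorFit":
        d = np.load(path, allow_pickle=True)
        pw = d["pointwise"]
        return cls(
            names=[str(x) for x in d["names"]],
            variant=str(d["variant"]),
            social=bool(d["social"]),
            subject_ids=d["subject_ids"],
            mu=d["mu"],
            scale=d["scale"],
            subject=d["subject"],
            pointwise=pw if pw.size else None,
            converged=bool(d["converged"]),
        )


class HierarchicalFitter:
    """Fits one model variant to one experimental condition.

    `data` is a stacked dataset (see synth.stack_dataset) already
    restricted to a single condition; `social` controls whether the
    (sigma, theta) block exists (False for the solo condition, where
    sigma = 0 is assumed, and for the asocial variant).
    """

    def __init__(
        self,
        data: dict,
        variant: str = "decision_biasing",
        social: bool | None = None,
        prior: PriorSpec | None = None,
    ):
        self.choices = np.asarray(data["choices"], dtype=int)
        self.payoffs = np.asarray(data["payoffs"], dtype=float)
        self.counts = np.asarray(data["counts"], dtype=float)
        self.subject_ids = np.asarray(data["subject_ids"])
        self.variant = variant
        if social is None:
            social = variant != "asocial"
        self.social = bool(social)
        self.names = ["alpha", "beta"] + (["sigma", "theta"] if self.social else [])
        self.prior = prior or PriorSpec()
        self.n = self.choices.shape[0]
        if self.n < 1:
            raise ValueError("need at least one subject")

    # -- model ----------------------------------------------------------

    def _natural_params(self, mu, log_v, z):
        out = {}
        for j, name in enumerate(self.names):
            eta = mu[j] + np.exp(log_v[j]) * z[:, j]
            out[name] = _TRANSFORMS[name](eta)
        if not self.social:
            out["sigma"] = np.zeros(self.n)
            out["theta"] = np.zeros(self.n)
        return out

    def _loglik(self, mu, log_v, z, pointwise=False):
        p = self._natural_params(mu, log_v, z)
        variant = self.variant if self.social else "asocial"
        return replay_loglik(
            self.choices,
            self.payoffs,
            self.counts,
            p["alpha"],
            p["beta"],
            p["sigma"],
            p["theta"],
            variant=variant,
            pointwise=pointwise,
        )

    def _logp_globals(self, mu, log_v) -> float:
        return self.prior.logp_mu(mu) + self.prior.logp_scale(log_v)

    # -- sampling -------------------------------------------------------

    def fit(self, settings: McmcSettings | None = None) -> PosteriorFit:
        settings = settings or McmcSettings()
        if settings.draws < 2:
            raise ValueError("need at least 2 posterior draws")
        P, n = len(self.names), self.n
        root = np.random.default_rng(settings.seed)
        chain_seeds = root.integers(0, 2**31 - 1, size=settings.chains)

        mus = np.empty((settings.chains, settings.draws, P))
        scales = np.empty_like(mus)
        subjects = np.empty((settings.chains, settings.draws, n, P))
        T = self.choices.shape[1]
        pointwise = (
            np.empty((settings.chains, settings.draws, n, T))
            if settings.store_pointwise
            else None
        )
        accept = {"z": [], "mu": [], "scale": []}

        for c in range(settings.chains):
            rng = np.random.default_rng(int(chain_seeds[c]))
            mu = rng.normal(0.0, 0.5, P)
            log_v = np.log(0.5) + rng.normal(0.0, 0.3, P)
            z = 0.1 * rng.standard_normal((n, P))
            z_scale = np.full(n, 0.3)
            mu_scale = np.full(P, 0.15)
            v_scale = np.full(P, 0.2)
            cv_scale = np.full(P, 0.3)

            ll = self._loglik(mu, log_v, z)
            lp_z = -0.5 * (z**2).sum(axis=1)
            lp_g = self._logp_globals(mu, log_v)
            acc_counts = {"z": 0.0, "mu": 0.0, "scale": 0.0}
            n_sweeps = settings.warmup + settings.draws
            for sweep in range(n_sweeps):
                warm = sweep < settings.warmup
                gamma = (sweep + 1) ** -0.6
                # subject-level z updates (vectorised over subjects)
                for _ in range(settings.z_updates_per_sweep):
                    prop = z + z_scale[:, None] * rng.standard_normal((n, P))
                    ll_p = self._loglik(mu, log_v, prop)
                    lp_zp = -0.5 * (prop**2).sum(axis=1)
                    with np.errstate(invalid="ignore"):
                        logr = (ll_p + lp_zp) - (ll + lp_z)
                    acc = np.log(rng.random(n)) < logr
                    z[acc] = prop[acc]
                    ll[acc] = ll_p[acc]
                    lp_z[acc] = lp_zp[acc]
                    if warm:
                        z_scale *= np.exp(gamma * (acc.astype(float) - 0.3))
                        np.clip(z_scale, 1e-3, 10.0, out=z_scale)
                    else:
                        acc_counts["z"] += acc.mean() / settings.z_updates_per_sweep
                # global locations, component-wise
                for j in range(P):
                    mu_p = mu.copy()
                    mu_p[j] += mu_scale[j] * rng.standard_normal()
                    ll_p = self._loglik(mu_p, log_v, z)
                    lp_gp = self._logp_globals(mu_p, log_v)
                    logr = (ll_p.sum() + lp_gp) - (ll.sum() + lp_g)
                    if np.log(rng.random()) < logr:
                        mu, ll, lp_g = mu_p, ll_p, lp_gp
                        if not warm:
                            acc_counts["mu"] += 1.0 / P
                        if warm:
                            mu_scale[j] *= np.exp(gamma * (1.0 - 0.44))
                    elif warm:
                        mu_scale[j] *= np.exp(gamma * (0.0 - 0.44))
                    np.clip(mu_scale, 1e-3, 5.0, out=mu_scale)
                # global scales, component-wise on log v
                for j in range(P):
                    lv_p = log_v.copy()
                    lv_p[j] += v_scale[j] * rng.standard_normal()
                    ll_p = self._loglik(mu, lv_p, z)
                    lp_gp = self._logp_globals(mu, lv_p)
                    logr = (ll_p.sum() + lp_gp) - (ll.sum() + lp_g)
                    if np.log(rng.random()) < logr:
                        log_v, ll, lp_g = lv_p, ll_p, lp_gp
                        if not warm:
                            acc_counts["scale"] += 1.0 / P
                        if warm:
                            v_scale[j] *= np.exp(gamma * (1.0 - 0.44))
                    elif warm:
                        v_scale[j] *= np.exp(gamma * (0.0 - 0.44))
                    np.clip(v_scale, 1e-3, 5.0, out=v_scale)

                # interweaving: centred update of the globals with the
                # subject-level effects eta held fixed (likelihood-free)
                for j in range(P):
                    v_j = np.exp(log_v[j])
                    eta = mu[j] + v_j * z[:, j]
                    # exact conjugate draw of mu_j | eta, v_j
                    prec = 1.0 / self.prior.mu_sd**2 + n / v_j**2
                    mean = (
                        self.prior.mu_loc / self.prior.mu_sd**2 + eta.sum() / v_j**2
                    ) / prec
                    mu[j] = mean + rng.standard_normal() / np.sqrt(prec)
                    # Metropolis on log v_j | eta, mu_j
                    resid2 = float(((eta - mu[j]) ** 2).sum())

                    def _lp(lv: float) -> float:
                        return (
                            -n * lv
                            - 0.5 * resid2 * np.exp(-2.0 * lv)
                            + self.prior.logp_scale_scalar(lv)
                        )

                    cur = _lp(float(log_v[j]))
                    lv_p = float(log_v[j]) + cv_scale[j] * rng.standard_normal()
                    if np.log(rng.random()) < _lp(lv_p) - cur:
                        log_v[j] = lv_p
                        if warm:
                            cv_scale[j] *= np.exp(gamma * (1.0 - 0.44))
                    elif warm:
                        cv_scale[j] *= np.exp(gamma * (0.0 - 0.44))
                    np.clip(cv_scale, 1e-3, 5.0, out=cv_scale)
                    z[:, j] = (eta - mu[j]) / np.exp(log_v[j])
                lp_z = -0.5 * (z**2).sum(axis=1)
                lp_g = self._logp_globals(mu, log_v)

                if not warm:
                    d = sweep - settings.warmup
                    mus[c, d] = mu
                    scales[c, d] = np.exp(log_v)
                    nat = self._natural_params(mu, log_v, z)
                    subjects[c, d] = np.column_stack([nat[k] for k in self.names])
                    if pointwise is not None:
                        pointwise[c, d] = self._loglik(mu, log_v, z, pointwise=True)
            for k in accept:
                accept[k].append(acc_counts[k] / settings.draws)

        fit = PosteriorFit(
            names=list(self.names),
            variant=self.variant,
            social=self.social,
            subject_ids=self.subject_ids,
            mu=mus,
            scale=scales,
            subject=subjects,
            pointwise=pointwise,
            accept_rates={k: float(np.mean(v)) for k, v in accept.items()},
        )
        self._attach_diagnostics(fit, settings)
        return fit

    def _attach_diagnostics(self, fit: PosteriorFit, settings: McmcSettings) -> None:
        import arviz as az

        post = {}
        for j, name in enumerate(fit.names):
            post[f"mu_{name}"] = fit.mu[..., j]
            post[f"scale_{name}"] = fit.scale[..., j]
            post[f"subject_{name}"] = fit.subject[..., j]
        idata = az.from_dict(posterior=post)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        all_ok = True
        for var in post:
            r = np.asarray(rhat[var]).max()
            e = np.asarray(ess[var]).min()
            fit.rhat[var] = float(r)
            fit.ess[var] = float(e)
            if not np.isfinite(r) or r >= settings.rhat_threshold:
                all_ok = False
            if var.startswith(("mu_", "scale_")) and e < settings.ess_threshold:
                all_ok = False
        fit.converged = all_ok
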