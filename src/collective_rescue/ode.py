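"""Reduced population dynamics of collective risky choice.

The population of size N splits into three compartments: NR individuals
currently choosing the risky option, and NS-, NS+ choosing the safe
option with a negative or positive attitude towards risk. A fraction e of
the risk-choosers hold the positive attitude (NR+ = e*NR), so e proxies
the risk premium. Behavioural transition probabilities are

    P = (1 - sigma) * p_base + sigma * N_i^theta / (NR^theta + NS^theta),

with asocial base rates ph (towards the preferred option) and pl (away
from it), 0 <= pl <= ph <= 1. The asocial system (sigma = 0) has a unique
equilibrium with a closed form for NR* - NS*; the social system is probed
numerically from grids of initial conditions to locate (possibly
multiple) locally stable equilibria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PopulationParams",
    "PopulationState",
    "transition_probs",
    "ode_rhs",
    "integrate_to_equilibrium",
    "asocial_equilibrium_diff",
    "stable_equilibria_scan",
    "classify_regime",
]


@dataclass(frozen=True)
class PopulationParams:
    """Rates of the population model; see module docstring for meanings."""

    N: float
    e: float
    pl: float
    ph: float
    sigma: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pl <= self.ph <= 1.0:
            raise ValueError(f"need 0 <= pl <= ph <= 1, got pl={self.pl}, ph={self.ph}")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError(f"e must be in [0, 1], got {self.e}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if self.N <= 0:
            raise ValueError("N must be > 0")


@dataclass(frozen=True)
class PopulationState:
    """Compartment densities (NR, NS_minus, NS_plus)."""

    NR: float
    NS_minus: float
    NS_plus: float

    @property
    def NS(self) -> float:
        return self.NS_minus + self.NS_plus

    @property
    def total(self) -> float:
        return self.NR + self.NS_minus + self.NS_plus

    def NR_plus(self, e: float) -> float:
        return e * self.NR

    def NR_minus(self, e: float) -> float:
        return (1.0 - e) * self.NR

    def as_array(self) -> np.ndarray:
        return np.array([self.NR, self.NS_minus, self.NS_plus])


def _freq_weight(n_i: float, n_other: float, theta: float) -> float:
    """Social frequency weight n_i^theta / (n_i^theta + n_other^theta),
    safe at zero densities and negative exponents."""
    if n_i < 0 or n_other < 0:
        raise ValueError("densities must be >= 0")
    if n_i == 0.0 and n_other == 0.0:
        raise ValueError("social weight undefined when NR = NS = 0")
    if theta == 0.0:
        return 0.5
    with np.errstate(divide="ignore"):
        xi = theta * np.log(n_i) if n_i > 0 else (-np.inf if theta > 0 else np.inf)
        xo = theta * np.log(n_other) if n_other > 0 else (-np.inf if theta > 0 else np.inf)
    if xi == xo:
        return 0.5
    if np.isinf(xi) and xi > 0:
        return 1.0
    if np.isinf(xo) and xo > 0:
        return 0.0
    m = max(xi, xo)
    ei, eo = np.exp(xi - m), np.exp(xo - m)
    return float(ei / (ei + eo))


def transition_probs(state: PopulationState, params: PopulationParams):
    """Per-capita transition probabilities (PS_minus, PR_minus, PS_plus,
    PR_plus) given the current behavioural distribution."""
    nr, ns = state.NR, state.NS
    fr = _freq_weight(nr, ns, params.theta)
    fs = 1.0 - fr
    s = params.sigma
    ps_minus = (1.0 - s) * params.ph + s * fs
    pr_minus = (1.0 - s) * params.pl + s * fr
    ps_plus = (1.0 - s) * params.pl + s * fs
    pr_plus = (1.0 - s) * params.ph + s * fr
    return ps_minus, pr_minus, ps_plus, pr_plus


def ode_rhs(state: PopulationState, params: PopulationParams) -> np.ndarray:
    """Time derivatives (dNR/dt, dNS-/dt, dNS+/dt); they sum to zero."""
    ps_minus, pr_minus, ps_plus, pr_plus = transition_probs(state, params)
    e = params.e
    nr_minus = (1.0 - e) * state.NR
    nr_plus = e * state.NR
    d_nr = (
        pr_minus * state.NS_minus
        - ps_minus * nr_minus
        + pr_plus * state.NS_plus
        - ps_plus * nr_plus
    )
    d_ns_minus = -pr_minus * state.NS_minus + ps_minus * nr_minus
    d_ns_plus = -pr_plus * state.NS_plus + ps_plus * nr_plus
    return np.array([d_nr, d_ns_minus, d_ns_plus])


def _rhs_vec(y: np.ndarray, params: PopulationParams) -> np.ndarray:
    return ode_rhs(PopulationState(*np.maximum(y, 0.0)), params)


def integrate_to_equilibrium(
    params: PopulationParams,
    init: PopulationState,
    tol: float = 1e-8,
    t_max: float = 1e4,
    _chunk: float = 200.0,
) -> tuple[PopulationState, bool]:
    """Integrate until all derivatives fall below `tol` (in absolute
    value) or `t_max` is reached; returns (state, converged)."""
    total = init.total
    if abs(total - params.N) > 1e-6 * params.N:
        raise ValueError(
            f"initial state total {total} does not match population size {params.N}"
        )
    y = init.as_array().astype(float)
    t = 0.0
    while t < t_max:
        span = min(_chunk, t_max - t)
        sol = solve_ivp(
            lambda _t, yy: _rhs_vec(yy, params),
            (0.0, span),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-10,
        )
        y = np.maximum(sol.y[:, -1], 0.0)
        t += span
        if np.max(np.abs(_rhs_vec(y, params))) < tol:
            return PopulationState(*y), True
    return PopulationState(*y), False


def asocial_equilibrium_diff(ph: float, pl: float, e: float, n: float) -> float:
    """Closed-form equilibrium bias NR* - NS* of the asocial system:

        -n (ph - pl) {(1-e) ph - e pl} / [(ph + pl) {(1-e) ph + e pl}]

    equivalent to the equilibrium ratio NS*:NR* = e(pl/ph) + (1-e)(ph/pl) : 1.
    """
    if pl > ph:
        raise ValueError("need pl <= ph")
    if ph + pl == 0:
        raise ValueError("ph = pl = 0 leaves the dynamics undefined")
    num = -n * (ph - pl) * ((1.0 - e) * ph - e * pl)
    den = (ph + pl) * ((1.0 - e) * ph + e * pl)
    return num / den


def classify_regime(state: PopulationState, N: float, tol: float = 1e-3) -> str:
    """Label an equilibrium: risk_seeking if NR* > NS*, risk_averse if
    NR* < NS*, neutral within `tol * N`."""
    diff = state.NR - state.NS
    if diff > tol * N:
        return "risk_seeking"
    if diff < -tol * N:
        return "risk_averse"
    return "neutral"


def _split_ns(ns: float, ns_minus: float, ns_plus: float) -> tuple[float, float]:
    # distribute a safe-density total over +/- attitudes proportionally to
    # the current split (evenly when the current split is degenerate)
    cur = ns_minus + ns_plus
    if cur <= 0:
        return ns / 2.0, ns / 2.0
    return ns * ns_minus / cur, ns * ns_plus / cur


def _is_stable(
    eq: PopulationState, params: PopulationParams, tol: float, perturb: float = 0.5
) -> bool:
    for delta in (+perturb, -perturb):
        nr = float(np.clip(eq.NR + delta, 0.0, params.N))
        if nr == eq.NR:
            continue
        ns_minus, ns_plus = _split_ns(params.N - nr, eq.NS_minus, eq.NS_plus)
        state, ok = integrate_to_equilibrium(
            params, PopulationState(nr, ns_minus, ns_plus)
        )
        if not ok or abs(state.NR - eq.NR) > tol:
            return False
    return True


def stable_equilibria_scan(
    N: float = 20.0,
    e: float = 0.65,
    pl: float = 0.2,
    ph: float = 0.7,
    theta: float = 2.0,
    sigma_grid=None,
    init_grid=None,
    *,
    distinct_tol: float = 0.1,
) -> pd.DataFrame:
    """Scan social weights sigma and initial conditions for locally
    stable equilibria.

    For each sigma, the system is integrated from every NR(0) in
    `init_grid` (default 0..N integers) with the safe density split
    evenly between attitudes; terminal states are clustered on NR*
    (tolerance `distinct_tol`) and each candidate is kept only if
    re-integration from +/-0.5-individual perturbations returns to it.

    Returns one row per (sigma, equilibrium): columns sigma, NR_star,
    NS_star, n_stable (count of distinct stable equilibria at that
    sigma), regime, and any_unconverged flag.
    """
    if sigma_grid is None:
        sigma_grid = np.linspace(0.0, 1.0, 21)
    if init_grid is None:
        init_grid = np.arange(0.0, N + 0.5, 1.0)
    rows = []
    for sigma in np.atleast_1d(sigma_grid):
        params = PopulationParams(N=N, e=e, pl=pl, ph=ph, sigma=float(sigma), theta=theta)
        endpoints: list[PopulationState] = []
        unconverged = False
        for nr0 in np.atleast_1d(init_grid):
            ns0 = (N - nr0) / 2.0
            state, ok = integrate_to_equilibrium(
                params, PopulationState(float(nr0), ns0, ns0)
            )
            if not ok:
                unconverged = True
                continue
            endpoints.append(state)
        # cluster endpoints on NR*
        clusters: list[PopulationState] = []
        for st in sorted(endpoints, key=lambda s: s.NR):
            if not clusters or abs(st.NR - clusters[-1].NR) > distinct_tol:
                clusters.append(st)
        stable = [eq for eq in clusters if _is_stable(eq, params, distinct_tol)]
        for eq in stable:
            rows.append(
                {
                    "sigma": float(sigma),
                    "NR_star": eq.NR,
                    "NS_star": eq.NS,
                    "n_stable": len(stable),
                    "regime": classify_regime(eq, N),
                    "any_unconverged": unconverged,
                }
            )
        if not stable:
            rows.append(
                {
                    "sigma": float(sigma), "NR_star": np.nan, "NS_star": np.nan,
                    "n_stable": 0, "regime": "unresolved", "any_unconverged": unconverged,
                }
            )
    return pd.DataFrame(rows)
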