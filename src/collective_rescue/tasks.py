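"""Bandit task environments.

A task is an ordered set of payoff-generating options. The canonical
two-armed task pairs a safe option paying a constant 1 against a risky
option paying Normal(1.5, 1); the experiment-style tasks use two-point
(Bernoulli) risky payoffs in points with lightly noised safe options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PayoffSpec",
    "TaskOption",
    "TaskConfig",
    "make_preset_task",
    "expected_value",
    "draw_payoff",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class PayoffSpec:
    """Payoff distribution of a single bandit arm.

    kind is one of ``constant`` (degenerate at `value`), ``gaussian``
    (Normal(`mean`, `sd`)) or ``two_point`` (pays `low` with probability
    `p_low`, else `high`).
    """

    kind: str
    value: float | None = None
    mean: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    p_low: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.value is None:
                raise ValueError("constant payoff requires `value`")
        elif self.kind == "gaussian":
            if self.mean is None or self.sd is None:
                raise ValueError("gaussian payoff requires `mean` and `sd`")
            if self.sd < 0:
                raise ValueError(f"gaussian sd must be >= 0, got {self.sd}")
        elif self.kind == "two_point":
            if self.low is None or self.high is None or self.p_low is None:
                raise ValueError("two_point payoff requires `low`, `high`, `p_low`")
            if not 0.0 <= self.p_low <= 1.0:
                raise ValueError(f"p_low must be in [0, 1], got {self.p_low}")
        else:
            raise ValueError(
                f"unknown payoff kind {self.kind!r}; "
                "expected one of constant/gaussian/two_point"
            )

    @classmethod
    def constant(cls, value: float) -> "PayoffSpec":
        return cls(kind="constant", value=float(value))

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "PayoffSpec":
        return cls(kind="gaussian", mean=float(mean), sd=float(sd))

    @classmethod
    def two_point(cls, low: float, high: float, p_low: float) -> "PayoffSpec":
        return cls(kind="two_point", low=float(low), high=float(high), p_low=float(p_low))

    @property
    def expected_value(self) -> float:
        """Exact expectation of the payoff distribution."""
        if self.kind == "constant":
            return float(self.value)
        if self.kind == "gaussian":
            return float(self.mean)
        return float(self.p_low * self.low + (1.0 - self.p_low) * self.high)

    def draw(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Sample payoffs; long-run mean converges to `expected_value`."""
        if self.kind == "constant":
            if size is None:
                return float(self.value)
            return np.full(size, self.value, dtype=float)
        if self.kind == "gaussian":
            return rng.normal(self.mean, self.sd, size=size)
        u = rng.random(size=size)
        return np.where(u < self.p_low, self.low, self.high)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for k in ("value", "mean", "sd", "low", "high", "p_low"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PayoffSpec":
        return cls(**d)


def expected_value(spec: PayoffSpec) -> float:
    """Exact expected payoff of `spec`."""
    return spec.expected_value


def draw_payoff(spec: PayoffSpec, rng: np.random.Generator, size=None):
    """Draw payoff(s) from `spec` using the given generator."""
    return spec.draw(rng, size=size)


@dataclass(frozen=True)
class TaskOption:
    label: str
    spec: PayoffSpec
    risky: bool = False


@dataclass(frozen=True)
class TaskConfig:
    """A multi-armed bandit task.

    `payoff_scale` multiplies realised payoffs before they enter the
    learning model (raw points are still what sessions record); the
    experiment-style tasks use 0.01 so that value estimates are O(1).
    """

    name: str
    options: tuple[TaskOption, ...]
    horizon: int
    payoff_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise ValueError("a task needs at least 2 options")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.payoff_scale <= 0:
            raise ValueError("payoff_scale must be > 0")
        if not any(o.risky for o in self.options):
            raise ValueError("a task needs at least one risky option")
        if not any(not o.risky for o in self.options):
            raise ValueError("a task needs at least one safe option")

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def expected_values(self) -> np.ndarray:
        return np.array([o.spec.expected_value for o in self.options])

    @property
    def risk_premium(self) -> float:
        """max risky EV minus max safe EV (in raw payoff units)."""
        ev = self.expected_values
        risky = np.array([o.risky for o in self.options])
        return float(ev[risky].max() - ev[~risky].max())

    @property
    def risk_premium_sign(self) -> int:
        return int(np.sign(self.risk_premium))

    @property
    def target_risky_index(self) -> int:
        """Index of the highest-EV risky option (the focal option for
        risky-choice proportions)."""
        ev = self.expected_values.copy()
        ev[[not o.risky for o in self.options]] = -np.inf
        return int(np.argmax(ev))

    @property
    def optimal_index(self) -> int:
        return int(np.argmax(self.expected_values))

    def replace(self, **kwargs) -> "TaskConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": self.horizon,
            "payoff_scale": self.payoff_scale,
            "options": [
                {"label": o.label, "risky": o.risky, **o.spec.to_dict()}
                for o in self.options
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        options = []
        for od in d["options"]:
            od = dict(od)
            label = od.pop("label")
            risky = od.pop("risky", False)
            options.append(TaskOption(label=label, spec=PayoffSpec.from_dict(od), risky=risky))
        return cls(
            name=d["name"],
            options=tuple(options),
            horizon=int(d["horizon"]),
            payoff_scale=float(d.get("payoff_scale", 1.0)),
        )


def _safe(points: float) -> PayoffSpec:
    # experimental safe options carry small Gaussian noise, s.d. = 5 points
    return PayoffSpec.gaussian(points, 5.0)


def _presets() -> dict[str, TaskConfig]:
    return {
        "gaussian_2arm": TaskConfig(
            name="gaussian_2arm",
            options=(
                TaskOption("safe", PayoffSpec.constant(1.0), risky=False),
                TaskOption("risky", PayoffSpec.gaussian(1.5, 1.0), risky=True),
            ),
            horizon=150,
            payoff_scale=1.0,
        ),
        "exp_1r1s_pos": TaskConfig(
            name="exp_1r1s_pos",
            options=(
                TaskOption("risky", PayoffSpec.two_point(50.0, 550.0, 0.7), risky=True),
                TaskOption("safe", _safe(150.0), risky=False),
            ),
            horizon=70,
            payoff_scale=0.01,
        ),
        "exp_1r3s_pos": TaskConfig(
            name="exp_1r3s_pos",
            options=(
                TaskOption("risky", PayoffSpec.two_point(50.0, 425.0, 0.6), risky=True),
                TaskOption("safe_150", _safe(150.0), risky=False),
                TaskOption("safe_125", _safe(125.0), risky=False),
                TaskOption("safe_100", _safe(100.0), risky=False),
            ),
            horizon=70,
            payoff_scale=0.01,
        ),
        "exp_2r2s_pos": TaskConfig(
            name="exp_2r2s_pos",
            options=(
                TaskOption("risky_optimal", PayoffSpec.two_point(50.0, 425.0, 0.6), risky=True),
                TaskOption("risky_suboptimal", PayoffSpec.two_point(50.0, 238.0, 0.6), risky=True),
                TaskOption("safe_150", _safe(150.0), risky=False),
                TaskOption("safe_125", _safe(125.0), risky=False),
            ),
            horizon=70,
            payoff_scale=0.01,
        ),
        "exp_1r1s_neg": TaskConfig(
            name="exp_1r1s_neg",
            options=(
                TaskOption("risky", PayoffSpec.two_point(50.0, 220.0, 0.7), risky=True),
                TaskOption("safe", _safe(150.0), risky=False),
            ),
            horizon=70,
            payoff_scale=0.01,
        ),
    }


PRESET_NAMES = tuple(sorted(_presets()))


def make_preset_task(name: str, payoff_scale: float | None = None) -> TaskConfig:
    """Return a preset task configuration by name.

    Valid names: gaussian_2arm, exp_1r1s_pos, exp_1r3s_pos, exp_2r2s_pos,
    exp_1r1s_neg. `payoff_scale` overrides the preset's default scaling of
    payoffs entering the learning model.
    """
    presets = _presets()
    if name not in presets:
        raise ValueError(
            f"unknown task preset {name!r}; valid presets: {', '.join(sorted(presets))}"
        )
    task = presets[name]
    if payoff_scale is not None:
        task = task.replace(payoff_scale=payoff_scale)
    return task
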