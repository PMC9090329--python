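"""Run configuration, seed management, and manifests.

A run config is a YAML/JSON mapping with at least `stage` and `seed`;
stage-specific parameters live in a nested block named after the stage.
A master seed is expanded into named per-stage substreams so that stages
are reproducible independently of each other.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "stage_rng", "stage_seed", "write_manifest"]

STAGES = (
    "simulate",
    "sweep",
    "heterogeneous",
    "horizons",
    "ode",
    "generate",
    "fit",
    "compare",
    "recover",
    "posthoc",
)

log = logging.getLogger("collective_rescue")


@dataclass
class RunConfig:
    stage: str
    seed: int
    outdir: str = "."
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for key in ("stage", "seed"):
            if key not in d:
                raise ValueError(f"config is missing required field {key!r}")
        stage = d["stage"]
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}")
        return cls(
            stage=stage,
            seed=int(d["seed"]),
            outdir=d.get("outdir", "."),
            log_level=d.get("log_level", "INFO"),
            params=d.get(stage, d.get("params", {})),
        )


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        if path.endswith(".json"):
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config at {path} must be a mapping")
    return RunConfig.from_dict(d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    h = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence([int(master_seed), h])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def write_manifest(outdir: str, config: RunConfig, extra: dict | None = None) -> str:
    """Write a manifest (config echo, seed, package version, wall time)
    next to a run's outputs; returns the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "stage": config.stage,
        "seed": config.seed,
        "params": config.params,
        "package_version": __version__,
        "written_at_unix": time.time(),
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(outdir, f"manifest_{config.stage}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
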