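"""Run configuration: schema validation, seeds and resolved-config output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


_VALID_METHODS = ("spectral", "homogeneous")
_VALID_MODELS = ("neuronal", "sis", "ecological")
_VALID_GENERATORS = ("sbm", "hetsbm", "fixture")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of a pipeline run.

    network
        Either ``{"file": path, "format": "dense"|"edgelist"}`` or
        ``{"generator": "sbm"|"hetsbm"|"fixture", "sizes": [...],
        "density": [[...]], ...}`` (``weights`` instead of ``density`` for
        the fixture; ``heterogeneity: {family, params}`` for ``hetsbm``).
    partition
        ``{"file": path}``, ``{"sizes": [...]}`` (contiguous blocks), and
        optionally ``{"refine_to": int}`` applied on top.
    model
        ``{"name": ..., "params": {...}}``.
    sweep
        ``{"k_min", "k_max", "num", "direction", "tol", "t_max", "x0_low",
        "x0_high"}`` — the sigma grid is log-spaced so that the reduced
        system's mean in-degree covers ``[k_min, k_max]``.
    """

    network: dict
    partition: dict
    model: dict
    sweep: dict = field(default_factory=dict)
    methods: tuple = _VALID_METHODS
    epsilon: float | None = None
    seed: int = 0
    outdir: str = "netreduce_out"

    def __post_init__(self) -> None:
        net = self.network
        if ("file" in net) == ("generator" in net):
            raise ConfigError("network needs exactly one of 'file' or 'generator'")
        if "generator" in net and net["generator"] not in _VALID_GENERATORS:
            raise ConfigError(f"unknown generator {net['generator']!r}")
        if "file" in net and net.get("format", "edgelist") not in ("dense", "edgelist"):
            raise ConfigError(f"unknown network format {net.get('format')!r}")
        if not ("file" in self.partition or "sizes" in self.partition):
            raise ConfigError("partition needs 'file' or 'sizes'")
        name = self.model.get("name")
        if name not in _VALID_MODELS:
            raise ConfigError(f"model name must be one of {_VALID_MODELS}, got {name!r}")
        for m in self.methods:
            if m not in _VALID_METHODS:
                raise ConfigError(f"unknown method {m!r}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        sw = self.sweep
        if sw.get("k_min", 1.0) <= 0 or sw.get("k_max", 2.0) <= sw.get("k_min", 1.0):
            raise ConfigError("sweep needs 0 < k_min < k_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def resolved(self) -> dict:
        doc = {
            "network": self.network,
            "partition": self.partition,
            "model": self.model,
            "sweep": self.sweep,
            "methods": list(self.methods),
            "epsilon": self.epsilon,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        doc["config_hash"] = self.digest()
        return doc

    def digest(self) -> str:
        payload = json.dumps(
            {
                k: v
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def spawn_rngs(self, n: int) -> list[np.random.Generator]:
        """Independent per-stage streams fanned out from the global seed.

        Adding stages or replicates never shifts the streams of earlier
        stages.
        """
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]

    def write_resolved(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)
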