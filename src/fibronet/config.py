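"""Validated run configuration and seeded reproducibility.

A :class:`RunConfig` gathers every knob of the pipeline with defaults
matching the standard protocol: 20% of springs injured at csa 5 at
iteration 150 of a 2000-iteration run, fibrosis-bound threshold csa >= 5.
Unknown keys are rejected. A single global seed expands into three
sub-seeds (network, injury, run) through numpy's SeedSequence spawning,
so one integer reproduces an entire experiment.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .agents import ResponseParams, calibrated
from .network import SpatialNetwork, generate_voronoi_network

__all__ = [
    "NetworkConfig",
    "AgentConfig",
    "ProtocolConfig",
    "AnalysisConfig",
    "SeedConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "split_seed",
    "network_from_config",
    "params_from_config",
]

SCHEMA_VERSION = "1"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkConfig(_Strict):
    n_seeds: int = Field(default=120, ge=4)
    domain: tuple[float, float] = (1.0, 1.0)
    pre_stretch: float = Field(default=1.1, gt=0)
    eps_home: float | None = None
    k0: float = Field(default=1.0, gt=0)
    relax_tol: float = Field(default=1e-7, gt=0)
    solver: Literal["minimize", "anneal"] = "minimize"


class AgentConfig(_Strict):
    w1: float = Field(default=1.0, ge=0)
    w2: float = Field(default=1.3, ge=0)
    eps50: float = Field(default=0.06, gt=0)
    n_eps: float = Field(default=4.0, ge=1)
    amp_eps: float = Field(default=1.0, gt=0)
    k50: float = Field(default=5.0, gt=0)
    n_k: float = Field(default=8.0, ge=1)
    amp_k: float = Field(default=1.0, gt=0)
    delta: float = Field(default=0.15, gt=0)
    csa_min: float = Field(default=0.1, gt=0)
    csa_max: float = Field(default=50.0, gt=0)
    agents_per_spring: float = Field(default=0.1, gt=0)


class ProtocolConfig(_Strict):
    injury_kind: Literal["random", "clustered", "none"] = "random"
    fraction: float = Field(default=0.2, ge=0, le=1)
    injured_csa: float = Field(default=5.0, gt=0)
    cluster_size: int = Field(default=30, ge=1)
    injury_iteration: int = Field(default=150, ge=1)
    n_iterations: int = Field(default=2000, ge=0)

    @model_validator(mode="after")
    def _order(self) -> "ProtocolConfig":
        if self.n_iterations and self.injury_iteration >= self.n_iterations:
            raise ValueError("injury_iteration must be < n_iterations")
        return self


class AnalysisConfig(_Strict):
    csa_threshold: float = Field(default=5.0, gt=0)
    ratio_threshold: float = Field(default=1.25, gt=0)
    trend_window: float = Field(default=0.25, gt=0, le=1)
    percolation_grid: list[float] = Field(
        default_factory=lambda: [round(0.60 + 0.02 * i, 2) for i in range(8)]
    )
    percolation_replicates: int = Field(default=200, ge=1)


class SeedConfig(_Strict):
    seed: int = Field(default=0, ge=0)


class RunConfig(_Strict):
    """Complete, schema-validated configuration of one experiment."""

    schema_version: str = SCHEMA_VERSION
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    agents: AgentConfig = Field(default_factory=AgentConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seeds: SeedConfig = Field(default_factory=SeedConfig)


def split_seed(seed: int, n: int = 3) -> tuple[int, ...]:
    """Expand one global seed into ``n`` independent sub-seeds (< 2**31).

    Splitting rule: ``SeedSequence(seed).spawn(n)``, taking one 32-bit
    word from each child modulo 2**31. Documented and stable.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return tuple(int(c.generate_state(1)[0] % 2**31) for c in children)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file; defaults fill gaps.

    An empty file yields the full default (standard-protocol) config.
    Schema violations raise pydantic's ValidationError naming the key.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config as JSON (also valid YAML)."""
    Path(path).write_text(json.dumps(config.model_dump(mode="json"), indent=2))


def network_from_config(config: RunConfig, network_seed: int) -> SpatialNetwork:
    nc = config.network
    return generate_voronoi_network(
        n_seeds=nc.n_seeds,
        domain=nc.domain,
        rng_seed=network_seed,
        pre_stretch=nc.pre_stretch,
        eps_home=nc.eps_home,
        k0=nc.k0,
    )


def params_from_config(config: RunConfig) -> ResponseParams:
    ac = config.agents
    nc = config.network
    eps_home = nc.eps_home if nc.eps_home is not None else nc.pre_stretch - 1.0
    return calibrated(
        ResponseParams(
            w1=ac.w1,
            w2=ac.w2,
            eps50=ac.eps50,
            n_eps=ac.n_eps,
            amp_eps=ac.amp_eps,
            k50=ac.k50,
            n_k=ac.n_k,
            amp_k=ac.amp_k,
            delta=ac.delta,
            csa_min=ac.csa_min,
            csa_max=ac.csa_max,
            eps_home=eps_home,
            k0=nc.k0,
        )
    )
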