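"""Fibroblast agents, Hill-function mechanotransduction, and the simulation loop.

Agents perform random walks on the spring network. Whenever an agent
traverses a spring it evaluates that spring's strain ``eps`` and stiffness
``K`` and computes a total activation

    a = w1 * a_eps(eps) + w2 * a_K(K) - c,

where ``a_eps`` and ``a_K`` are Hill functions and ``c`` is calibrated so
that ``a = 0`` exactly at the homeostatic set point (eps = eps_home,
csa = 1). Positive activation deposits collagen (csa grows), negative
activation digests it (csa shrinks). The strain term is a negative
feedback (high strain -> stiffen -> strain falls) responsible for
self-healing; the stiffness term is a positive feedback (stiff springs
are stiffened further) responsible for irreversible fibrosis. The
stiffness K* at which the positive feedback outweighs the largest
possible strain deficit is the emergent fibrotic threshold.

One simulation iteration = every agent takes a single step across a
spring, then the network is re-solved for mechanical equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .exceptions import ConvergenceError, InvalidStateError
from .injury import InjuryPattern
from .network import SpatialNetwork, relax_network, total_stiffness

__all__ = [
    "ResponseParams",
    "AgentState",
    "Trajectory",
    "hill_response",
    "total_activation",
    "calibrate_c",
    "calibrated",
    "default_params",
    "fibrotic_threshold_stiffness",
    "update_spring_csa",
    "agent_step",
    "run_simulation",
]


@dataclass(frozen=True)
class ResponseParams:
    """Agent response parameters.

    The default values are the package's calibrated reference set (see
    ``scripts/calibrate_params.py``): with them an uninjured network is
    homeostatically stable, while the standard injury protocol (20% of
    springs at csa 5) produces both healed and fibrotic outcomes across
    random-network replicates.

    Attributes
    ----------
    w1, w2 : float
        Weights of the strain and stiffness responses (>= 0). ``w2``
        controls the strength of the profibrotic positive feedback.
    c : float or None
        Homeostatic offset; ``None`` until calibrated (see
        :func:`calibrate_c`).
    eps50, n_eps, amp_eps : float
        Strain Hill function: half-max strain, exponent, amplitude. The
        default half-max sits below the homeostatic strain, so the
        strain response is nearly saturated at the set point: digestion
        under low strain is strong while deposition under excess strain
        is weak and bounded, which lets an injured network return close
        to baseline instead of ratcheting diffusely upward.
    k50, n_k, amp_k : float
        Stiffness Hill function: half-max stiffness (units of k0),
        exponent, amplitude. The steep default keeps the stiffness
        response negligible across the healthy csa range (no spontaneous
        inflation of an uninjured network) and concentrates the
        profibrotic positive feedback just above the injury level.
    delta : float
        Fractional csa change per agent visit: csa <- csa * (1 + delta*a).
    csa_min, csa_max : float
        Clamps on csa: a digestion floor, and a deposition ceiling
        (finite collagen packing) that keeps runaway fibrotic growth
        numerically bounded.
    eps_home : float
        Homeostatic strain set point.
    csa_home, k0 : float
        Homeostatic csa (1 by convention) and unit spring stiffness.
    """

    w1: float = 1.0
    w2: float = 1.3
    c: float | None = None
    eps50: float = 0.06
    n_eps: float = 4.0
    amp_eps: float = 1.0
    k50: float = 5.0
    n_k: float = 8.0
    amp_k: float = 1.0
    delta: float = 0.15
    csa_min: float = 0.1
    csa_max: float = 50.0
    eps_home: float = 0.1
    csa_home: float = 1.0
    k0: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights w1, w2 must be nonnegative")
        if self.n_eps < 1 or self.n_k < 1:
            raise ValueError("Hill exponents must be >= 1")
        if self.eps50 <= 0 or self.k50 <= 0:
            raise ValueError("Hill half-max values must be positive")
        if self.delta <= 0:
            raise ValueError("deposition rate delta must be positive")
        if self.csa_min <= 0:
            raise ValueError("csa_min must be positive")


@dataclass
class AgentState:
    """A fibroblast agent: its position and the last spring it crossed."""

    id: int
    node: int
    last_spring: int | None = None
    activation: float = 0.0


def hill_response(value, half_max: float, exponent: float, amplitude: float = 1.0):
    """Hill function amplitude * v^n / (half_max^n + v^n).

    Negative inputs (transient compressive strain) are clamped to 0, where
    the response is 0. Accepts scalars or arrays; monotone nondecreasing
    and bounded in [0, amplitude).
    """
    if half_max <= 0:
        raise ValueError("half_max must be positive")
    if exponent < 1:
        raise ValueError("exponent must be >= 1")
    v = np.maximum(np.asarray(value, dtype=float), 0.0)
    vn = (v / half_max) ** exponent
    out = amplitude * vn / (1.0 + vn)
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out


def calibrate_c(params: ResponseParams) -> float:
    """Offset making total activation vanish at the homeostatic set point.

    c = w1 * a_eps(eps_home) + w2 * a_K(k0 * csa_home), so that
    ``total_activation(eps_home, k0*csa_home) == 0`` exactly.
    """
    return params.w1 * hill_response(
        params.eps_home, params.eps50, params.n_eps, params.amp_eps
    ) + params.w2 * hill_response(
        params.k0 * params.csa_home, params.k50, params.n_k, params.amp_k
    )


def calibrated(params: ResponseParams) -> ResponseParams:
    """Copy of ``params`` with the homeostatic offset ``c`` filled in."""
    return replace(params, c=calibrate_c(params))


def default_params() -> ResponseParams:
    """The calibrated reference parameter set."""
    return calibrated(ResponseParams())


def total_activation(eps, K, params: ResponseParams):
    """Total agent activation a = w1*a_eps(eps) + w2*a_K(K) - c.

    Sign convention: a > 0 deposits collagen, a < 0 digests it.
    Requires calibrated params (``c`` set).
    """
    if params.c is None:
        raise InvalidStateError(
            "ResponseParams.c is not calibrated; call calibrate_c/calibrated first"
        )
    a_eps = hill_response(eps, params.eps50, params.n_eps, params.amp_eps)
    a_k = hill_response(K, params.k50, params.n_k, params.amp_k)
    return params.w1 * a_eps + params.w2 * a_k - params.c


def fibrotic_threshold_stiffness(params: ResponseParams, k_max: float = 1e6) -> float | None:
    """Stiffness K* above which a spring deposits even at zero strain.

    Solves ``w2 * (a_K(K*) - a_K(k0)) = w1 * a_eps(eps_home)`` for K*.
    Springs stiffer than K* are locked into the fibrotic positive feedback
    loop regardless of strain. Returns ``None`` when the positive feedback
    can never outweigh the strain deficit (pure-healing regime).
    """
    from scipy.optimize import brentq

    p = calibrated(params)

    def f(k: float) -> float:
        return float(total_activation(0.0, k, p))

    if f(k_max) <= 0:
        return None
    if f(p.k0 * p.csa_home) >= 0:
        return p.k0 * p.csa_home
    return float(brentq(f, p.k0 * p.csa_home, k_max, xtol=1e-10))


def update_spring_csa(csa, a, params: ResponseParams):
    """Multiplicative csa update csa * (1 + delta*a), clamped to [csa_min, csa_max].

    Works on scalars or arrays; raises if the result is not finite.
    """
    new = np.asarray(csa, dtype=float) * (1.0 + params.delta * np.asarray(a, dtype=float))
    new = np.clip(new, params.csa_min, params.csa_max)
    if not np.all(np.isfinite(new)):
        raise InvalidStateError("csa update produced a non-finite value")
    return float(new) if np.ndim(csa) == 0 else new


def agent_step(
    agent: AgentState,
    network: SpatialNetwork,
    params: ResponseParams,
    rng: np.random.Generator,
    incident: list[np.ndarray] | None = None,
) -> AgentState:
    """One agent step: traverse a uniformly chosen incident spring.

    The agent evaluates (eps, K) on the chosen spring, updates that
    spring's csa in place on ``network``, and moves to the opposite node.
    """
    inc = incident if incident is not None else network.incident_springs()
    choices = inc[agent.node]
    if choices.size == 0:
        raise InvalidStateError(f"agent {agent.id} sits on an isolated node")
    j = int(choices[rng.integers(choices.size)])
    a_node, b_node = int(network.edges[j, 0]), int(network.edges[j, 1])
    d = network.positions[b_node] - network.positions[a_node]
    length = math.hypot(d[0], d[1])
    eps = (length - network.rest_length[j]) / network.rest_length[j]
    a = float(total_activation(eps, network.k0 * network.csa[j], params))
    network.csa[j] = update_spring_csa(float(network.csa[j]), a, params)
    agent.node = b_node if agent.node == a_node else a_node
    agent.last_spring = j
    agent.activation = a
    return agent


# ----------------------------------------------------------------------
# Simulation driver


@dataclass
class Trajectory:
    """Record of one simulated injury-and-remodeling run.

    ``snapshots[t]`` holds the per-spring csa array at iteration ``t``;
    the injury-iteration snapshot is taken immediately after the injury is
    imposed (before any agent steps that iteration), so injured springs
    show exactly their assigned csa there. ``position_snapshots`` stores
    node coordinates at the same iterations. ``network`` is the final
    state.
    """

    iterations: np.ndarray
    total_stiffness: np.ndarray
    snapshots: dict[int, np.ndarray]
    position_snapshots: dict[int, np.ndarray]
    network: SpatialNetwork
    injury: InjuryPattern | None = None
    injury_iteration: int | None = None
    manifest: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def baseline_stiffness(self) -> float:
        """Stiffness of the homogeneous (all csa = 1) network: N * k0."""
        return self.network.n_springs * self.network.k0

    @property
    def final_csa(self) -> np.ndarray:
        if not self.snapshots:
            raise InvalidStateError("trajectory has no snapshots")
        return self.snapshots[max(self.snapshots)]

    @property
    def injured_ids(self) -> frozenset[int]:
        return frozenset(self.injury.assignments) if self.injury is not None else frozenset()


def run_simulation(
    network: SpatialNetwork,
    injury: InjuryPattern | None,
    n_iterations: int = 2000,
    injury_iteration: int = 150,
    params: ResponseParams | None = None,
    rng_seed: int | np.random.SeedSequence | None = 0,
    n_agents: int | None = None,
    snapshot_iterations: Iterable[int] | None = None,
    relax_tol: float = 1e-7,
    relax_method: str = "minimize",
) -> Trajectory:
    """Run the agent-based remodeling simulation.

    Protocol: the network evolves under agent remodeling from iteration 1;
    at ``injury_iteration`` the injury pattern's csa assignments are
    imposed and the network re-equilibrated (the standard protocol injures
    at iteration 150 of a 2000-iteration run, leaving a pre-injury phase
    that equilibrates homeostasis). Each iteration, every agent steps
    across one spring and the network is then relaxed to equilibrium.

    ``n_agents`` defaults to one agent per 10 springs (at least 1).
    Snapshots are always taken at the injury iteration (post-injury,
    pre-step) and at the final iteration. The run is fully reproducible
    from its seeds; identical seeds give bit-identical trajectories.
    """
    if params is None:
        params = default_params()
    if params.c is None:
        params = calibrated(params)
    if injury is not None and len(injury.assignments) > 0:
        if injury_iteration >= n_iterations and n_iterations > 0:
            raise ValueError("injury_iteration must be < n_iterations")
        bad = [j for j in injury.assignments if j < 0 or j >= network.n_springs]
        if bad:
            raise ValueError(f"injury refers to unknown spring ids {bad[:5]}")

    net = network.copy()
    rng = np.random.default_rng(rng_seed)
    manifest = {
        "rng_seed": repr(rng_seed),
        "n_iterations": int(n_iterations),
        "injury_iteration": int(injury_iteration),
        "params": {k: v for k, v in params.__dict__.items()},
        "relax_tol": relax_tol,
        "relax_method": relax_method,
        "network_meta": dict(net.meta),
    }

    if n_iterations == 0:
        return Trajectory(
            iterations=np.zeros(0, dtype=int),
            total_stiffness=np.zeros(0),
            snapshots={},
            position_snapshots={},
            network=net,
            injury=injury,
            injury_iteration=None,
            manifest=manifest,
        )

    if n_agents is None:
        n_agents = max(1, net.n_springs // 10)
    incident = net.incident_springs()
    agents = [
        AgentState(i, int(node))
        for i, node in enumerate(rng.integers(net.n_nodes, size=n_agents))
    ]
    manifest["n_agents"] = n_agents

    wanted = set(int(t) for t in snapshot_iterations) if snapshot_iterations else set()
    wanted.add(int(n_iterations))

    relax_network(net, tol=relax_tol, method=relax_method, in_place=True)

    stiffness_trace = np.empty(n_iterations)
    snapshots: dict[int, np.ndarray] = {}
    position_snapshots: dict[int, np.ndarray] = {}
    error: str | None = None
    t_done = 0
    apply_injury = injury is not None and len(injury.assignments) > 0

    for t in range(1, n_iterations + 1):
        try:
            if apply_injury and t == injury_iteration:
                for j, value in injury.assignments.items():
                    net.csa[j] = float(value)
                relax_network(net, tol=relax_tol, method=relax_method, in_place=True)
                snapshots[t] = net.csa.copy()
                position_snapshots[t] = net.positions.copy()
            for agent in agents:
                agent_step(agent, net, params, rng, incident)
            relax_network(net, tol=relax_tol, method=relax_method, in_place=True)
        except ConvergenceError as err:
            error = f"relaxation failed at iteration {t}: {err}"
            break
        stiffness_trace[t - 1] = total_stiffness(net)
        t_done = t
        if t in wanted and t not in snapshots:
            snapshots[t] = net.csa.copy()
            position_snapshots[t] = net.positions.copy()

    iterations = np.arange(1, t_done + 1)
    return Trajectory(
        iterations=iterations,
        total_stiffness=stiffness_trace[:t_done].copy(),
        snapshots=snapshots,
        position_snapshots=position_snapshots,
        network=net,
        injury=injury,
        injury_iteration=int(injury_iteration) if apply_injury else None,
        manifest=manifest,
        error=error,
    )
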