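"""Synthetic initial-injury generators and small hand-built fixture networks.

An injury mimics the tissue response to an insult (e.g. local
inflammation) by raising the cross-sectional area of a set of springs
from the homeostatic value 1 to an injured value (5 by default) at the
injury iteration. Two protocols are provided: a uniform random selection
of a fixed fraction of springs (20% by default), and a single connected
cluster grown by breadth-first accretion. A third operation derives a
modified pattern from an existing one by changing exactly one spring's
assigned csa -- the building block of single-spring "hotspot" sweeps.
"Removing" a spring is expressed as modifying it down to the csa floor
rather than deleting it, which preserves mesh validity.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import SpatialNetwork

__all__ = [
    "InjuryPattern",
    "random_injury",
    "clustered_injury",
    "modify_spring",
    "fixture_networks",
    "bifurcation_fixture",
    "spring_adjacency",
]


@dataclass(frozen=True)
class InjuryPattern:
    """A set of springs to injure and the csa value assigned to each.

    ``provenance`` records (base pattern kind, modified spring id,
    modified value) for patterns of kind ``"modified"``.
    """

    assignments: Mapping[int, float]
    kind: str = "random"
    rng_seed: object = None
    provenance: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        if any(v <= 0 for v in self.assignments.values()):
            raise ValueError("assigned csa values must be positive")
        if self.kind not in {"random", "clustered", "modified", "custom"}:
            raise ValueError(f"unknown injury kind {self.kind!r}")

    @property
    def spring_ids(self) -> frozenset[int]:
        return frozenset(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "seed": repr(self.rng_seed),
                "assignments": sorted(
                    [int(k), float(v)] for k, v in self.assignments.items()
                ),
                "provenance": list(self.provenance) if self.provenance else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "InjuryPattern":
        obj = json.loads(text)
        return cls(
            assignments={int(k): float(v) for k, v in obj["assignments"]},
            kind=obj["kind"],
            rng_seed=obj.get("seed"),
            provenance=tuple(obj["provenance"]) if obj.get("provenance") else None,
        )


def random_injury(
    network: SpatialNetwork,
    fraction: float = 0.2,
    injured_csa: float = 5.0,
    rng_seed: int | np.random.SeedSequence | None = 0,
) -> InjuryPattern:
    """Injure round(fraction * N) springs chosen uniformly without replacement.

    Rounding is round-half-even for cross-platform determinism. The
    default protocol injures 20% of springs at csa 5.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if injured_csa <= 0:
        raise ValueError("injured_csa must be positive")
    n = network.n_springs
    count = round(fraction * n)
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(n, size=count, replace=False) if count else np.empty(0, int)
    return InjuryPattern(
        assignments={int(j): float(injured_csa) for j in chosen},
        kind="random",
        rng_seed=rng_seed,
    )


def spring_adjacency(network: SpatialNetwork) -> list[set[int]]:
    """For each spring, the ids of springs sharing at least one node with it."""
    incident = network.incident_springs()
    adj: list[set[int]] = [set() for _ in range(network.n_springs)]
    for springs_here in incident:
        ids = springs_here.tolist()
        for j in ids:
            adj[j].update(ids)
    for j in range(network.n_springs):
        adj[j].discard(j)
    return adj


def clustered_injury(
    network: SpatialNetwork,
    n_springs: int,
    seed_spring: int | None = None,
    injured_csa: float = 5.0,
    rng_seed: int | np.random.SeedSequence | None = 0,
) -> InjuryPattern:
    """Grow a single connected injured cluster of exactly ``n_springs`` springs.

    Growth is breadth-first accretion from ``seed_spring`` (chosen by the
    seeded rng when omitted), with frontier springs visited in ascending
    spring id for reproducibility. The injured set always forms one
    connected component under shared-node adjacency.
    """
    if not 1 <= n_springs <= network.n_springs:
        raise ValueError(
            f"n_springs must be in [1, {network.n_springs}], got {n_springs}"
        )
    rng = np.random.default_rng(rng_seed)
    if seed_spring is None:
        seed_spring = int(rng.integers(network.n_springs))
    if not 0 <= seed_spring < network.n_springs:
        raise ValueError(f"seed_spring {seed_spring} not in network")
    adj = spring_adjacency(network)
    chosen: set[int] = {seed_spring}
    queue: deque[int] = deque([seed_spring])
    while queue and len(chosen) < n_springs:
        current = queue.popleft()
        for nb in sorted(adj[current]):
            if nb not in chosen:
                chosen.add(nb)
                queue.append(nb)
                if len(chosen) == n_springs:
                    break
    if len(chosen) < n_springs:
        raise ValueError(
            "network component containing seed_spring is smaller than n_springs"
        )
    return InjuryPattern(
        assignments={int(j): float(injured_csa) for j in sorted(chosen)},
        kind="clustered",
        rng_seed=rng_seed,
    )


def modify_spring(
    pattern: InjuryPattern, spring_id: int, new_csa: float
) -> InjuryPattern:
    """Copy of ``pattern`` with exactly one assignment changed.

    The original pattern is left untouched; provenance records the edit.
    Used for hotspot sweeps (csa between 1 and 5) and for "manual healing"
    of a spring at the time of injury (new_csa = 1).
    """
    if spring_id not in pattern.assignments:
        raise ValueError(f"spring {spring_id} is not in the injury pattern")
    if new_csa <= 0:
        raise ValueError("new_csa must be positive")
    assignments = dict(pattern.assignments)
    assignments[spring_id] = float(new_csa)
    return InjuryPattern(
        assignments=assignments,
        kind="modified",
        rng_seed=pattern.rng_seed,
        provenance=(pattern.kind, int(spring_id), float(new_csa)),
    )


# ----------------------------------------------------------------------
# Hand-built fixtures


def _build(positions, edges, boundary, eps_home: float = 0.0) -> SpatialNetwork:
    positions = np.asarray(positions, dtype=float)
    edges = np.asarray(edges, dtype=np.int64)
    is_boundary = np.zeros(len(positions), dtype=bool)
    is_boundary[list(boundary)] = True
    net = SpatialNetwork(
        positions=positions,
        edges=edges,
        rest_length=np.ones(len(edges)),
        csa=np.ones(len(edges)),
        is_boundary=is_boundary,
        domain=(
            float(positions[:, 0].max() - positions[:, 0].min()) or 1.0,
            float(positions[:, 1].max() - positions[:, 1].min()) or 1.0,
        ),
    )
    net.rest_length = net.lengths() / (1.0 + eps_home)
    return net


def bifurcation_fixture(
    gap: float = 3.0,
    radius: float = 1.0,
    pre_stretch: float = 1.1,
    blob_csa: float = 3.0,
    chain_csa: float = 2.0,
    hotspot_csa: float = 5.0,
) -> tuple[SpatialNetwork, InjuryPattern, int]:
    """Engineered two-cluster-plus-bridge network with a single hotspot.

    Two triangulated hexagonal blobs (center + 6-ring, 12 springs each)
    are joined by a 3-spring chain across a gap; only the two far-side
    ring vertices of each blob are pinned, so both blobs can relax
    toward each other. The injury stiffens every blob spring to
    ``blob_csa`` (marginal: below the fibrotic lock threshold) and the
    chain to ``chain_csa``, with the middle chain spring -- the hotspot,
    carrying the tension between the two stiff clusters in series --
    assigned ``hotspot_csa``.

    The hotspot's initial csa decides the race between blob digestion
    and chain lock-in: low values let both clusters heal, high values
    stiffen the bridge's series partners and tip the whole assembly into
    irreversible fibrosis. Returns (network, injury, hotspot spring id).
    """
    nodes: list[tuple[float, float]] = []
    edges: list[tuple[int, int]] = []
    pinned: list[int] = []

    def blob(cx: float, tip_angle: float, pin_angles: tuple[float, float]) -> int:
        base = len(nodes)
        nodes.append((cx, 0.0))
        ring = []
        for k in range(6):
            ang = np.deg2rad(tip_angle + 60.0 * k)
            nodes.append((cx + radius * np.cos(ang), radius * np.sin(ang)))
            ring.append(base + 1 + k)
        for k in range(6):
            edges.append((base, ring[k]))
            edges.append((ring[k], ring[(k + 1) % 6]))
        for ang in pin_angles:
            k = int(((ang - tip_angle) % 360.0) // 60)
            pinned.append(ring[k])
        return ring[0]  # the tip vertex facing the gap

    left_tip = blob(-(gap / 2 + radius), 0.0, (120.0, 240.0))
    right_tip = blob(+(gap / 2 + radius), 180.0, (300.0, 60.0))
    prev = left_tip
    chain: list[int] = []
    for i in range(1, 3):
        nodes.append((-gap / 2 + gap * i / 3.0, 0.0))
        edges.append((prev, len(nodes) - 1))
        chain.append(len(edges) - 1)
        prev = len(nodes) - 1
    edges.append((prev, right_tip))
    chain.append(len(edges) - 1)

    positions = np.asarray(nodes, dtype=float) * pre_stretch
    is_boundary = np.zeros(len(nodes), dtype=bool)
    is_boundary[pinned] = True
    net = SpatialNetwork(
        positions=positions,
        edges=np.asarray(edges, dtype=np.int64),
        rest_length=np.ones(len(edges)),
        csa=np.ones(len(edges)),
        is_boundary=is_boundary,
        domain=(gap + 4 * radius, 2 * radius),
        meta={"fixture": "bifurcation"},
    )
    net.rest_length = net.lengths() / pre_stretch

    hotspot = chain[1]
    assignments = {j: float(blob_csa) for j in range(len(edges)) if j not in chain}
    for cj in chain:
        assignments[cj] = float(chain_csa)
    assignments[hotspot] = float(hotspot_csa)
    return net, InjuryPattern(assignments=assignments, kind="custom"), hotspot


def fixture_networks() -> dict[str, SpatialNetwork]:
    """Small exactly-specified networks for oracle tests.

    - ``star``: one hub node with 4 leaves (hub degree 4).
    - ``two_triangle``: two triangles sharing a central node; contains
      cycles, so a second-generation candidate can be reachable both
      through an injured and an uninjured first-generation spring.
    - ``chain``: five collinear springs in series; the minimal layout in
      which a generation-2 spring is blocked by an uninjured
      generation-1 intermediate.
    - ``dumbbell``: two triangles whose nearest nodes are 3.0 apart,
      joined by one bridge spring; injuring both lobes (not the bridge)
      yields exactly 2 clusters with intercluster gap 3.0.
    - ``bridged_blobs``: the network of :func:`bifurcation_fixture`.
    """
    catalog: dict[str, SpatialNetwork] = {}

    catalog["star"] = _build(
        positions=[(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)],
        edges=[(0, 1), (0, 2), (0, 3), (0, 4)],
        boundary=[1, 2, 3, 4],
    )

    catalog["two_triangle"] = _build(
        positions=[
            (0.0, 0.0),  # shared center
            (-1.0, 0.5),
            (-1.0, -0.5),
            (1.0, 0.5),
            (1.0, -0.5),
        ],
        edges=[(0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (3, 4)],
        boundary=[1, 2, 3, 4],
    )

    catalog["chain"] = _build(
        positions=[(float(i), 0.0) for i in range(6)],
        edges=[(i, i + 1) for i in range(5)],
        boundary=[0, 5],
    )

    catalog["bridged_blobs"] = bifurcation_fixture()[0]

    catalog["dumbbell"] = _build(
        positions=[
            (0.0, 0.0),
            (1.0, 0.0),
            (0.5, 0.8),  # left triangle
            (4.0, 0.0),
            (5.0, 0.0),
            (4.5, 0.8),  # right triangle
        ],
        edges=[(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (1, 3)],
        boundary=[0, 2, 4, 5],
    )

    return catalog
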