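"""Serialization: networks (GraphML + CSV), injuries (JSON), runs (CSV/JSON).

All formats are plain text and round-trip losslessly: floats are written
with 17 significant digits, enough to reconstruct any IEEE-754 double
exactly. A saved run directory contains a manifest sufficient to replay
the simulation bit-exactly with the deterministic solver.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .agents import ResponseParams, Trajectory, run_simulation
from .injury import InjuryPattern
from .network import SpatialNetwork

__all__ = [
    "save_network_graphml",
    "load_network_graphml",
    "save_network_csv",
    "load_network_csv",
    "save_injury",
    "load_injury",
    "save_run",
    "load_run",
    "replay_run",
]

_FLOAT = "%.17g"


# ----------------------------------------------------------------------
# Networks


def _to_graph(network: SpatialNetwork) -> nx.Graph:
    g = nx.Graph()
    g.graph["k0"] = float(network.k0)
    g.graph["domain_w"] = float(network.domain[0])
    g.graph["domain_h"] = float(network.domain[1])
    for i in range(network.n_nodes):
        g.add_node(
            i,
            x=float(network.positions[i, 0]),
            y=float(network.positions[i, 1]),
            is_boundary=bool(network.is_boundary[i]),
        )
    for j, (a, b) in enumerate(network.edges):
        g.add_edge(
            int(a),
            int(b),
            spring_id=int(j),
            L0=float(network.rest_length[j]),
            csa=float(network.csa[j]),
        )
    return g


def _from_graph(g: nx.Graph) -> SpatialNetwork:
    n = g.number_of_nodes()
    positions = np.zeros((n, 2))
    is_boundary = np.zeros(n, dtype=bool)
    for i, data in g.nodes(data=True):
        i = int(i)
        positions[i] = (float(data["x"]), float(data["y"]))
        is_boundary[i] = bool(data["is_boundary"])
    m = g.number_of_edges()
    edges = np.zeros((m, 2), dtype=np.int64)
    rest = np.zeros(m)
    csa = np.zeros(m)
    for a, b, data in g.edges(data=True):
        j = int(data["spring_id"])
        edges[j] = (int(a), int(b))
        rest[j] = float(data["L0"])
        csa[j] = float(data["csa"])
    return SpatialNetwork(
        positions=positions,
        edges=edges,
        rest_length=rest,
        csa=csa,
        is_boundary=is_boundary,
        k0=float(g.graph.get("k0", 1.0)),
        domain=(float(g.graph.get("domain_w", 1.0)), float(g.graph.get("domain_h", 1.0))),
    )


def save_network_graphml(network: SpatialNetwork, path: str | Path) -> None:
    nx.write_graphml(_to_graph(network), str(path))


def load_network_graphml(path: str | Path) -> SpatialNetwork:
    return _from_graph(nx.read_graphml(str(path), node_type=int))


def save_network_csv(network: SpatialNetwork, directory: str | Path) -> None:
    """Write nodes.csv (id, x, y, is_boundary) and springs.csv (id, a, b, L0, csa)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(network.n_nodes),
            "x": network.positions[:, 0],
            "y": network.positions[:, 1],
            "is_boundary": network.is_boundary.astype(int),
        }
    )
    springs = pd.DataFrame(
        {
            "id": np.arange(network.n_springs),
            "node_a": network.edges[:, 0],
            "node_b": network.edges[:, 1],
            "L0": network.rest_length,
            "csa": network.csa,
        }
    )
    nodes.to_csv(directory / "nodes.csv", index=False, float_format=_FLOAT)
    springs.to_csv(directory / "springs.csv", index=False, float_format=_FLOAT)
    meta = {"k0": network.k0, "domain": list(network.domain)}
    (directory / "network_meta.json").write_text(json.dumps(meta))


def load_network_csv(directory: str | Path) -> SpatialNetwork:
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.csv", float_precision="round_trip")
    springs = pd.read_csv(directory / "springs.csv", float_precision="round_trip")
    meta_path = directory / "network_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    nodes = nodes.sort_values("id")
    springs = springs.sort_values("id")
    return SpatialNetwork(
        positions=nodes[["x", "y"]].to_numpy(),
        edges=springs[["node_a", "node_b"]].to_numpy(dtype=np.int64),
        rest_length=springs["L0"].to_numpy(),
        csa=springs["csa"].to_numpy(),
        is_boundary=nodes["is_boundary"].to_numpy().astype(bool),
        k0=float(meta.get("k0", 1.0)),
        domain=tuple(meta.get("domain", (1.0, 1.0))),
    )


# ----------------------------------------------------------------------
# Injuries


def save_injury(pattern: InjuryPattern, path: str | Path) -> None:
    Path(path).write_text(pattern.to_json())


def load_injury(path: str | Path) -> InjuryPattern:
    return InjuryPattern.from_json(Path(path).read_text())


# ----------------------------------------------------------------------
# Runs


def save_run(trajectory: Trajectory, directory: str | Path) -> None:
    """Write a run directory: manifest, stiffness trace, snapshots, injury, network."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = dict(trajectory.manifest)
    manifest["injury_iteration"] = trajectory.injury_iteration
    manifest["error"] = trajectory.error
    manifest["snapshot_iterations"] = sorted(int(t) for t in trajectory.snapshots)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    pd.DataFrame(
        {
            "iteration": trajectory.iterations,
            "total_stiffness": trajectory.total_stiffness,
        }
    ).to_csv(directory / "trajectory.csv", index=False, float_format=_FLOAT)

    snap_rows = []
    for t in sorted(trajectory.snapshots):
        csa = trajectory.snapshots[t]
        snap_rows.append(
            pd.DataFrame(
                {
                    "iteration": t,
                    "spring_id": np.arange(csa.size),
                    "csa": csa,
                }
            )
        )
    if snap_rows:
        pd.concat(snap_rows).to_csv(
            directory / "snapshots.csv", index=False, float_format=_FLOAT
        )
    pos_rows = []
    for t in sorted(trajectory.position_snapshots):
        pos = trajectory.position_snapshots[t]
        pos_rows.append(
            pd.DataFrame(
                {
                    "iteration": t,
                    "node_id": np.arange(pos.shape[0]),
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
        )
    if pos_rows:
        pd.concat(pos_rows).to_csv(
            directory / "positions.csv", index=False, float_format=_FLOAT
        )

    if trajectory.injury is not None:
        save_injury(trajectory.injury, directory / "injury.json")
    save_network_graphml(trajectory.network, directory / "network_final.graphml")


def load_run(directory: str | Path) -> Trajectory:
    """Reconstruct a Trajectory from a run directory written by save_run."""
    directory = Path(directory)
    for required in ("manifest.json", "trajectory.csv"):
        if not (directory / required).exists():
            raise FileNotFoundError(f"run directory is missing {required}")
    manifest = json.loads((directory / "manifest.json").read_text())
    trace = pd.read_csv(directory / "trajectory.csv", float_precision="round_trip")

    snapshots: dict[int, np.ndarray] = {}
    snap_path = directory / "snapshots.csv"
    if manifest.get("snapshot_iterations") and not snap_path.exists():
        raise FileNotFoundError("run directory is missing snapshots.csv")
    if snap_path.exists():
        snaps = pd.read_csv(snap_path, float_precision="round_trip")
        for t, group in snaps.groupby("iteration"):
            snapshots[int(t)] = (
                group.sort_values("spring_id")["csa"].to_numpy()
            )
    position_snapshots: dict[int, np.ndarray] = {}
    pos_path = directory / "positions.csv"
    if pos_path.exists():
        pos = pd.read_csv(pos_path, float_precision="round_trip")
        for t, group in pos.groupby("iteration"):
            position_snapshots[int(t)] = (
                group.sort_values("node_id")[["x", "y"]].to_numpy()
            )

    injury = None
    if (directory / "injury.json").exists():
        injury = load_injury(directory / "injury.json")
    network = load_network_graphml(directory / "network_final.graphml")

    return Trajectory(
        iterations=trace["iteration"].to_numpy(dtype=int),
        total_stiffness=trace["total_stiffness"].to_numpy(),
        snapshots=snapshots,
        position_snapshots=position_snapshots,
        network=network,
        injury=injury,
        injury_iteration=manifest.get("injury_iteration"),
        manifest=manifest,
        error=manifest.get("error"),
    )


def replay_run(
    network: SpatialNetwork, manifest: dict, injury: InjuryPattern | None
) -> Trajectory:
    """Re-run a simulation from its manifest; bit-identical to the original."""
    params = ResponseParams(**manifest["params"])
    seed_repr = manifest["rng_seed"]
    seed = int(seed_repr) if str(seed_repr).lstrip("-").isdigit() else None
    if seed is None:
        raise ValueError(f"manifest rng_seed {seed_repr!r} is not replayable")
    return run_simulation(
        network,
        injury,
        n_iterations=manifest["n_iterations"],
        injury_iteration=manifest["injury_iteration"] or 150,
        params=params,
        rng_seed=seed,
        n_agents=manifest.get("n_agents"),
        snapshot_iterations=manifest.get("snapshot_iterations"),
        relax_tol=manifest.get("relax_tol", 1e-7),
        relax_method=manifest.get("relax_method", "minimize"),
    )
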