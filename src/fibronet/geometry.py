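"""Geometric structure of an initial injury.

Four quantities characterize how injured springs are arranged:

- a generation-limited clustering coefficient (CC) per spring: the number
  of injured springs within two spring-adjacency generations of a focal
  spring, where two springs are adjacent iff they share a node. The focal
  spring is generation 0 (it counts toward its own CC iff injured);
  injured springs adjacent to it are generation 1; injured springs
  adjacent to an *injured* generation-1 spring are generation 2. In
  looped topologies a candidate reachable only through uninjured
  intermediates therefore does not count. With a spring and two of its
  neighbors within two generations injured, CC = 3.
- connected injured clusters: components of the subgraph induced by
  injured springs (shared-node adjacency);
- per-cluster maximum diameter: the largest Euclidean distance between
  any two nodes of a cluster;
- minimum intercluster distances: for each cluster pair, the smallest
  Euclidean distance between a node of one and a node of the other.

High CC, large diameters and short intercluster gaps mark injuries that
are close to forming a percolating stiff cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist

from .injury import spring_adjacency
from .network import SpatialNetwork

__all__ = [
    "ClusterSet",
    "GeometryReport",
    "clustering_coefficient",
    "clustering_coefficients",
    "find_injury_clusters",
    "max_cluster_diameter",
    "min_intercluster_distances",
    "geometry_report",
]


@dataclass(frozen=True)
class ClusterSet:
    """Partition of an injured spring set into connected clusters.

    Clusters are numbered 0, 1, ... in ascending order of their smallest
    member spring id. ``clusters[i] = (cluster_id, spring ids, node ids)``.
    """

    clusters: tuple[tuple[int, frozenset[int], frozenset[int]], ...]
    iteration: int | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(s) for _, s, _ in self.clusters]

    def spring_sets(self) -> list[frozenset[int]]:
        return [s for _, s, _ in self.clusters]

    def node_sets(self) -> list[frozenset[int]]:
        return [n for _, _, n in self.clusters]


@dataclass(frozen=True)
class GeometryReport:
    """All geometry metrics of one injury configuration."""

    cc: Mapping[int, int]
    cluster_set: ClusterSet
    max_diameter: Mapping[int, float]
    min_intercluster_distance: Mapping[frozenset[int], float]

    def min_distance_per_cluster(self) -> dict[int, float]:
        """Each cluster's distance to its nearest other cluster.

        This per-cluster summary feeds the healed-vs-fibrotic distance
        distributions; empty when there is a single cluster.
        """
        out: dict[int, float] = {}
        for pair, d in self.min_intercluster_distance.items():
            for cid in pair:
                out[cid] = min(out.get(cid, np.inf), d)
        return out


def clustering_coefficient(
    network: SpatialNetwork,
    injured: Iterable[int],
    spring_id: int,
    adjacency: list[set[int]] | None = None,
) -> int:
    """Generation-limited clustering coefficient of one spring.

    Counts distinct injured springs in generations 0-2 of ``spring_id``
    under the rule described in the module docstring.
    """
    if not 0 <= spring_id < network.n_springs:
        raise ValueError(f"unknown spring id {spring_id}")
    injured_set = set(injured)
    adj = adjacency if adjacency is not None else spring_adjacency(network)

    counted: set[int] = set()
    if spring_id in injured_set:
        counted.add(spring_id)
    gen1 = {j for j in adj[spring_id] if j in injured_set}
    counted |= gen1
    for g1 in gen1:  # generation 2 must connect through an injured gen-1 spring
        for j in adj[g1]:
            if j in injured_set and j != spring_id:
                counted.add(j)
    return len(counted)


def clustering_coefficients(
    network: SpatialNetwork,
    injured: Iterable[int],
    spring_ids: Iterable[int] | None = None,
) -> dict[int, int]:
    """CC of every requested spring (all springs by default)."""
    adj = spring_adjacency(network)
    ids = range(network.n_springs) if spring_ids is None else spring_ids
    injured_set = set(injured)
    return {
        int(j): clustering_coefficient(network, injured_set, int(j), adjacency=adj)
        for j in ids
    }


def find_injury_clusters(
    network: SpatialNetwork,
    injured: Iterable[int],
    iteration: int | None = None,
) -> ClusterSet:
    """Connected components of the injured-spring subgraph.

    Two injured springs belong to the same cluster iff they are linked by
    a chain of injured springs sharing nodes (equivalently: components of
    the node graph restricted to injured springs).
    """
    injured_ids = sorted(set(int(j) for j in injured))
    if any(j < 0 or j >= network.n_springs for j in injured_ids):
        raise ValueError("injured set contains unknown spring ids")
    if not injured_ids:
        return ClusterSet(clusters=(), iteration=iteration)

    edges = network.edges[injured_ids]
    n = network.n_nodes
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)

    by_label: dict[int, tuple[set[int], set[int]]] = {}
    for j, (a, b) in zip(injured_ids, edges):
        lab = int(labels[a])
        springs, nodes = by_label.setdefault(lab, (set(), set()))
        springs.add(int(j))
        nodes.update((int(a), int(b)))
    ordered = sorted(by_label.values(), key=lambda sn: min(sn[0]))
    clusters = tuple(
        (cid, frozenset(springs), frozenset(nodes))
        for cid, (springs, nodes) in enumerate(ordered)
    )
    # injured clusters never share a node: a shared node would merge them
    all_nodes = [n for _, _, ns in clusters for n in ns]
    assert len(all_nodes) == len(set(all_nodes))
    return ClusterSet(clusters=clusters, iteration=iteration)


def max_cluster_diameter(
    cluster_nodes: Iterable[int], positions: np.ndarray
) -> float:
    """Largest Euclidean distance between any two nodes of a cluster."""
    ids = sorted(set(int(i) for i in cluster_nodes))
    if not ids:
        raise ValueError("cluster is empty")
    pts = positions[ids]
    if len(ids) == 1:
        return 0.0
    return float(pdist(pts).max())


def min_intercluster_distances(
    cluster_set: ClusterSet, positions: np.ndarray
) -> dict[frozenset[int], float]:
    """Minimum node-to-node Euclidean distance for every cluster pair.

    Returns a symmetric mapping keyed by frozenset({id_a, id_b}); empty
    when there are fewer than two clusters.
    """
    if len(cluster_set) < 1:
        raise ValueError("need at least one cluster")
    node_sets = [(cid, sorted(nodes)) for cid, _, nodes in cluster_set.clusters]
    out: dict[frozenset[int], float] = {}
    for i in range(len(node_sets)):
        cid_i, nodes_i = node_sets[i]
        for k in range(i + 1, len(node_sets)):
            cid_k, nodes_k = node_sets[k]
            d = cdist(positions[nodes_i], positions[nodes_k]).min()
            out[frozenset((cid_i, cid_k))] = float(d)
    return out


def geometry_report(
    network: SpatialNetwork,
    injured: Iterable[int],
    positions: np.ndarray | None = None,
    iteration: int | None = None,
) -> GeometryReport:
    """Full geometry characterization of an injured configuration.

    ``positions`` defaults to the network's current node coordinates;
    pass a stored snapshot to evaluate the geometry at the injury
    iteration (the default convention for outcome comparisons).
    """
    pos = network.positions if positions is None else np.asarray(positions, float)
    injured_set = set(int(j) for j in injured)
    cc = clustering_coefficients(network, injured_set)
    cluster_set = find_injury_clusters(network, injured_set, iteration=iteration)
    diameters = {
        cid: max_cluster_diameter(nodes, pos)
        for cid, _, nodes in cluster_set.clusters
    }
    distances = (
        min_intercluster_distances(cluster_set, pos) if len(cluster_set) else {}
    )
    return GeometryReport(
        cc=cc,
        cluster_set=cluster_set,
        max_diameter=diameters,
        min_intercluster_distance=distances,
    )
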