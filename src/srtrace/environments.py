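"""Graph topologies and random-walk sequence generation.

The task environments are 15-node, degree-4-regular undirected graphs of three
kinds: a modular graph (3 clusters of 5 nodes joined in a ring by single
connector edges), a ring lattice (each node joined to its two nearest
neighbours on either side), and a uniformly sampled connected 4-regular graph.
Stimulus sequences are unbiased random walks on these graphs; because every
node has degree 4, the walk's stationary distribution is uniform, equating
long-run node frequencies across kinds.

Node ids are 0-based internally; text I/O uses 1-based ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

N_NODES = 15
DEGREE = 4
GRAPH_KINDS = ("modular", "lattice", "random")


@dataclass(frozen=True)
class Graph:
    """An undirected task graph.

    Attributes
    ----------
    kind : str
        One of ``"modular"``, ``"lattice"``, ``"random"``.
    adjacency : np.ndarray
        Symmetric boolean (n, n) matrix without self-edges.
    cluster_of : np.ndarray or None
        Cluster label per node (modular graphs only).
    """

    kind: str
    adjacency: np.ndarray
    cluster_of: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[node])

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency.astype(int))
        if self.cluster_of is not None:
            nx.set_node_attributes(
                g, {i: int(c) for i, c in enumerate(self.cluster_of)}, "cluster"
            )
        return g


@dataclass(frozen=True)
class StateSequence:
    """A walk on a graph: ordered node ids for one stage."""

    nodes: np.ndarray
    stage: int = 0
    graph_kind: str | None = None

    def __len__(self) -> int:
        return len(self.nodes)


def _modular_adjacency() -> tuple[np.ndarray, np.ndarray]:
    """3 clusters of 5, complete within-cluster except between the two
    connector nodes, connectors linked in a ring of clusters."""
    adj = np.zeros((N_NODES, N_NODES), dtype=bool)
    cluster_of = np.repeat(np.arange(3), 5)
    for c in range(3):
        nodes = np.arange(5 * c, 5 * c + 5)
        for a in nodes:
            for b in nodes:
                if a < b:
                    adj[a, b] = adj[b, a] = True
    # connector nodes: first and last of each cluster; drop their mutual edge
    for c in range(3):
        lo, hi = 5 * c, 5 * c + 4
        adj[lo, hi] = adj[hi, lo] = False
    # ring of clusters: cluster c's exit connector -> cluster (c+1)'s entry
    for c in range(3):
        a = 5 * c + 4
        b = 5 * ((c + 1) % 3)
        adj[a, b] = adj[b, a] = True
    return adj, cluster_of


def _lattice_adjacency() -> np.ndarray:
    adj = np.zeros((N_NODES, N_NODES), dtype=bool)
    for i in range(N_NODES):
        for d in (1, 2):
            j = (i + d) % N_NODES
            adj[i, j] = adj[j, i] = True
    return adj


def _random_regular_adjacency(rng: np.random.Generator) -> np.ndarray:
    # rejection-sample until connected
    for _ in range(1000):
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.random_regular_graph(DEGREE, N_NODES, seed=seed)
        if nx.is_connected(g):
            return nx.to_numpy_array(g, dtype=bool)
    raise RuntimeError("failed to sample a connected 4-regular graph")


def build_graph(kind: str, seed: int | None = None) -> Graph:
    """Construct one of the three 15-node degree-4 task graphs.

    ``seed`` only matters for ``kind="random"``; the modular and lattice
    graphs are deterministic.
    """
    if kind == "modular":
        adj, cluster_of = _modular_adjacency()
        return Graph(kind=kind, adjacency=adj, cluster_of=cluster_of, seed=seed)
    if kind == "lattice":
        return Graph(kind=kind, adjacency=_lattice_adjacency(), seed=seed)
    if kind == "random":
        rng = np.random.default_rng(seed)
        return Graph(kind=kind, adjacency=_random_regular_adjacency(rng), seed=seed)
    raise ValueError(f"unknown graph kind {kind!r}; expected one of {GRAPH_KINDS}")


def random_walk(
    graph: Graph, n_trials: int, seed: int | None = None, stage: int = 0
) -> StateSequence:
    """Unbiased random walk: uniform start, then uniform over neighbours."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    neighbors = [graph.neighbors(i) for i in range(graph.n_nodes)]
    nodes = np.empty(n_trials, dtype=np.int64)
    nodes[0] = rng.integers(graph.n_nodes)
    for t in range(1, n_trials):
        nbrs = neighbors[nodes[t - 1]]
        nodes[t] = nbrs[rng.integers(len(nbrs))]
    return StateSequence(nodes=nodes, stage=stage, graph_kind=graph.kind)


def assign_motor_targets(n_nodes: int = N_NODES, seed: int | None = None) -> np.ndarray:
    """Random bijection node -> motor-target code.

    The 15 codes index the 5 single-key plus C(5,2)=10 two-key combinations;
    codes are 0-based internally (written 1-based in tables).
    """
    if n_nodes != N_NODES:
        raise ValueError(f"expected {N_NODES} nodes, got {n_nodes}")
    rng = np.random.default_rng(seed)
    return rng.permutation(n_nodes)


def write_edge_list(graph: Graph, path) -> None:
    """Edge-list text: two 1-based integer columns, optional cluster column."""
    lines = [f"{a + 1}\t{b + 1}" for a, b in graph.edges()]
    header = "# kind=%s seed=%s\n" % (graph.kind, graph.seed)
    body = "\n".join(lines) + "\n"
    if graph.cluster_of is not None:
        clusters = "\n".join(
            f"# cluster\t{i + 1}\t{int(c) + 1}" for i, c in enumerate(graph.cluster_of)
        )
        body += clusters + "\n"
    with open(path, "w") as fh:
        fh.write(header + body)
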