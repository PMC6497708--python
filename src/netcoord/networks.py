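"""Generators, measures and serialization for the study's network classes.

The experimental design compares coordination dynamics on three 20-node,
38-edge topologies (density 38/190 = 0.2):

* ``random`` — uniform random simple graphs (Erdős–Rényi style, conditioned
  on connectedness), with low clustering and a narrow degree distribution;
* ``clustered`` — Watts–Strogatz small-world graphs: a ring lattice whose
  edges are rewired with low probability, giving high clustering and short
  paths;
* ``centralized`` — Barabási–Albert preferential-attachment graphs with a
  few high-degree hubs and many peripheral nodes.

The classic generators produce a variable number of edges, while the
experimental networks have an exact density, so every generator here
post-adjusts its output to an exact edge count by uniformly random edge
removals/additions that preserve connectedness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np

RANDOM = "random"
CLUSTERED = "clustered"
CENTRALIZED = "centralized"
CUSTOM = "custom"

CLASS_LABELS = (RANDOM, CLUSTERED, CENTRALIZED, CUSTOM)

#: Experiment profile: 20 players, 38 edges, density 0.2.
EXPERIMENT_NODES = 20
EXPERIMENT_EDGES = 38

#: Bound on resampling attempts when conditioning a generator on connectedness.
MAX_ATTEMPTS = 1000


class ParameterError(ValueError):
    """An infeasible or invalid generator / measure parameter."""


class GenerationError(RuntimeError):
    """A generator failed to satisfy its postconditions within its bounds."""


class EdgeListError(ValueError):
    """A malformed or invalid edge-list file."""


@dataclass
class Network:
    """An undirected simple graph of players.

    Nodes are the integers ``0..N-1``. ``class_label`` records which network
    class the graph represents, ``generator_params`` and ``seed`` how it was
    built (empty / ``None`` for custom graphs).
    """

    graph: nx.Graph
    class_label: str = CUSTOM
    generator_params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ParameterError("self-loops are not allowed")
        expected = set(range(g.number_of_nodes()))
        if set(g.nodes) != expected:
            raise ParameterError("node ids must be consecutive integers 0..N-1")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        return nx.density(self.graph)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def neighbors(self, node: int) -> list[int]:
        return sorted(self.graph.neighbors(node))

    def edge_set(self) -> set[tuple[int, int]]:
        """Edges as unordered pairs normalized to ``(min, max)``."""
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in node-id order."""
        return nx.to_numpy_array(self.graph, nodelist=range(self.n_nodes), dtype=np.int8)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


def _check_edge_bounds(n_nodes: int, n_edges: int) -> None:
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges < n_nodes - 1:
        raise ParameterError(
            f"{n_edges} edges cannot connect {n_nodes} nodes (need at least {n_nodes - 1})"
        )
    if n_edges > max_edges:
        raise ParameterError(
            f"{n_edges} edges exceed the simple-graph maximum {max_edges} for {n_nodes} nodes"
        )


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


def _match_edge_count(g: nx.Graph, target_edges: int, rng: np.random.Generator) -> None:
    """Adjust ``g`` in place to exactly ``target_edges`` edges.

    Removals pick uniformly among non-bridge edges so the graph stays
    connected; additions pick uniformly among absent pairs.
    """
    while g.number_of_edges() > target_edges:
        bridges = {(min(u, v), max(u, v)) for u, v in nx.bridges(g)}
        removable = sorted(
            (min(u, v), max(u, v)) for u, v in g.edges if (min(u, v), max(u, v)) not in bridges
        )
        if not removable:
            raise GenerationError("cannot reduce edge count without disconnecting the graph")
        u, v = removable[_sub_seed(rng) % len(removable)]
        g.remove_edge(u, v)
    if g.number_of_edges() < target_edges:
        absent = sorted(
            (u, v)
            for u, v in itertools.combinations(range(g.number_of_nodes()), 2)
            if not g.has_edge(u, v)
        )
        need = target_edges - g.number_of_edges()
        idx = rng.choice(len(absent), size=need, replace=False)
        for i in sorted(int(j) for j in idx):
            g.add_edge(*absent[i])


def generate_random(n_nodes: int, n_edges: int, seed: int) -> Network:
    """Uniform random connected simple graph with exactly ``n_edges`` edges.

    Samples G(n, m) graphs and resamples (up to ``MAX_ATTEMPTS`` times) until
    the draw is connected, i.e. the distribution is uniform over connected
    graphs with the requested edge count.
    """
    _check_edge_bounds(n_nodes, n_edges)
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=_sub_seed(rng))
        if nx.is_connected(g):
            return Network(
                g, RANDOM, {"n_nodes": n_nodes, "n_edges": n_edges}, seed
            )
    raise GenerationError(
        f"no connected graph with {n_nodes} nodes / {n_edges} edges in {MAX_ATTEMPTS} attempts"
    )


def generate_small_world(
    n_nodes: int,
    lattice_neighbors: int,
    rewire_prob: float,
    target_edges: int | None = None,
    seed: int = 0,
) -> Network:
    """Watts–Strogatz small-world graph, adjusted to an exact edge count.

    Starts from a ring lattice in which each node is connected to its
    ``lattice_neighbors`` nearest neighbors and rewires each edge with
    probability ``rewire_prob``; connectedness is enforced by resampling and
    the edge count is then matched to ``target_edges`` (default: the lattice's
    own count) while preserving connectedness.
    """
    if lattice_neighbors % 2 != 0:
        raise ParameterError("lattice_neighbors must be even (ring-lattice construction)")
    if not 0 <= lattice_neighbors < n_nodes:
        raise ParameterError("lattice_neighbors must be in [0, n_nodes)")
    if not 0.0 <= rewire_prob <= 1.0:
        raise ParameterError("rewire_prob must be a probability")
    lattice_edges = n_nodes * lattice_neighbors // 2
    if target_edges is None:
        target_edges = lattice_edges
    _check_edge_bounds(n_nodes, target_edges)
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        g = nx.watts_strogatz_graph(n_nodes, lattice_neighbors, rewire_prob, seed=_sub_seed(rng))
        if nx.is_connected(g):
            _match_edge_count(g, target_edges, rng)
            return Network(
                g,
                CLUSTERED,
                {
                    "n_nodes": n_nodes,
                    "lattice_neighbors": lattice_neighbors,
                    "rewire_prob": rewire_prob,
                    "target_edges": target_edges,
                },
                seed,
            )
    raise GenerationError(
        f"no connected Watts–Strogatz draw in {MAX_ATTEMPTS} attempts"
    )


def generate_preferential(
    n_nodes: int, attach_count: int, target_edges: int | None = None, seed: int = 0
) -> Network:
    """Barabási–Albert preferential-attachment graph with an exact edge count.

    Growth attaches each new node to ``attach_count`` existing nodes with
    probability proportional to degree ("rich get richer"), producing hubs;
    the edge count is then matched to ``target_edges`` preserving
    connectedness.
    """
    if not 1 <= attach_count < n_nodes:
        raise ParameterError("attach_count must satisfy 1 <= attach_count < n_nodes")
    if target_edges is not None:
        _check_edge_bounds(n_nodes, target_edges)
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attach_count, seed=_sub_seed(rng))
    if target_edges is not None:
        _match_edge_count(g, target_edges, rng)
    return Network(
        g,
        CENTRALIZED,
        {"n_nodes": n_nodes, "attach_count": attach_count, "target_edges": target_edges},
        seed,
    )


def degree_centrality(network: Network) -> dict[int, int]:
    """Integer degree per node (the study's degree-centrality measure)."""
    return {n: int(d) for n, d in network.graph.degree()}


def clustering_coefficient(network: Network) -> float:
    """Average local clustering coefficient.

    Per node: the fraction of its neighbor pairs that are themselves
    connected (0 for degree < 2), averaged over all nodes.
    """
    return float(nx.average_clustering(network.graph))


def detect_communities(network: Network) -> list[list[int]]:
    """Deterministic greedy-modularity partition of the nodes.

    Blocks are returned as sorted node lists, ordered by their smallest
    member, so repeated calls on the same graph yield the identical partition.
    """
    if not network.is_connected():
        raise ParameterError("community detection expects a connected network")
    blocks = nx.community.greedy_modularity_communities(network.graph)
    out = [sorted(b) for b in blocks]
    out.sort(key=lambda b: b[0])
    return out


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write the network as ``# N=<n>`` header plus one ``i j`` pair per line."""
    path = Path(path)
    lines = [f"# N={network.n_nodes}"]
    lines += [f"{u} {v}" for u, v in sorted(network.edge_set())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_lines(text: str) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line:
            yield lineno, line


def read_edge_list(path: str | Path, class_label: str = CUSTOM) -> Network:
    """Read an edge-list file written by :func:`write_edge_list`.

    Raises :class:`EdgeListError` (with the offending line number) on
    malformed lines, self-loops, duplicate edges or out-of-range node ids.
    """
    path = Path(path)
    declared_n: int | None = None
    edges: set[tuple[int, int]] = set()
    max_node = -1
    for lineno, line in _parse_lines(path.read_text(encoding="utf-8")):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.upper().startswith("N="):
                try:
                    declared_n = int(body[2:])
                except ValueError as exc:
                    raise EdgeListError(f"line {lineno}: bad header {line!r}") from exc
            continue
        parts = line.split()
        if len(parts) != 2:
            raise EdgeListError(f"line {lineno}: expected two node ids, got {line!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EdgeListError(f"line {lineno}: non-integer node id in {line!r}") from exc
        if u == v:
            raise EdgeListError(f"line {lineno}: self-loop {u}-{v}")
        if u < 0 or v < 0:
            raise EdgeListError(f"line {lineno}: negative node id in {line!r}")
        edge = (min(u, v), max(u, v))
        if edge in edges:
            raise EdgeListError(f"line {lineno}: duplicate edge {u}-{v}")
        edges.add(edge)
        max_node = max(max_node, u, v)
    n = declared_n if declared_n is not None else max_node + 1
    if max_node >= n:
        raise EdgeListError(f"node id {max_node} out of range for declared N={n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return Network(g, class_label)
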