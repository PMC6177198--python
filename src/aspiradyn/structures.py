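"""Population structures and coplayer-sampling semantics.

Two interaction modes:

- ``well_mixed``: no graph; each payoff evaluation draws d-1 coplayers
  uniformly without replacement from the N-1 other individuals (one-shot
  interactions, hypergeometric group composition).
- ``network``: a simple undirected graph; the focal draws d-1 coplayers
  uniformly without replacement from its neighborhood. Every node must
  keep degree >= d-1 so each individual has enough neighbors for the
  d-player game. On a regular graph of degree exactly d-1 the draw is the
  whole neighborhood, so the game group is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "PopulationStructure",
    "make_ring",
    "make_complete",
    "make_well_mixed",
    "make_random_graph",
    "from_edgelist",
    "to_edgelist",
    "sample_coplayers",
]

#: attempts allowed when resampling a random graph to meet the degree floor
MAX_GRAPH_RETRIES = 200


@dataclass
class PopulationStructure:
    """A population of N individuals plus its interaction topology."""

    n: int
    mode: str  # "well_mixed" | "network"
    kind: str  # complete | ring | k_regular | erdos_renyi | barabasi_albert | custom | well_mixed
    graph: nx.Graph | None = None
    _csr: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in {"well_mixed", "network"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "network":
            g = self.graph
            if g is None or g.number_of_nodes() != self.n:
                raise ValueError("network mode requires a graph on exactly N nodes")
            if any(g.has_edge(u, u) for u in g):
                raise ValueError("self-loops are not allowed")
            if sorted(g.nodes) != list(range(self.n)):
                raise ValueError("nodes must be labelled 0..N-1")

    @property
    def is_regular(self) -> bool:
        if self.mode != "network":
            return False
        degs = {d for _, d in self.graph.degree()}
        return len(degs) == 1

    def degree(self, node: int) -> int:
        if self.mode != "network":
            return self.n - 1
        return self.graph.degree(node)

    def min_degree(self) -> int:
        if self.mode != "network":
            return self.n - 1
        return min(d for _, d in self.graph.degree())

    def neighbors(self, node: int) -> np.ndarray:
        indptr, indices = self.csr()
        return indices[indptr[node] : indptr[node + 1]]

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbor lists in CSR layout (indptr, indices); empty for well-mixed."""
        if self._csr is None:
            if self.mode == "well_mixed":
                self._csr = (np.zeros(self.n + 1, dtype=np.int64), np.zeros(0, dtype=np.int64))
            else:
                indptr = np.zeros(self.n + 1, dtype=np.int64)
                nbrs = [np.array(sorted(self.graph.neighbors(u)), dtype=np.int64) for u in range(self.n)]
                indptr[1:] = np.cumsum([len(x) for x in nbrs])
                indices = np.concatenate(nbrs) if nbrs else np.zeros(0, dtype=np.int64)
                self._csr = (indptr, indices)
        return self._csr


def make_ring(n: int) -> PopulationStructure:
    """Cycle graph: each individual interacts with its two nearest neighbors."""
    if n < 3:
        raise ValueError(f"a ring needs at least 3 individuals, got {n}")
    return PopulationStructure(n=n, mode="network", kind="ring", graph=nx.cycle_graph(n))


def make_complete(n: int) -> PopulationStructure:
    """Complete graph (every pair linked)."""
    if n < 2:
        raise ValueError("complete graph needs at least 2 nodes")
    return PopulationStructure(n=n, mode="network", kind="complete", graph=nx.complete_graph(n))


def make_well_mixed(n: int) -> PopulationStructure:
    """Structureless population: coplayers drawn from everyone else."""
    if n < 2:
        raise ValueError("population size must be at least 2")
    return PopulationStructure(n=n, mode="well_mixed", kind="well_mixed", graph=None)


def make_random_graph(
    n: int,
    kind: str,
    *,
    k: int | None = None,
    p: float | None = None,
    m: int | None = None,
    min_degree: int = 2,
    rng_seed: int | None = None,
) -> PopulationStructure:
    """Random population structure with an enforced degree floor.

    Kinds: ``k_regular`` (degree k), ``erdos_renyi`` (edge probability p,
    default 4/N for mean degree 4) and ``barabasi_albert`` (attachment
    m, default 2). The degree floor guarantees every individual enough
    neighbors to play with: regular graphs are resampled up to a bounded
    retry count until connected; Erdos-Renyi samples are repaired by
    wiring each deficient node to uniformly chosen non-neighbors and then
    bridging disconnected components with random edges (degrees only
    grow, so the floor survives the bridging).
    """
    rng = np.random.default_rng(rng_seed)
    if kind == "erdos_renyi" and p is None:
        p = 4.0 / n
    if kind == "barabasi_albert" and m is None:
        m = 2
    for _ in range(MAX_GRAPH_RETRIES):
        seed = int(rng.integers(0, 2**31 - 1))
        if kind == "k_regular":
            if k is None:
                raise ValueError("k_regular requires k")
            if k < min_degree:
                raise ValueError(f"k={k} below the degree floor {min_degree}")
            if k == 2:
                # the connected 2-regular graph is the ring
                return PopulationStructure(n=n, mode="network", kind="k_regular", graph=nx.cycle_graph(n))
            g = nx.random_regular_graph(k, n, seed=seed)
        elif kind == "erdos_renyi":
            g = _repair(nx.gnp_random_graph(n, p, seed=seed), min_degree, rng)
        elif kind == "barabasi_albert":
            if m < min_degree:
                raise ValueError(f"m={m} below the degree floor {min_degree}")
            g = _repair(nx.barabasi_albert_graph(n, m, seed=seed), min_degree, rng)
        else:
            raise ValueError(f"unknown random-graph kind {kind!r}")
        if (
            nx.is_connected(g)
            and min(d for _, d in g.degree()) >= min_degree
            and nx.number_of_selfloops(g) == 0
        ):
            return PopulationStructure(n=n, mode="network", kind=kind, graph=g)
    raise RuntimeError(
        f"could not generate a connected {kind} graph with min degree {min_degree} "
        f"in {MAX_GRAPH_RETRIES} attempts (n={n}, k={k}, p={p}, m={m})"
    )


def _repair(g: nx.Graph, min_degree: int, rng: np.random.Generator) -> nx.Graph:
    """Enforce the degree floor and connectivity by adding edges."""
    n = g.number_of_nodes()
    if min_degree >= n:
        raise ValueError("degree floor infeasible for this population size")
    for u in g.nodes:
        while g.degree(u) < min_degree:
            v = int(rng.integers(n))
            if v != u and not g.has_edge(u, v):
                g.add_edge(u, v)
    comps = [list(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        c1 = comps.pop()
        c2 = comps[-1]
        g.add_edge(
            c1[int(rng.integers(len(c1)))], c2[int(rng.integers(len(c2)))]
        )
        comps[-1] = c2 + c1
    return g


def from_edgelist(path, n: int | None = None) -> PopulationStructure:
    """Read a custom structure from a whitespace-delimited edge list (0-based ids)."""
    g = nx.read_edgelist(path, nodetype=int)
    if n is None:
        n = max(g.nodes) + 1
    g.add_nodes_from(range(n))
    return PopulationStructure(n=n, mode="network", kind="custom", graph=g)


def to_edgelist(structure: PopulationStructure, path) -> None:
    if structure.mode != "network":
        raise ValueError("well-mixed populations have no edges to write")
    nx.write_edgelist(structure.graph, path, data=False)


def sample_coplayers(
    structure: PopulationStructure, focal: int, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the d-1 coplayers of a focal individual for one game.

    Uniform without replacement from the focal's neighborhood (network
    mode) or from all other individuals (well-mixed); never includes the
    focal itself.
    """
    need = d - 1
    if structure.mode == "well_mixed":
        if structure.n < d:
            raise ValueError(f"population of {structure.n} too small for a {d}-player game")
        others = rng.choice(structure.n - 1, size=need, replace=False)
        return np.where(others >= focal, others + 1, others)
    nbrs = structure.neighbors(focal)
    if len(nbrs) < need:
        raise ValueError(
            f"node {focal} has degree {len(nbrs)} < d-1 = {need}; cannot form the game group"
        )
    if len(nbrs) == need:
        return nbrs.copy()
    return rng.choice(nbrs, size=need, replace=False)
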