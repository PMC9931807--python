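"""Core domain types and exact small-model mathematics.

This module defines the containers shared by the whole package — activity
matrices, undirected microcircuits, Markov blankets, pairwise-model
parameters — together with the exact operations (Ising energies, exact
Gibbs distributions by enumeration, DAG Markov blankets, moralization)
that the learner, the simulators and the test oracles build on.

A *microcircuit* here is an undirected simple graph over neuron labels:
an edge records a direct statistical association between the activity of
two neurons.  The binary generative model is the Ising model with fields,

    U(x) = -(sum_i r_i x_i + sum_{i<j} w_ij x_i x_j),
    P(x) = exp(-beta * U(x)) / Z,

with each unordered pair counted once (equivalently ``-(r'x + x'Wx/2)``
for a symmetric coupling matrix W with zero diagonal).  The continuous
analogue is the Gaussian Markov network, whose structure is the support
of the precision matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DataMatrix",
    "Microcircuit",
    "MarkovBlanket",
    "IsingParams",
    "GaussianMNParams",
    "DirectedGraph",
    "ising_energy",
    "ising_exact_distribution",
    "dag_markov_blanket",
    "moralize",
    "neighborhood",
]

_ENUMERATION_LIMIT = 20


def _check_unique_labels(labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise ValueError("node labels must be unique")
    return labels


@dataclass(frozen=True)
class DataMatrix:
    """An ``n_samples x n_nodes`` activity matrix.

    ``mode`` is ``"binary"`` for 0/1 spike counts per time bin and
    ``"continuous"`` for real-valued signals (e.g. dF/F0 traces).
    Rows are samples (time bins or trials), columns are neurons.
    """

    values: np.ndarray
    mode: str
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] < 1:
            raise ValueError("need at least one sample")
        labels = _check_unique_labels(self.node_labels)
        if values.shape[1] != len(labels):
            raise ValueError(
                f"{values.shape[1]} columns but {len(labels)} node labels"
            )
        if self.mode not in ("binary", "continuous"):
            raise ValueError("mode must be 'binary' or 'continuous'")
        if self.mode == "binary" and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("binary mode requires all values in {0, 1}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.index(label)]

    def index(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def select(self, labels: Sequence[str]) -> "DataMatrix":
        """Return a new matrix restricted to ``labels`` (in the given order)."""
        idx = [self.index(l) for l in labels]
        return DataMatrix(self.values[:, idx], self.mode, tuple(labels))

    @staticmethod
    def from_array(values, node_labels=None, mode=None) -> "DataMatrix":
        """Build a DataMatrix from any 2-D array-like, auto-detecting mode."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if node_labels is None:
            node_labels = tuple(f"X{i + 1}" for i in range(values.shape[1]))
        if mode is None:
            mode = "binary" if np.isin(values, (0.0, 1.0)).all() else "continuous"
        return DataMatrix(values, mode, tuple(node_labels))


class Microcircuit:
    """An undirected simple graph over node labels (symmetric adjacency)."""

    def __init__(self, node_labels: Sequence[str], adjacency: np.ndarray | None = None):
        self.node_labels = _check_unique_labels(node_labels)
        n = len(self.node_labels)
        if adjacency is None:
            adjacency = np.zeros((n, n), dtype=bool)
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(adjacency, adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if adjacency.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = adjacency
        self._index = {l: i for i, l in enumerate(self.node_labels)}

    @classmethod
    def from_edges(cls, node_labels: Sequence[str],
                   edges: Iterable[tuple[str, str]]) -> "Microcircuit":
        g = cls(node_labels)
        adj = g.adjacency.copy()
        for a, b in edges:
            i, j = g.index(a), g.index(b)
            if i == j:
                raise ValueError(f"self-loop on {a!r}")
            adj[i, j] = adj[j, i] = True
        return cls(node_labels, adj)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> set[tuple[str, str]]:
        """Edge set as sorted label pairs."""
        out = set()
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(ii, jj):
            a, b = self.node_labels[i], self.node_labels[j]
            out.add((a, b) if a <= b else (b, a))
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return bool(self.adjacency[self.index(a), self.index(b)])

    def subgraph(self, labels: Sequence[str]) -> "Microcircuit":
        idx = [self.index(l) for l in labels]
        return Microcircuit(tuple(labels), self.adjacency[np.ix_(idx, idx)])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges())
        return g

    def __eq__(self, other) -> bool:
        return (isinstance(other, Microcircuit)
                and self.node_labels == other.node_labels
                and np.array_equal(self.adjacency, other.adjacency))

    def __hash__(self):  # pragma: no cover - graphs are mutable-ish containers
        return hash((self.node_labels, self.adjacency.tobytes()))

    def __repr__(self) -> str:
        return (f"Microcircuit(n_nodes={self.n_nodes}, "
                f"n_edges={self.n_edges})")


@dataclass(frozen=True)
class MarkovBlanket:
    """A target node together with its detected Markov blanket members."""

    target: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(self.members)
        if self.target in members:
            raise ValueError("target cannot be a member of its own blanket")
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class IsingParams:
    """Fields r, symmetric couplings W (zero diagonal) and temperature beta."""

    r: np.ndarray
    W: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        W = np.asarray(self.W, dtype=float)
        if r.ndim != 1 or W.shape != (r.size, r.size):
            raise ValueError("r must be length n and W must be n x n")
        if not np.allclose(W, W.T):
            raise ValueError("coupling matrix W must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise ValueError("coupling matrix W must have zero diagonal")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "W", W)

    @property
    def n_nodes(self) -> int:
        return self.r.size

    def structure(self, node_labels: Sequence[str] | None = None) -> Microcircuit:
        """The microcircuit whose edges are the nonzero couplings."""
        if node_labels is None:
            node_labels = tuple(f"X{i + 1}" for i in range(self.n_nodes))
        adj = self.W != 0.0
        np.fill_diagonal(adj, False)
        return Microcircuit(node_labels, adj)


@dataclass(frozen=True)
class GaussianMNParams:
    """Gaussian Markov network: mean mu and covariance Sigma.

    The graph structure is the support of the precision matrix
    ``Sigma^{-1}``: an edge (i, j) is present iff the off-diagonal
    precision entry is nonzero beyond a relative tolerance.
    """

    mu: np.ndarray
    sigma: np.ndarray
    structure_rtol: float = 1e-8

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise ValueError("mu must be length n and sigma n x n")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise ValueError("sigma must be positive definite") from None
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_nodes(self) -> int:
        return self.mu.size

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.sigma)

    @property
    def A(self) -> np.ndarray:
        """Negative precision, the quadratic coefficient of the energy."""
        return -self.precision

    @property
    def b(self) -> np.ndarray:
        return self.mu @ self.A

    def structure(self, node_labels: Sequence[str] | None = None) -> Microcircuit:
        if node_labels is None:
            node_labels = tuple(f"X{i + 1}" for i in range(self.n_nodes))
        prec = self.precision
        off = prec.copy()
        np.fill_diagonal(off, 0.0)
        scale = np.abs(off).max(initial=0.0)
        tol = self.structure_rtol * scale if scale > 0 else 0.0
        adj = np.abs(off) > tol
        adj = adj | adj.T
        return Microcircuit(node_labels, adj)


class DirectedGraph:
    """A directed acyclic graph given as per-node parent sets."""

    def __init__(self, node_labels: Sequence[str],
                 parent_sets: Mapping[str, Iterable[str]] | None = None):
        self.node_labels = _check_unique_labels(node_labels)
        nodes = set(self.node_labels)
        parents: dict[str, frozenset[str]] = {l: frozenset() for l in self.node_labels}
        if parent_sets:
            for child, ps in parent_sets.items():
                if child not in nodes:
                    raise KeyError(f"unknown node label {child!r}")
                ps = frozenset(ps)
                if not ps <= nodes:
                    raise KeyError(f"unknown parents {ps - nodes} for {child!r}")
                if child in ps:
                    raise ValueError(f"{child!r} cannot be its own parent")
                parents[child] = ps
        self.parent_sets = parents
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over the parent-set representation.
        indeg = {v: len(self.parent_sets[v]) for v in self.node_labels}
        children = self.children_map()
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.node_labels):
            raise ValueError("graph contains a directed cycle")

    def children_map(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = {l: set() for l in self.node_labels}
        for child, ps in self.parent_sets.items():
            for p in ps:
                children[p].add(child)
        return children

    def parents(self, node: str) -> frozenset[str]:
        if node not in self.parent_sets:
            raise KeyError(f"unknown node label {node!r}")
        return self.parent_sets[node]


# ---------------------------------------------------------------------------
# Exact operations


def ising_energy(x, params: IsingParams) -> float:
    """Energy U(x) = -(r'x + x'Wx / 2) of a binary configuration.

    Each unordered coupling pair contributes once.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_nodes,):
        raise ValueError(
            f"configuration length {x.size} does not match {params.n_nodes} nodes"
        )
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("configuration must be binary")
    return float(-(params.r @ x + 0.5 * x @ params.W @ x))


def ising_exact_distribution(params: IsingParams):
    """Exact Gibbs distribution P(x) ∝ exp(-beta U(x)) by full enumeration.

    Returns ``(configs, probabilities, Z)`` where ``configs`` is the
    ``2^n x n`` array of all binary configurations in lexicographic order
    (node 1 is the most significant bit).  This is an oracle for small
    models only; it refuses n > 20.
    """
    n = params.n_nodes
    if n > _ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration limited to {_ENUMERATION_LIMIT} nodes (got {n}); "
            "use the Metropolis-Hastings sampler for larger models"
        )
    configs = np.array(list(itertools.product((0, 1), repeat=n)), dtype=float)
    energies = -(configs @ params.r
                 + 0.5 * np.einsum("ki,ij,kj->k", configs, params.W, configs))
    logw = -params.beta * energies
    shift = logw.max()
    w = np.exp(logw - shift)
    Z = float(w.sum() * np.exp(shift))
    return configs, w / w.sum(), Z


def dag_markov_blanket(g: DirectedGraph, node: str) -> set[str]:
    """Markov blanket of ``node`` in a DAG: parents, children and co-parents."""
    parents = set(g.parents(node))
    children_map = g.children_map()
    children = children_map[node]
    coparents: set[str] = set()
    for c in children:
        coparents |= set(g.parents(c))
    blanket = parents | children | coparents
    blanket.discard(node)
    return blanket


def moralize(g: DirectedGraph) -> Microcircuit:
    """Moral graph: undirected skeleton plus marriages between co-parents.

    The neighborhood of every node in the result equals its Markov
    blanket in the input DAG.
    """
    edges: set[tuple[str, str]] = set()

    def _add(a: str, b: str) -> None:
        edges.add((a, b) if a <= b else (b, a))

    for child, ps in g.parent_sets.items():
        for p in ps:
            _add(p, child)
        for a, b in itertools.combinations(sorted(ps), 2):
            _add(a, b)
    return Microcircuit.from_edges(g.node_labels, edges)


def neighborhood(g: Microcircuit, node: str) -> set[str]:
    """Set of nodes adjacent to ``node`` — its Markov blanket in a Markov network."""
    i = g.index(node)
    return {g.node_labels[j] for j in np.nonzero(g.adjacency[i])[0]}
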