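"""Structure-recovery evaluation and microcircuit subtype analysis.

Evaluation against a ground-truth graph uses edge-level TPR and FPR:
TPR is the number of correctly identified links over the number of true
edges; FPR is the number of falsely identified links over the number of
empty (absent) pairs in the ground truth.  Sensitivity = TPR,
specificity = 1 - FPR.

The subtype pipeline mirrors a per-trial microcircuit study: pairwise
Sørensen-Dice similarity between the learned graphs, multi-level
(Louvain) modularity optimization on the similarity network to find
clusters of recurring configurations, a representative graph per
cluster, graph-level centrality summaries (mean betweenness, mean
eigenvector centrality), and two-sample t-tests contrasting the
subtypes.
"""

from __future__ import annotations

import contextlib
import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .graphical_models import Microcircuit

__all__ = [
    "EvalResult",
    "SubtypeResult",
    "evaluate_structure",
    "dice_similarity",
    "similarity_matrix",
    "detect_subtypes",
    "representative_graph",
    "graph_centrality",
    "compare_subtypes",
    "MicrocircuitSubtyper",
]


@dataclass(frozen=True)
class EvalResult:
    """Edge-level confusion summary of an estimated graph vs ground truth."""

    n_edges_gt: int
    n_empty_gt: int
    tp: int
    fp: int
    tpr: float
    fpr: float

    @property
    def fn(self) -> int:
        return self.n_edges_gt - self.tp

    @property
    def tn(self) -> int:
        return self.n_empty_gt - self.fp

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


def evaluate_structure(est: Microcircuit, gt: Microcircuit,
                       nodes=None) -> EvalResult:
    """Compare an estimated microcircuit against the ground truth.

    If ``nodes`` is given, both graphs are restricted to that subset
    first (e.g. to the retained neurons); otherwise the node sets must
    match exactly.
    """
    if nodes is not None:
        nodes = tuple(nodes)
        est = est.subgraph(nodes)
        gt = gt.subgraph(nodes)
    if set(est.node_labels) != set(gt.node_labels):
        raise ValueError("node sets differ; pass nodes= to restrict evaluation")
    if est.node_labels != gt.node_labels:
        est = est.subgraph(gt.node_labels)
    e_est = est.edges()
    e_gt = gt.edges()
    n = gt.n_nodes
    n_pairs = n * (n - 1) // 2
    n_edges_gt = len(e_gt)
    n_empty_gt = n_pairs - n_edges_gt
    tp = len(e_est & e_gt)
    fp = len(e_est - e_gt)
    tpr = tp / n_edges_gt if n_edges_gt else 0.0
    fpr = fp / n_empty_gt if n_empty_gt else 0.0
    return EvalResult(n_edges_gt, n_empty_gt, tp, fp, tpr, fpr)


def dice_similarity(a: Microcircuit, b: Microcircuit) -> float:
    """Sørensen-Dice coefficient of two edge sets: 2|Ea ∩ Eb| / (|Ea| + |Eb|).

    1 means a perfect match, 0 no overlap.  Two empty graphs are
    identical objects and score 1.
    """
    if set(a.node_labels) != set(b.node_labels):
        raise ValueError("graphs must share the same node set")
    ea, eb = a.edges(), b.edges()
    denom = len(ea) + len(eb)
    if denom == 0:
        return 1.0
    return 2.0 * len(ea & eb) / denom


def similarity_matrix(graphs: list[Microcircuit]) -> np.ndarray:
    """Pairwise Dice similarity with unit diagonal."""
    if not graphs:
        raise ValueError("need at least one graph")
    m = len(graphs)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = dice_similarity(graphs[i], graphs[j])
    return sim


@contextlib.contextmanager
def _seeded_python_rng(seed: int):
    """python-igraph delegates randomness to the stdlib RNG; scope it."""
    state = _pyrandom.getstate()
    _pyrandom.seed(seed)
    try:
        yield
    finally:
        _pyrandom.setstate(state)


def detect_subtypes(sim: np.ndarray, seed: int = 0,
                    resolution: float = 1.0,
                    weight_floor: float = 1e-12) -> np.ndarray:
    """Cluster a similarity matrix by multi-level modularity optimization.

    The similarity matrix (square, symmetric, entries in [0, 1]) is
    interpreted as a weighted graph with self-loops removed and weights
    below ``weight_floor`` dropped; Louvain community detection on it
    yields the subtype label of each graph.  Deterministic given
    ``seed``.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.size == 0:
        raise ValueError("empty similarity matrix")
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T):
        raise ValueError("similarity matrix must be symmetric")
    if sim.min() < -1e-12 or sim.max() > 1.0 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")
    m = sim.shape[0]
    if m == 1:
        return np.zeros(1, dtype=int)
    W = sim.copy()
    np.fill_diagonal(W, 0.0)
    ii, jj = np.nonzero(np.triu(W > weight_floor, k=1))
    g = ig.Graph(m)
    g.add_edges(list(zip(ii.tolist(), jj.tolist())))
    weights = W[ii, jj].tolist()
    with _seeded_python_rng(seed):
        clustering = g.community_multilevel(weights=weights or None,
                                            resolution=resolution)
    return np.asarray(clustering.membership, dtype=int)


def representative_graph(graphs: list[Microcircuit],
                         labels) -> dict[int, int]:
    """Per cluster, the member with maximal mean similarity to co-members.

    Returns a mapping cluster id -> index into ``graphs``.  Singletons
    represent themselves; ties go to the lowest index.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(graphs):
        raise ValueError("labels must align with graphs")
    sim = similarity_matrix(graphs)
    reps: dict[int, int] = {}
    for cluster in sorted(set(labels.tolist())):
        members = np.nonzero(labels == cluster)[0]
        if members.size == 0:
            continue
        if members.size == 1:
            reps[cluster] = int(members[0])
            continue
        sub = sim[np.ix_(members, members)]
        mean_sim = (sub.sum(axis=1) - 1.0) / (members.size - 1)
        reps[cluster] = int(members[int(np.argmax(mean_sim))])
    return reps


def graph_centrality(g: Microcircuit, metric: str = "betweenness",
                     normalized: bool = False) -> float:
    """Graph-level centrality: the node-level metric averaged across nodes.

    ``betweenness`` counts shortest paths through each node
    (unnormalized by default); ``eigenvector`` is the principal
    eigenvector of the adjacency matrix, scaled to unit Euclidean norm.
    Eigenvector centrality is undefined on an edgeless graph.
    """
    if g.n_nodes == 0:
        raise ValueError("graph has no nodes")
    if metric == "betweenness":
        scores = nx.betweenness_centrality(g.to_networkx(), normalized=normalized)
        return float(np.mean(list(scores.values())))
    if metric == "eigenvector":
        if g.n_edges == 0:
            raise ValueError("eigenvector centrality is undefined on an "
                             "edgeless graph")
        A = g.adjacency.astype(float)
        w, v = np.linalg.eigh(A)
        vec = v[:, int(np.argmax(w))]
        vec = np.abs(vec)
        vec = vec / np.linalg.norm(vec)
        return float(vec.mean())
    raise ValueError("metric must be 'betweenness' or 'eigenvector'")


def compare_subtypes(scores, labels,
                     equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test (two-tailed) contrasting a score across two groups.

    Pooled-variance by default (Welch with ``equal_var=False``); the
    pooled variance is floored so perfectly separated constant groups
    give a huge finite |t| and identical groups give t = 0, p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must align")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if equal_var:
        pooled = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
        pooled = max(pooled, 1e-300)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        va, vb = max(a.var(ddof=1), 1e-300), max(b.var(ddof=1), 1e-300)
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if diff == 0.0:
        return 0.0, 1.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(min(p, 1.0))


class MicrocircuitSubtyper(BaseEstimator):
    """Cluster per-trial microcircuits into subtypes.

    Computes the pairwise Dice similarity network of the input graphs
    and partitions it by multi-level modularity optimization.

    Parameters
    ----------
    resolution : float, default 1.0
        Louvain resolution.
    random_state : int, default 0
        Seed for the community-detection pass.

    Attributes
    ----------
    similarity_ : ndarray
        Pairwise Dice similarity matrix, unit diagonal.
    labels_ : ndarray of int
        Subtype id per input graph.
    representatives_ : dict of int -> int
        Per subtype, the index of the graph with maximal mean
        similarity to its co-members.
    """

    def __init__(self, resolution: float = 1.0, random_state: int = 0):
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        graphs = list(X)
        if not graphs:
            raise ValueError("need at least one graph")
        self.similarity_ = similarity_matrix(graphs)
        self.labels_ = detect_subtypes(self.similarity_,
                                       seed=self.random_state,
                                       resolution=self.resolution)
        self.representatives_ = representative_graph(graphs, self.labels_)
        self.n_clusters_ = int(len(set(self.labels_.tolist())))
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
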