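"""Bayesian Coherence Analysis: node-wise blanket learning and combination.

The full BCA procedure learns one BNCIT model per node — every node in
turn is the leaf and all remaining nodes are candidate parents — and
then combines the M detected blankets into a single undirected
microcircuit by the OR rule: nodes i and j are connected iff
i ∈ mb*(j) or j ∈ mb*(i).  The OR combination improves sensitivity,
since a direct association only needs to be detected from one side.

The estimator :class:`BCAGraphLearner` wraps the procedure in
scikit-learn conventions (``fit`` on an ``(n_samples, n_nodes)`` matrix,
fitted attributes with trailing underscores, ``get_params`` /
``set_params``) so it composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bncit import ScoreConfig, find_markov_blanket
from .graphical_models import DataMatrix, MarkovBlanket, Microcircuit

__all__ = [
    "BlanketCollection",
    "BCAGraphLearner",
    "filter_inactive_nodes",
    "learn_blankets",
    "combine_blankets",
    "learn_microcircuit",
]


@dataclass(frozen=True)
class BlanketCollection:
    """The per-node blankets detected in one BCA run."""

    blankets: dict[str, MarkovBlanket]
    config: ScoreConfig

    def __post_init__(self) -> None:
        for label, mb in self.blankets.items():
            if mb.target != label:
                raise ValueError(f"blanket keyed {label!r} targets {mb.target!r}")


def filter_inactive_nodes(data: DataMatrix) -> tuple[DataMatrix, list[str]]:
    """Drop constant (zero-variance) columns, e.g. neurons that never fire.

    Returns the reduced matrix and the list of dropped labels.  Raises if
    every column is constant.
    """
    spans = np.ptp(data.values, axis=0)
    keep = [l for l, s in zip(data.node_labels, spans) if s > 0.0]
    dropped = [l for l, s in zip(data.node_labels, spans) if s == 0.0]
    if not keep:
        raise ValueError("all columns are constant; nothing to learn from")
    if not dropped:
        return data, []
    return data.select(keep), dropped


def learn_blankets(data: DataMatrix, cfg: ScoreConfig | None = None) -> BlanketCollection:
    """Run the BNCIT blanket search with every node as the leaf in turn."""
    cfg = cfg or ScoreConfig()
    blankets = {
        label: find_markov_blanket(data, label, cfg)
        for label in data.node_labels
    }
    return BlanketCollection(blankets, cfg)


def combine_blankets(bc: BlanketCollection, rule: str = "or",
                     node_labels=None) -> Microcircuit:
    """Combine per-node blankets into one undirected microcircuit.

    ``rule="or"`` (the BCA default) connects i and j iff i ∈ mb*(j) or
    j ∈ mb*(i); ``rule="and"`` requires both, trading sensitivity for
    specificity.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if node_labels is None:
        node_labels = tuple(bc.blankets.keys())
    g = Microcircuit(node_labels)
    adj = g.adjacency.copy()
    idx = {l: i for i, l in enumerate(node_labels)}
    for label, mb in bc.blankets.items():
        i = idx[label]
        for member in mb.members:
            j = idx[member]
            if rule == "or":
                adj[i, j] = adj[j, i] = True
            else:
                if label in bc.blankets.get(member, MarkovBlanket(member, frozenset())).members:
                    adj[i, j] = adj[j, i] = True
    return Microcircuit(node_labels, adj)


def learn_microcircuit(data: DataMatrix, cfg: ScoreConfig | None = None,
                       rule: str = "or") -> Microcircuit:
    """Full BCA: filter inactive nodes, learn blankets, combine.

    Dropped (constant) nodes are retained in the output as isolated
    nodes so that downstream evaluation over the full node set stays
    well-defined.
    """
    active, dropped = filter_inactive_nodes(data)
    bc = learn_blankets(active, cfg)
    learned = combine_blankets(bc, rule=rule)
    if not dropped:
        return learned
    full = Microcircuit(data.node_labels)
    adj = full.adjacency.copy()
    for a, b in learned.edges():
        i, j = full.index(a), full.index(b)
        adj[i, j] = adj[j, i] = True
    return Microcircuit(data.node_labels, adj)


class BCAGraphLearner(BaseEstimator):
    """Learn an undirected microcircuit by node-wise Markov blanket discovery.

    Parameters
    ----------
    score : {"auto", "bdeu", "bic"}
        Fitness function: BDeu for binary spike matrices, BIC for
        continuous traces.  ``"auto"`` picks BDeu when all values are
        in {0, 1}, BIC otherwise.
    ess : float, default 1.0
        BDeu equivalent sample size.
    max_parents : int or None
        Optional cap on per-node blanket size.
    combine : {"or", "and"}, default "or"
        Blanket combination rule; OR is the BCA default.
    variance_floor : float, default 1e-12
        Residual-variance floor for the Gaussian (BIC) family.

    Attributes
    ----------
    graph_ : Microcircuit
        The learned microcircuit over all input nodes (constant nodes
        appear isolated).
    blankets_ : dict of str -> MarkovBlanket
        Detected blanket per retained node.
    dropped_ : list of str
        Labels of constant columns excluded from learning.
    feature_names_in_ : ndarray of str
        Node labels, in column order.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> a = rng.integers(0, 2, 500)
    >>> X = np.column_stack([a, a, rng.integers(0, 2, 500)])
    >>> learner = BCAGraphLearner().fit(X)
    >>> sorted(learner.graph_.edges())
    [('X1', 'X2')]
    """

    def __init__(self, score: str = "auto", ess: float = 1.0,
                 max_parents: int | None = None, combine: str = "or",
                 variance_floor: float = 1e-12):
        self.score = score
        self.ess = ess
        self.max_parents = max_parents
        self.combine = combine
        self.variance_floor = variance_floor

    def _as_data_matrix(self, X) -> DataMatrix:
        if isinstance(X, DataMatrix):
            data = X
        elif isinstance(X, pd.DataFrame):
            data = DataMatrix.from_array(X.to_numpy(dtype=float),
                                         node_labels=[str(c) for c in X.columns])
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be a 2-D array")
            if not np.isfinite(X).all():
                raise ValueError("X contains non-finite values")
            data = DataMatrix.from_array(X)
        if self.score == "bdeu" and data.mode != "binary":
            raise ValueError("score='bdeu' requires binary data")
        if self.score == "bic" and data.mode == "binary":
            data = DataMatrix(data.values, "continuous", data.node_labels)
        return data

    def _score_config(self, data: DataMatrix) -> ScoreConfig:
        if self.score == "auto":
            score_type = "bdeu" if data.mode == "binary" else "bic"
        elif self.score in ("bdeu", "bic"):
            score_type = self.score
        else:
            raise ValueError("score must be 'auto', 'bdeu' or 'bic'")
        return ScoreConfig(score_type=score_type, ess=self.ess,
                           max_parents=self.max_parents,
                           variance_floor=self.variance_floor)

    def fit(self, X, y=None):
        """Learn the microcircuit from an (n_samples, n_nodes) matrix."""
        data = self._as_data_matrix(X)
        cfg = self._score_config(data)
        active, dropped = filter_inactive_nodes(data)
        if dropped:
            warnings.warn(f"excluded {len(dropped)} constant node(s): {dropped}",
                          stacklevel=2)
        bc = learn_blankets(active, cfg)
        learned = combine_blankets(bc, rule=self.combine)
        full = Microcircuit(data.node_labels)
        adj = full.adjacency.copy()
        for a, b in learned.edges():
            i, j = full.index(a), full.index(b)
            adj[i, j] = adj[j, i] = True
        self.graph_ = Microcircuit(data.node_labels, adj)
        self.blankets_ = bc.blankets
        self.dropped_ = dropped
        self.n_features_in_ = data.n_nodes
        self.feature_names_in_ = np.asarray(data.node_labels, dtype=object)
        return self

    def fit_predict(self, X, y=None) -> Microcircuit:
        return self.fit(X).graph_
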