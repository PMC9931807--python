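"""Markov blanket discovery for a single target node (BNCIT).

BNCIT (Bayesian Network Classifier with Inverse Tree structure) detects
the Markov blanket of a node X_i by casting it as a leaf of a Bayesian
network whose only free structure is the parent set of X_i.  All other
nodes are candidate parents, and the detected blanket mb*(X_i) is the
parent set maximizing a decomposable fitness score:

    mb*(X_i) = argmax_mb  Gamma(mb(X_i), D)

For binary data the score is the BDeu marginal likelihood (Dirichlet
hyperparameters ess / (q * r) per cell, q parent configurations, r = 2
states).  For continuous data it is the BIC of a linear-Gaussian family.
The optimization is greedy hill-climbing over single-parent additions
and removals starting from the empty set; because the score penalizes
complexity, the detected blanket is compact and — under the leaf-node
architecture — a subset of the true blanket with high probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.special import gammaln

from .graphical_models import DataMatrix, MarkovBlanket

__all__ = [
    "ScoreConfig",
    "bdeu_family_score",
    "bic_family_score",
    "find_markov_blanket",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Configuration of the blanket-search fitness function.

    Parameters
    ----------
    score_type : {"bdeu", "bic"}
        BDeu for binary data, BIC (linear-Gaussian) for continuous data.
    ess : float
        BDeu equivalent sample size (prior strength). Default 1.0.
    max_parents : int or None
        Optional cap on the blanket size; None means unlimited.
    variance_floor : float
        Lower bound on the residual variance in the Gaussian family,
        guarding perfectly predictable targets.
    improvement_tol : float
        A hill-climbing move must improve the score by more than this.
    """

    score_type: str = "bdeu"
    ess: float = 1.0
    max_parents: int | None = None
    variance_floor: float = 1e-12
    improvement_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.score_type not in ("bdeu", "bic"):
            raise ValueError("score_type must be 'bdeu' or 'bic'")
        if not self.ess > 0:
            raise ValueError("ess must be positive")
        if self.max_parents is not None and self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if not self.variance_floor > 0:
            raise ValueError("variance_floor must be positive")


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a


def bdeu_family_score(child, parents=None, ess: float = 1.0) -> float:
    """BDeu log marginal likelihood of a binary child given binary parents.

    With q = 2^p parent configurations and r = 2 child states, each
    (configuration, state) cell gets Dirichlet hyperparameter
    ``ess / (q * r)``.  Unobserved configurations contribute zero.
    Higher is better.
    """
    child = _check_binary(child, "child")
    n = child.size
    if parents is None:
        parents = np.empty((n, 0))
    parents = _check_binary(parents, "parents")
    if parents.ndim != 2 or parents.shape[0] != n:
        raise ValueError("parents must be an (n_samples, n_parents) matrix")
    p = parents.shape[1]
    q = 2.0 ** p
    alpha_jk = ess / (q * 2.0)
    alpha_j = ess / q

    if p == 0:
        codes = np.zeros(n, dtype=np.int64)
    elif p <= 62:
        codes = (parents.astype(np.int64) @ (np.int64(1) << np.arange(p, dtype=np.int64)))
    else:  # fall back to row-wise unique for very wide parent sets
        _, codes = np.unique(parents, axis=0, return_inverse=True)

    uniq, inv = np.unique(codes, return_inverse=True)
    n_conf = uniq.size
    counts = np.zeros((n_conf, 2))
    np.add.at(counts, (inv, child.astype(np.intp)), 1.0)
    n_j = counts.sum(axis=1)
    score = (gammaln(alpha_j) - gammaln(alpha_j + n_j)
             + gammaln(alpha_jk + counts).sum(axis=1) - 2.0 * gammaln(alpha_jk))
    return float(score.sum())


def bic_family_score(child, parents=None, variance_floor: float = 1e-12) -> float:
    """BIC of a linear-Gaussian family: child ~ intercept + parents.

    The maximized Gaussian log-likelihood (ML residual variance, floored
    at ``variance_floor``) minus ``(k/2) log n`` with
    ``k = n_parents + 2`` (coefficients + intercept + variance).
    Collinear parent columns are dropped with a warning.  Higher is better.
    """
    child = np.asarray(child, dtype=float)
    n = child.size
    if parents is None:
        parents = np.empty((n, 0))
    parents = np.asarray(parents, dtype=float)
    if parents.ndim != 2 or parents.shape[0] != n:
        raise ValueError("parents must be an (n_samples, n_parents) matrix")
    p = parents.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n_samples > n_parents + 2 (n={n}, parents={p})")

    design = np.column_stack([np.ones(n), parents])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR identifies a maximal independent column subset
        _, _, piv = qr(design, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"collinear parent columns dropped ({design.shape[1] - rank} redundant)",
            stacklevel=2,
        )
        design = design[:, keep]
        p = design.shape[1] - 1
    beta, _, _, _ = np.linalg.lstsq(design, child, rcond=None)
    resid = child - design @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, variance_floor)
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - rss / (2.0 * sigma2)
    k = p + 2
    return float(loglik - 0.5 * k * np.log(n))


def _family_score(y, X, cols, cfg: ScoreConfig) -> float:
    parents = X[:, cols] if len(cols) else np.empty((y.size, 0))
    if cfg.score_type == "bdeu":
        return bdeu_family_score(y, parents, ess=cfg.ess)
    return bic_family_score(y, parents, variance_floor=cfg.variance_floor)


def find_markov_blanket(data: DataMatrix, target: str,
                        cfg: ScoreConfig | None = None) -> MarkovBlanket:
    """Greedy hill-climbing search for the Markov blanket of ``target``.

    Starts from the empty parent set; at each step applies the single
    addition or removal that most improves the leaf-family score, with
    ties broken toward the lowest column index; stops when no move
    improves the score by more than ``cfg.improvement_tol``.
    """
    cfg = cfg or ScoreConfig()
    expected = "binary" if cfg.score_type == "bdeu" else "continuous"
    if data.mode != expected:
        raise ValueError(
            f"score_type {cfg.score_type!r} requires {expected} data, "
            f"got {data.mode!r}"
        )
    t_idx = data.index(target)
    y = data.values[:, t_idx]
    if np.ptp(y) == 0.0:
        warnings.warn(f"target {target!r} is constant; returning empty blanket",
                      stacklevel=2)
        return MarkovBlanket(target, frozenset())
    X = data.values
    candidates = [i for i in range(data.n_nodes) if i != t_idx]

    current: list[int] = []
    current_score = _family_score(y, X, current, cfg)
    while True:
        best_gain = cfg.improvement_tol
        best_move: tuple[str, int] | None = None
        in_set = set(current)
        max_p = cfg.max_parents if cfg.max_parents is not None else len(candidates)
        for c in candidates:
            if c in in_set:
                continue
            if len(current) >= max_p:
                continue
            if cfg.score_type == "bic" and y.size <= len(current) + 3:
                continue
            gain = _family_score(y, X, current + [c], cfg) - current_score
            if gain > best_gain:
                best_gain, best_move = gain, ("add", c)
        for c in current:
            trial = [i for i in current if i != c]
            gain = _family_score(y, X, trial, cfg) - current_score
            if gain > best_gain:
                best_gain, best_move = gain, ("remove", c)
        if best_move is None:
            break
        op, c = best_move
        if op == "add":
            current = sorted(current + [c])
        else:
            current = [i for i in current if i != c]
        current_score += best_gain

    members = frozenset(data.node_labels[i] for i in current)
    return MarkovBlanket(target, members)
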