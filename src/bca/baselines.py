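"""Comparison methods: correlation thresholding and node-wise lasso logistic.

Two standard alternatives to BCA for functional-connectivity graphs:

* **Correlation graph** — all pairwise Spearman correlations, two-sided
  p-values, Benjamini-Hochberg FDR across all pairs jointly, and an edge
  wherever the adjusted p-value clears a significance level.  Fast, but
  blind to conditional independence, so indirect associations (A - C in
  a chain A - B - C) survive thresholding and the graph comes out dense.

* **Regression graph** — the eLasso / IsingFit construction: for every
  node, an L1-penalized logistic regression on all remaining nodes over
  a descending lambda grid, model selection by the extended BIC

      EBIC(lambda) = -2 loglik + k log n + 2 gamma k log(p - 1)

  (k = number of nonzero coefficients), and the per-node neighborhoods
  combined across nodes with an AND or OR rule.

Both are exposed as sklearn-style estimators plus thin functions, and a
small ensemble combiner intersects or unions two learned graphs.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._kernels import logistic_lasso_path
from .graphical_models import DataMatrix, Microcircuit

__all__ = [
    "CorrelationGraphLearner",
    "IsingRegressionGraphLearner",
    "correlation_graph",
    "regression_graph",
    "ensemble_combine",
]

_PERMUTATION_N = 30  # below this, Spearman p-values come from permutation
_EXACT_PERMUTATION_N = 7


def _spearman_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p; permutation-based for small n."""
    n = x.size
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        return np.nan, 1.0
    if n >= _PERMUTATION_N:
        if abs(rho) >= 1.0:
            return float(rho), 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return float(rho), float(min(p, 1.0))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_PERMUTATION_N:
        perms = itertools.permutations(ry)
        stats_ = [abs(np.corrcoef(rx, np.asarray(p))[0, 1]) for p in perms]
        p_val = np.mean([s >= observed - 1e-12 for s in stats_])
    else:
        rng = np.random.default_rng(971231)  # fixed: the p-value is a statistic
        count = 1
        n_perm = 9999
        for _ in range(n_perm):
            s = abs(np.corrcoef(rx, rng.permutation(ry))[0, 1])
            if s >= observed - 1e-12:
                count += 1
        p_val = count / (n_perm + 1)
    return float(rho), float(p_val)


def correlation_graph(data: DataMatrix, alpha: float = 0.05):
    """Spearman-correlation graph with BH-FDR thresholding.

    Returns ``(Microcircuit, rho_matrix, p_adjusted_matrix)``.  Pairs
    involving a constant column get p = 1 (no edge) with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    X = data.values
    n, m = X.shape
    labels = data.node_labels
    constant = np.ptp(X, axis=0) == 0.0
    if constant.any():
        warnings.warn(
            f"constant column(s) {[l for l, c in zip(labels, constant) if c]}: "
            "their pairs get no edge", stacklevel=2)
    pairs = list(itertools.combinations(range(m), 2))
    rho = np.full((m, m), np.nan)
    np.fill_diagonal(rho, 1.0)
    pvals = np.ones(len(pairs))

    if n >= _PERMUTATION_N and not constant.any():
        # vectorized: Spearman is Pearson on ranks
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        C = np.corrcoef(ranks, rowvar=False)
        for k, (i, j) in enumerate(pairs):
            r = C[i, j]
            rho[i, j] = rho[j, i] = r
            if abs(r) >= 1.0:
                pvals[k] = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                pvals[k] = min(2.0 * stats.t.sf(abs(t), df=n - 2), 1.0)
    else:
        for k, (i, j) in enumerate(pairs):
            if constant[i] or constant[j]:
                rho[i, j] = rho[j, i] = np.nan
                pvals[k] = 1.0
                continue
            r, p = _spearman_pvalue(X[:, i], X[:, j])
            rho[i, j] = rho[j, i] = r
            pvals[k] = p

    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    p_adj_mat = np.ones((m, m))
    np.fill_diagonal(p_adj_mat, 0.0)
    adj = np.zeros((m, m), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        p_adj_mat[i, j] = p_adj_mat[j, i] = p_adj[k]
        if reject[k]:
            adj[i, j] = adj[j, i] = True
    return Microcircuit(labels, adj), rho, p_adj_mat


def regression_graph(data: DataMatrix, gamma: float = 0.25, rule: str = "and",
                     n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
                     standardize: bool = True):
    """eLasso graph: node-wise L1 logistic regressions + EBIC selection.

    Predictors are standardized to unit variance before penalization by
    default, matching the glmnet convention of the reference
    implementation; the selected support is unaffected by the
    back-transform.  Returns ``(Microcircuit, neighborhoods)`` where
    ``neighborhoods`` maps each node to the predictors selected by the
    EBIC-minimizing lambda of its regression.
    """
    if data.mode != "binary":
        raise ValueError("the regression baseline requires binary data")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    X = np.ascontiguousarray(data.values)
    n, m = X.shape
    labels = data.node_labels
    neighborhoods: dict[str, set[str]] = {}
    for s in range(m):
        y = X[:, s]
        others = [j for j in range(m) if j != s]
        D = np.ascontiguousarray(X[:, others])
        if np.ptp(y) == 0.0:
            warnings.warn(f"node {labels[s]!r} is constant: no selection",
                          stacklevel=2)
            neighborhoods[labels[s]] = set()
            continue
        sd = D.std(axis=0)
        usable = sd > 0.0
        D = np.ascontiguousarray(D[:, usable])
        others = [j for j, u in zip(others, usable) if u]
        # standardized-scale penalty via per-feature factors sd_j; the
        # selected support equals that of the explicitly standardized fit
        pf = sd[usable] if standardize else np.ones(D.shape[1])
        grad0 = np.abs(D.T @ (y - y.mean())) / (y.size * pf)
        lam_max = float(grad0.max(initial=0.0)) or 1e-3
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        coefs, _, logliks = logistic_lasso_path(D, y, lambdas,
                                                np.ascontiguousarray(pf),
                                                1e-4, 500)
        p_pred = m - 1
        best_ebic = np.inf
        best_support: set[int] = set()
        for li in range(lambdas.size):
            if not np.isfinite(logliks[li]) or not np.isfinite(coefs[li]).all():
                continue  # degenerate fit: no selection at this lambda
            k = int(np.count_nonzero(coefs[li]))
            ebic = (-2.0 * logliks[li] + k * math.log(n)
                    + 2.0 * gamma * k * math.log(p_pred))
            if ebic < best_ebic - 1e-12:
                best_ebic = ebic
                best_support = {others[j] for j in np.nonzero(coefs[li])[0]}
        neighborhoods[labels[s]] = {labels[j] for j in best_support}

    adj = np.zeros((m, m), dtype=bool)
    idx = {l: i for i, l in enumerate(labels)}
    for a in labels:
        for b in neighborhoods[a]:
            i, j = idx[a], idx[b]
            if rule == "or" or a in neighborhoods[b]:
                adj[i, j] = adj[j, i] = True
    return Microcircuit(labels, adj), neighborhoods


def ensemble_combine(a: Microcircuit, b: Microcircuit, mode: str) -> Microcircuit:
    """Edge-set intersection (``"and"``) or union (``"or"``) of two graphs."""
    if a.node_labels != b.node_labels:
        raise ValueError("graphs must share the same node set")
    mode = mode.lower()
    if mode == "and":
        adj = a.adjacency & b.adjacency
    elif mode == "or":
        adj = a.adjacency | b.adjacency
    else:
        raise ValueError("mode must be 'and' or 'or'")
    return Microcircuit(a.node_labels, adj)


class CorrelationGraphLearner(BaseEstimator):
    """Spearman correlation graph with BH-FDR edge selection.

    Attributes after ``fit``: ``graph_``, ``correlations_``,
    ``pvalues_adjusted_``, ``feature_names_in_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        data = _as_data_matrix(X)
        self.graph_, self.correlations_, self.pvalues_adjusted_ = \
            correlation_graph(data, alpha=self.alpha)
        self.n_features_in_ = data.n_nodes
        self.feature_names_in_ = np.asarray(data.node_labels, dtype=object)
        return self

    def fit_predict(self, X, y=None) -> Microcircuit:
        return self.fit(X).graph_


class IsingRegressionGraphLearner(BaseEstimator):
    """eLasso: node-wise L1 logistic regression with EBIC model selection.

    Parameters follow van Borkulo's construction: ``gamma`` is the EBIC
    hyperparameter (default 0.25) and ``rule`` the cross-node
    neighborhood combination (default ``"and"``).
    """

    def __init__(self, gamma: float = 0.25, rule: str = "and",
                 n_lambdas: int = 100, lambda_min_ratio: float = 1e-3):
        self.gamma = gamma
        self.rule = rule
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, X, y=None):
        data = _as_data_matrix(X)
        self.graph_, self.neighborhoods_ = regression_graph(
            data, gamma=self.gamma, rule=self.rule,
            n_lambdas=self.n_lambdas, lambda_min_ratio=self.lambda_min_ratio)
        self.n_features_in_ = data.n_nodes
        self.feature_names_in_ = np.asarray(data.node_labels, dtype=object)
        return self

    def fit_predict(self, X, y=None) -> Microcircuit:
        return self.fit(X).graph_


def _as_data_matrix(X) -> DataMatrix:
    if isinstance(X, DataMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return DataMatrix.from_array(X.to_numpy(dtype=float),
                                     node_labels=[str(c) for c in X.columns])
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    return DataMatrix.from_array(X)
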