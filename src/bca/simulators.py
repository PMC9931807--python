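"""Synthetic data generators: Ising sampling, LIF networks, Gaussian fields.

All experiments in this package run on simulated data with a known
ground-truth microcircuit, produced here:

* a 6-node Ising model with fixed couplings, sampled by single-site
  Metropolis-Hastings;
* a 100-neuron feed-forward leaky integrate-and-fire (LIF) network in
  which each of 50 downstream neurons (group B) listens to two randomly
  chosen upstream neurons (group A); the reference microcircuit over
  group B connects neurons sharing at least one parent;
* Gaussian Markov network samples for the continuous mode;
* a two-subtype trial collection emulating a per-trial calcium-imaging
  study, for the subtype-detection pipeline;
* forward sampling of small binary Bayesian networks, used as a
  benchmark for blanket discovery.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import mh_sample_ising
from .graphical_models import (
    DataMatrix,
    DirectedGraph,
    GaussianMNParams,
    IsingParams,
    Microcircuit,
)

__all__ = [
    "LIFConfig",
    "LIFResult",
    "six_node_model",
    "sample_ising_mh",
    "simulate_lif",
    "random_wiring",
    "shared_parent_graph",
    "sample_gaussian_mn",
    "gaussian_mn_from_graph",
    "gaussian_chain_model",
    "default_trial_templates",
    "generate_trial_collection",
    "benchmark_collider_dag",
    "sample_binary_dag",
]


# ---------------------------------------------------------------------------
# 6-node Ising model


def six_node_model() -> tuple[IsingParams, Microcircuit]:
    """The 6-node Ising benchmark: fixed couplings, zero fields, beta = 2.

    Couplings: w12 = w14 = w23 = w34 = 0.5, w45 = -0.8, w56 = 0.9.  The
    ground-truth microcircuit has exactly these 6 edges (9 empty pairs).
    """
    W = np.zeros((6, 6))
    for i, j, w in [(0, 1, 0.5), (0, 3, 0.5), (1, 2, 0.5),
                    (2, 3, 0.5), (3, 4, -0.8), (4, 5, 0.9)]:
        W[i, j] = W[j, i] = w
    params = IsingParams(r=np.zeros(6), W=W, beta=2.0)
    return params, params.structure()


def sample_ising_mh(params: IsingParams, n_samples: int,
                    burn_in: int = 5000, thin: int = 10,
                    seed: int = 0) -> DataMatrix:
    """Metropolis-Hastings samples from an Ising model with fields.

    ``burn_in`` and ``thin`` are measured in sweeps (one sweep = M
    proposed single-site flips).  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    values = mh_sample_ising(
        np.ascontiguousarray(params.W, dtype=np.float64),
        np.ascontiguousarray(params.r, dtype=np.float64),
        float(params.beta), int(n_samples), int(burn_in), int(thin),
        int(seed) % (2**32),
    )
    labels = tuple(f"X{i + 1}" for i in range(params.n_nodes))
    return DataMatrix(values, "binary", labels)


# ---------------------------------------------------------------------------
# Feed-forward LIF network


@dataclass(frozen=True)
class LIFConfig:
    """Parameters of the feed-forward LIF simulation.

    Units: time constants and ``dt`` in milliseconds; potentials in
    threshold units (the spike threshold is 1).  Group A (upstream)
    neurons are driven by an external stimulus presented every 3 or 4
    frames; each group-B neuron receives a synaptic increment ``a`` one
    frame after any of its two parent A-neurons fires.

    ``stimulus_gain`` and ``stimulus_response_prob`` shape the drive: on
    a stimulus frame each A-neuron independently responds with
    probability ``stimulus_response_prob``, receiving ``stimulus_gain``
    added to its membrane potential.  The probabilistic response models
    trial-to-trial synaptic variability; a deterministic drive would
    synchronize group A perfectly and make the group-B structure
    unidentifiable.
    """

    n_A: int = 50
    n_B: int = 50
    tau_A_mean: float = 20.0
    tau_A_sd: float = 5.0
    tau_B: float = 100.0
    sigma: float = 0.2
    a: float = 0.8
    dt: float = 5.0
    threshold: float = 1.0
    v_rest: float = 0.0
    stimulus_gain: float = 1.2
    stimulus_response_prob: float = 0.35
    parents_per_B: int = 2
    n_frames: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tau_A_mean, self.tau_B, self.dt) <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.parents_per_B > self.n_A:
            raise ValueError("parents_per_B cannot exceed n_A")


@dataclass(frozen=True)
class LIFResult:
    """Output of :func:`simulate_lif`."""

    data: DataMatrix
    wiring: dict[str, tuple[str, ...]]
    ground_truth: Microcircuit  # shared-parent graph over retained B neurons
    retained_b: tuple[str, ...]
    silent: tuple[str, ...]


def random_wiring(n_A: int, n_B: int, parents_per_B: int = 2,
                  seed: int = 0) -> dict[str, tuple[str, ...]]:
    """Each B-neuron picks ``parents_per_B`` distinct A-parents uniformly."""
    rng = np.random.default_rng(seed)
    wiring = {}
    for b in range(n_B):
        parents = rng.choice(n_A, size=parents_per_B, replace=False)
        wiring[f"B{b + 1}"] = tuple(f"A{a + 1}" for a in sorted(parents))
    return wiring


def shared_parent_graph(wiring: dict[str, tuple[str, ...]],
                        retained=None) -> Microcircuit:
    """Edge between two B-neurons iff they share at least one A-parent."""
    if retained is None:
        retained = list(wiring.keys())
    retained = list(retained)
    unknown = set(retained) - set(wiring)
    if unknown:
        raise KeyError(f"retained labels not in wiring: {sorted(unknown)}")
    edges = []
    for i, bi in enumerate(retained):
        for bj in retained[i + 1:]:
            if set(wiring[bi]) & set(wiring[bj]):
                edges.append((bi, bj))
    return Microcircuit.from_edges(tuple(retained), edges)


def _stimulus_frames(n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stimulus presented every 3 or 4 frames, gaps chosen uniformly."""
    mask = np.zeros(n_frames, dtype=bool)
    t = int(rng.integers(3, 5))
    while t < n_frames:
        mask[t] = True
        t += int(rng.integers(3, 5))
    return mask


def simulate_lif(cfg: LIFConfig | None = None) -> LIFResult:
    """Euler-integrate the feed-forward LIF network frame by frame.

    Per frame: membrane leak toward rest plus Gaussian noise
    ``sigma * eps * tau**-0.5``; stimulus drive to responding A-neurons;
    synaptic increments to B-neurons whose parents fired on the previous
    frame; threshold crossing (V > 1) emits a spike and resets V to
    rest.  Spikes are binarized per frame into the activity matrix.
    """
    cfg = cfg or LIFConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_A + cfg.n_B
    tau = np.empty(n)
    tau[:cfg.n_A] = np.clip(
        rng.normal(cfg.tau_A_mean, cfg.tau_A_sd, cfg.n_A), 1.0, None)
    tau[cfg.n_A:] = cfg.tau_B

    wiring_idx = {}
    for b in range(cfg.n_B):
        parents = rng.choice(cfg.n_A, size=cfg.parents_per_B, replace=False)
        wiring_idx[b] = np.sort(parents)
    stim = _stimulus_frames(cfg.n_frames, rng)

    parent_matrix = np.zeros((cfg.n_B, cfg.n_A))
    for b, parents in wiring_idx.items():
        parent_matrix[b, parents] = 1.0

    V = np.full(n, cfg.v_rest, dtype=float)
    spikes = np.zeros((cfg.n_frames, n), dtype=float)
    noise_scale = cfg.sigma / np.sqrt(tau)
    prev_a_spikes = np.zeros(cfg.n_A)
    for t in range(cfg.n_frames):
        V += cfg.dt * (cfg.v_rest - V) / tau
        V += noise_scale * rng.standard_normal(n)
        if stim[t]:
            responding = rng.random(cfg.n_A) < cfg.stimulus_response_prob
            V[:cfg.n_A] += cfg.stimulus_gain * responding
        V[cfg.n_A:] += cfg.a * (parent_matrix @ prev_a_spikes)
        fired = V > cfg.threshold
        spikes[t] = fired
        V[fired] = cfg.v_rest
        prev_a_spikes = fired[:cfg.n_A].astype(float)

    labels = tuple([f"A{i + 1}" for i in range(cfg.n_A)]
                   + [f"B{i + 1}" for i in range(cfg.n_B)])
    data = DataMatrix(spikes, "binary", labels)
    wiring = {f"B{b + 1}": tuple(f"A{a + 1}" for a in wiring_idx[b])
              for b in range(cfg.n_B)}
    b_labels = labels[cfg.n_A:]
    b_active = spikes[:, cfg.n_A:].any(axis=0)
    retained = tuple(l for l, act in zip(b_labels, b_active) if act)
    silent = tuple(l for l, act in zip(b_labels, b_active) if not act)
    gt = shared_parent_graph(wiring, retained)
    return LIFResult(data, wiring, gt, retained, silent)


# ---------------------------------------------------------------------------
# Gaussian Markov networks


def sample_gaussian_mn(params: GaussianMNParams, n: int,
                       seed: int = 0) -> DataMatrix:
    """Draw n multivariate-normal samples (continuous mode)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.multivariate_normal(params.mu, params.sigma, size=n,
                                     method="cholesky")
    labels = tuple(f"X{i + 1}" for i in range(params.n_nodes))
    return DataMatrix(values, "continuous", labels)


def gaussian_mn_from_graph(g: Microcircuit, coupling: float = 0.35,
                           min_eigenvalue: float = 0.05) -> GaussianMNParams:
    """Zero-mean Gaussian Markov network with the given structure.

    The precision matrix has unit diagonal and ``-coupling`` on every
    edge; if that is not comfortably positive definite the diagonal is
    loaded until the smallest eigenvalue reaches ``min_eigenvalue``.
    """
    n = g.n_nodes
    Q = np.eye(n)
    for a, b in g.edges():
        i, j = g.index(a), g.index(b)
        Q[i, j] = Q[j, i] = -coupling
    w_min = float(np.linalg.eigvalsh(Q)[0])
    if w_min < min_eigenvalue:
        Q += (min_eigenvalue - w_min) * np.eye(n)
    sigma = np.linalg.inv(Q)
    sigma = 0.5 * (sigma + sigma.T)
    return GaussianMNParams(mu=np.zeros(n), sigma=sigma)


def gaussian_chain_model(n_nodes: int = 10,
                         coupling: float = 0.45) -> tuple[GaussianMNParams, Microcircuit]:
    """A chain X1 - X2 - ... - Xn with tridiagonal precision."""
    labels = tuple(f"X{i + 1}" for i in range(n_nodes))
    chain = Microcircuit.from_edges(
        labels, [(labels[i], labels[i + 1]) for i in range(n_nodes - 1)])
    return gaussian_mn_from_graph(chain, coupling=coupling), chain


# ---------------------------------------------------------------------------
# Two-subtype trial collection (per-trial microcircuit study surrogate)


def default_trial_templates(n_nodes: int = 20,
                            coupling: float = 0.35) -> tuple[GaussianMNParams, GaussianMNParams]:
    """Two well-separated 2-regular template structures on n_nodes nodes.

    Template A is the ring (i, i+1); template B pairs each node with the
    one ``n_nodes // 3 + 1`` steps away, giving an edge set disjoint
    from the ring.
    """
    labels = tuple(f"X{i + 1}" for i in range(n_nodes))
    ring = Microcircuit.from_edges(
        labels, [(labels[i], labels[(i + 1) % n_nodes]) for i in range(n_nodes)])
    step = n_nodes // 3 + 1
    cross = Microcircuit.from_edges(
        labels,
        {tuple(sorted((labels[i], labels[(i + step) % n_nodes])))
         for i in range(n_nodes)})
    return (gaussian_mn_from_graph(ring, coupling=coupling),
            gaussian_mn_from_graph(cross, coupling=coupling))


def _perturb_structure(g: Microcircuit, flip_noise: float,
                       rng: np.random.Generator) -> Microcircuit:
    """Toggle a fraction ``flip_noise`` of edges: remove k, add k elsewhere."""
    edges = sorted(g.edges())
    k = int(round(flip_noise * len(edges)))
    if k == 0:
        return g
    labels = g.node_labels
    all_pairs = [(labels[i], labels[j])
                 for i in range(len(labels)) for j in range(i + 1, len(labels))]
    non_edges = [p for p in all_pairs if p not in set(edges)]
    drop = {edges[i] for i in rng.choice(len(edges), size=k, replace=False)}
    add = {non_edges[i] for i in rng.choice(len(non_edges), size=min(k, len(non_edges)),
                                            replace=False)}
    new_edges = (set(edges) - drop) | add
    return Microcircuit.from_edges(labels, new_edges)


def generate_trial_collection(n_trials_per_type: int = 25,
                              template_a: GaussianMNParams | None = None,
                              template_b: GaussianMNParams | None = None,
                              flip_noise: float = 0.1,
                              n_samples_per_trial: int = 300,
                              coupling: float = 0.35,
                              seed: int = 0) -> tuple[list[DataMatrix], list[str]]:
    """Per-trial activity matrices from two structural subtypes.

    Each trial perturbs a fraction ``flip_noise`` of its template's
    precision edges (toggling them off and toggling an equal number of
    empty pairs on), rebuilds a positive-definite precision, and draws
    ``n_samples_per_trial`` continuous samples.  Returns the list of
    trial matrices and the aligned list of type labels
    (``"type_a"`` / ``"type_b"``).
    """
    if template_a is None or template_b is None:
        ta, tb = default_trial_templates(coupling=coupling)
        template_a = template_a or ta
        template_b = template_b or tb
    if template_a.n_nodes != template_b.n_nodes:
        raise ValueError("templates must share the node count")
    rng = np.random.default_rng(seed)
    structures = {"type_a": template_a.structure(),
                  "type_b": template_b.structure()}
    trials: list[DataMatrix] = []
    labels: list[str] = []
    for ttype in ("type_a", "type_b"):
        for _ in range(n_trials_per_type):
            g = _perturb_structure(structures[ttype], flip_noise, rng)
            params = gaussian_mn_from_graph(g, coupling=coupling)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            trials.append(sample_gaussian_mn(params, n_samples_per_trial,
                                             seed=sub_seed))
            labels.append(ttype)
    return trials, labels


# ---------------------------------------------------------------------------
# Binary Bayesian-network benchmark


def benchmark_collider_dag() -> tuple[DirectedGraph, dict]:
    """A 5-node DAG (A -> C <- B, C -> D <- E) with additive Bernoulli CPTs.

    Root marginals are 0.5; each parent shifts its child's firing
    probability by 0.4 (base 0.1), giving strong, individually
    detectable dependences.  The Markov blanket of C is {A, B, D, E}:
    parents A and B, child D, and D's co-parent E.
    """
    g = DirectedGraph(("A", "B", "C", "D", "E"),
                      {"C": {"A", "B"}, "D": {"C", "E"}})
    cpts = {
        "A": ((), np.array([0.5])),
        "B": ((), np.array([0.5])),
        "E": ((), np.array([0.5])),
        # index = sum of 2^k over parents with value 1, parent order as given
        "C": (("A", "B"), np.array([0.1, 0.5, 0.5, 0.9])),
        "D": (("C", "E"), np.array([0.1, 0.5, 0.5, 0.9])),
    }
    return g, cpts


def sample_binary_dag(g: DirectedGraph, cpts: dict, n: int,
                      seed: int = 0) -> DataMatrix:
    """Forward-sample a binary Bayesian network.

    ``cpts`` maps each node to ``(parent_order, probs)`` where ``probs``
    has length ``2 ** len(parent_order)`` and is indexed by the binary
    code of the parent values (first parent = least significant bit).
    """
    rng = np.random.default_rng(seed)
    order = _topological_order(g)
    values = {}
    for node in order:
        parent_order, probs = cpts[node]
        if set(parent_order) != set(g.parents(node)):
            raise ValueError(f"CPT parents for {node!r} do not match the DAG")
        code = np.zeros(n, dtype=np.int64)
        for k, p in enumerate(parent_order):
            code += (values[p].astype(np.int64) << k)
        values[node] = (rng.random(n) < probs[code]).astype(float)
    mat = np.column_stack([values[l] for l in g.node_labels])
    return DataMatrix(mat, "binary", g.node_labels)


def _topological_order(g: DirectedGraph) -> list[str]:
    indeg = {v: len(g.parent_sets[v]) for v in g.node_labels}
    children = g.children_map()
    order = []
    queue = sorted(v for v, d in indeg.items() if d == 0)
    while queue:
        v = queue.pop(0)
        order.append(v)
        for c in sorted(children[v]):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return order
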