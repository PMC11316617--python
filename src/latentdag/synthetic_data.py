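"""Ground-truth generators for end-to-end testing of the pipeline.

Emulates the statistical structure of a z-normalized genes-by-conditions
perturbation screen: a known linear SEM over a ground-truth DAG generates
observational expression, per-gene knockdown conditions are produced by
shifting a gene's exogenous term and propagating through the SEM, and
per-gene scalar properties correlated with graph neighborhoods stand in for
external gene-level targets such as conservation scores.

Convention (shared with the whole package): edge ``i -> j`` means ``w_ij != 0``
and gene ``i`` is a parent of gene ``j``; samples are rows, genes columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np

from .containers import (
    DagNetwork,
    ExpressionMatrix,
    GeneNetwork,
    PerturbationDataset,
)

__all__ = [
    "GroundTruth",
    "simulate_dag",
    "assign_weights",
    "simulate_expression",
    "simulate_perturbation_dataset",
    "simulate_node_property",
    "simulate_modular_dag",
    "structure_metrics",
]


def _gene_labels(d: int) -> tuple[str, ...]:
    width = len(str(d - 1))
    return tuple(f"g{i:0{width}d}" for i in range(d))


@dataclass(frozen=True)
class GroundTruth:
    """A known SEM: weights, the DAG they support, and noise scales."""

    weights: np.ndarray
    gene_ids: tuple[str, ...]
    noise_sd: np.ndarray
    module_labels: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (w.shape[0],)
        ).copy()
        object.__setattr__(self, "noise_sd", sd)
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be positive")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal weights must be zero")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("ground-truth support is not acyclic")

    @property
    def d(self) -> int:
        return self.weights.shape[0]

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        ii, jj = np.nonzero(self.weights)
        return frozenset(
            (self.gene_ids[i], self.gene_ids[j]) for i, j in zip(ii, jj)
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        ii, jj = np.nonzero(self.weights)
        g.add_edges_from(
            (self.gene_ids[i], self.gene_ids[j]) for i, j in zip(ii, jj)
        )
        return g

    def to_dag_network(self) -> DagNetwork:
        return DagNetwork(gene_ids=self.gene_ids, edges=self.edges)

    def skeleton(self) -> GeneNetwork:
        return self.to_dag_network().skeleton()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            ii, jj = np.nonzero(self.weights)
            for i, j in sorted(zip(ii.tolist(), jj.tolist())):
                fh.write(
                    f"{self.gene_ids[i]}\t{self.gene_ids[j]}\t{self.weights[i, j]:g}\n"
                )


def simulate_dag(
    d: int,
    m: int,
    model: Literal["erdos_renyi", "scale_free"] = "erdos_renyi",
    seed: int | None = None,
) -> GroundTruth:
    """Sample a random DAG with ``d`` genes and (about) ``m`` edges.

    ``erdos_renyi`` draws exactly ``m`` distinct ordered pairs consistent
    with a random topological order. ``scale_free`` grows a
    preferential-attachment graph and orients its edges along a random
    topological order; its mechanism can only approximate ``m``.

    The returned :class:`GroundTruth` has unit placeholder weights; use
    :func:`assign_weights` to draw SEM coefficients.
    """
    if d < 2:
        raise ValueError("need at least 2 genes")
    max_m = d * (d - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"edge count m={m} outside [0, {max_m}] for d={d}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(d)

    if model == "erdos_renyi":
        # sample m of the d*(d-1)/2 position pairs (a<b), orient along order
        flat = rng.choice(max_m, size=m, replace=False)
        pairs = []
        # decode the a<b pair index k: row a has (d-1-a) entries
        for k in sorted(flat.tolist()):
            a = 0
            offset = k
            while offset >= d - 1 - a:
                offset -= d - 1 - a
                a += 1
            b = a + 1 + offset
            pairs.append((a, b))
    elif model == "scale_free":
        k_attach = max(1, round(m / max(d - 1, 1)))
        g = nx.barabasi_albert_graph(d, min(k_attach, d - 1), seed=int(rng.integers(2**31)))
        pairs = [(min(a, b), max(a, b)) for a, b in g.edges()]
    else:
        raise ValueError(f"unknown model {model!r}")

    W = np.zeros((d, d))
    for a, b in pairs:
        # position a precedes b in the random topological order
        W[order[a], order[b]] = 1.0
    return GroundTruth(weights=W, gene_ids=_gene_labels(d), noise_sd=np.ones(d))


def assign_weights(
    gt: GroundTruth,
    magnitude_range: tuple[float, float] = (0.5, 2.0),
    seed: int | None = None,
    positive: bool = False,
) -> GroundTruth:
    """Draw SEM coefficients uniformly from ``±[lo, hi]`` on the DAG's edges.

    ``positive=True`` restricts to ``+[lo, hi]`` (co-activating regulation,
    appropriate for co-functional module fixtures).
    """
    lo, hi = magnitude_range
    if not 0 < lo <= hi:
        raise ValueError(
            "need 0 < lo <= hi: zero-magnitude edges are unidentifiable"
        )
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(gt.weights)
    W = np.zeros_like(gt.weights)
    mags = rng.uniform(lo, hi, size=len(ii))
    signs = np.ones(len(ii)) if positive else rng.choice([-1.0, 1.0], size=len(ii))
    W[ii, jj] = mags * signs
    return GroundTruth(
        weights=W,
        gene_ids=gt.gene_ids,
        noise_sd=gt.noise_sd,
        module_labels=gt.module_labels,
    )


def simulate_expression(
    gt: GroundTruth, n: int, seed: int | None = None
) -> ExpressionMatrix:
    """Draw ``n`` i.i.d. samples of the linear Gaussian SEM ``x = W^T x + e``.

    Equivalently ``X = E (I - W)^{-1}`` with ``E`` having independent
    ``N(0, noise_sd_j^2)`` columns, so ``X (I - W) = E`` up to round-off.
    """
    rng = np.random.default_rng(seed)
    d = gt.d
    E = rng.normal(size=(n, d)) * gt.noise_sd
    X = np.linalg.solve((np.eye(d) - gt.weights).T, E.T).T
    return ExpressionMatrix(values=X, gene_ids=gt.gene_ids)


def simulate_perturbation_dataset(
    gt: GroundTruth,
    n_control: int = 2000,
    knockdown_shift: float = -5.0,
    n_per_condition: int = 2000,
    seed: int | None = None,
) -> PerturbationDataset:
    """Simulate a perturbation screen: controls plus one knockdown per gene.

    Under knockdown of gene ``g`` the exogenous term of ``g`` has mean
    ``knockdown_shift`` (< 0: knockdown lowers expression); effects propagate
    through the SEM to descendants only. Per-condition mean expression of
    every gene is recorded.
    """
    if knockdown_shift >= 0:
        raise ValueError("knockdown_shift must be negative")
    rng = np.random.default_rng(seed)
    d = gt.d
    A = np.eye(d) - gt.weights  # X = E A^{-1}

    E_ctrl = rng.normal(size=(n_control, d)) * gt.noise_sd
    control = np.linalg.solve(A.T, E_ctrl.T).T

    means: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(gt.gene_ids):
        E = rng.normal(size=(n_per_condition, d)) * gt.noise_sd
        E[:, gi] += knockdown_shift
        Xg = np.linalg.solve(A.T, E.T).T
        means[gene] = Xg.mean(axis=0)
    return PerturbationDataset(
        gene_ids=gt.gene_ids, control=control, condition_means=means
    )


def simulate_node_property(
    network: GeneNetwork,
    features: ExpressionMatrix,
    mix: float = 0.8,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> dict[str, float]:
    """Per-gene scalar target blending own and neighbor feature means.

    ``y_i = mix * mean_{j in N(i)} f_j + (1 - mix) * f_i + eps`` where ``f_i``
    is gene *i*'s mean feature value; isolated genes use their own mean for
    the neighbor term. With ``mix`` near 1 the target carries graph signal a
    neighborhood-aware model can exploit.
    """
    if not 0 <= mix <= 1:
        raise ValueError("mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    f = {g: float(features.column(g).mean()) for g in features.gene_ids}
    y: dict[str, float] = {}
    adj: dict[str, set[str]] = {g: set() for g in network.genes}
    for u, v in network.edges:
        adj[u].add(v)
        adj[v].add(u)
    for g in features.gene_ids:
        nbrs = adj.get(g, set())
        nbr_term = (
            float(np.mean([f[j] for j in sorted(nbrs)])) if nbrs else f[g]
        )
        y[g] = mix * nbr_term + (1 - mix) * f[g] + rng.normal(0, noise_sd)
    return y


def simulate_modular_dag(
    n_modules: int = 5,
    module_size: int = 12,
    within_edges: int = 18,
    magnitude_range: tuple[float, float] = (0.5, 2.0),
    seed: int | None = None,
) -> GroundTruth:
    """A DAG of disjoint, densely connected modules with known labels.

    Modules share no edges, so the ground-truth partition is exactly the
    connected-component structure; weights are positive (co-activating), so
    module members are positively co-expressed. Used for clustering
    benchmarks.
    """
    rng = np.random.default_rng(seed)
    d = n_modules * module_size
    genes = _gene_labels(d)
    W = np.zeros((d, d))
    labels: dict[str, int] = {}
    for mod in range(n_modules):
        base = mod * module_size
        sub = simulate_dag(
            module_size, within_edges, "erdos_renyi", seed=int(rng.integers(2**31))
        )
        sub = assign_weights(
            sub, magnitude_range, seed=int(rng.integers(2**31)), positive=True
        )
        W[base : base + module_size, base : base + module_size] = sub.weights
        for k in range(module_size):
            labels[genes[base + k]] = mod
    return GroundTruth(
        weights=W, gene_ids=genes, noise_sd=np.ones(d), module_labels=labels
    )


def structure_metrics(learned: DagNetwork, truth: DagNetwork) -> dict[str, float]:
    """Structural Hamming distance and directed-edge precision/recall/F1.

    SHD counts edge insertions, deletions, and reversals needed to turn the
    learned DAG into the truth (a reversed pair counts once).
    """
    if set(learned.gene_ids) != set(truth.gene_ids):
        raise ValueError("learned and truth are over different gene universes")
    E1, E2 = set(learned.edges), set(truth.edges)
    extra = E1 - E2
    missing = E2 - E1
    reversals = {(u, v) for u, v in extra if (v, u) in missing}
    shd = len(extra) + len(missing) - len(reversals)
    tp = len(E1 & E2)
    precision = tp / len(E1) if E1 else (1.0 if not E2 else 0.0)
    recall = tp / len(E2) if E2 else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "shd": float(shd),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
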