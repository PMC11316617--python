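"""Node-embedding extraction and density-based gene clustering.

The embedding of a gene is the post-activation output of the trained model's
last graph-convolution layer. Clustering follows a three-step pipeline:
per-dimension standardization, a neighborhood-preserving low-dimensional
embedding (20 dimensions, 7 neighbors by default), and density-based
hierarchical clustering (single linkage over mutual-reachability distances)
cut to a requested number of flat clusters with small clusters pruned to
noise (label -1).

The low-dimensional embedding backend is pluggable: ``"umap"`` (default, a
neighbor-graph embedding in the same family as minimum-distortion
embeddings), ``"spectral"`` (spectral embedding of the k-nearest-neighbor
graph), or ``"none"`` (cluster the standardized data directly).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix
from .gnn_benchmark import NodeRegressor
from .network_io import PairScoreTable
from .stats import WelchResult, welch_t_test

__all__ = [
    "ClusterResult",
    "extract_embeddings",
    "cluster_embeddings",
    "within_cluster_pair_scores",
    "WithinClusterScores",
]


def extract_embeddings(
    model: NodeRegressor, features: np.ndarray, prop: np.ndarray
) -> np.ndarray:
    """Genes-by-k embedding from the last convolution layer (post-activation).

    Row order follows the gene universe order of ``features``; ``k`` is the
    configured size of the last convolution layer.
    """
    return model.conv_output(features, prop).data.copy()


@dataclass(frozen=True)
class ClusterResult:
    """Flat clustering of genes; ``-1`` marks unclustered (noise) genes."""

    labels: Mapping[str, int]
    n_clusters: int
    params: Mapping[str, object]

    def __post_init__(self) -> None:
        ids = sorted({c for c in self.labels.values() if c >= 0})
        if ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def unclustered(self) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == -1)

    def members(self, cluster_id: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster_id)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.labels.items():
            if c >= 0:
                out.setdefault(c, []).append(g)
        return {c: sorted(v) for c, v in out.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcluster_id\n")
            for g in sorted(self.labels):
                fh.write(f"{g}\t{self.labels[g]}\n")


def _embed(
    Z: np.ndarray,
    backend: str,
    embed_dim: int,
    n_neighbors: int,
    repulsive_fraction: float,
    seed: int,
) -> np.ndarray:
    n = Z.shape[0]
    dim = min(embed_dim, max(2, n - 2), Z.shape[1])
    if backend == "none" or Z.shape[1] <= dim:
        return Z
    if backend == "spectral":
        from sklearn.manifold import SpectralEmbedding

        se = SpectralEmbedding(
            n_components=dim,
            n_neighbors=min(n_neighbors, n - 1),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return se.fit_transform(Z)
    if backend == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=dim,
            n_neighbors=min(n_neighbors, n - 1),
            repulsion_strength=repulsive_fraction,
            random_state=seed,
            metric="euclidean",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return reducer.fit_transform(Z)
    raise ValueError(f"unknown embedding backend {backend!r}")


def _flat_density_clusters(
    Y: np.ndarray,
    n_clusters: int,
    min_cluster_size: int,
    min_samples: int,
) -> np.ndarray:
    """Single-linkage over mutual-reachability distances, cut top-down to
    exactly ``n_clusters`` clusters; sub-threshold side branches are noise."""
    n = Y.shape[0]
    dist = squareform(pdist(Y, metric="euclidean"))
    k = min(min_samples, n - 1)
    core = np.sort(dist, axis=1)[:, k]  # distance to k-th neighbor
    mreach = np.maximum(dist, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(mreach, 0.0)
    Z = linkage(squareform(mreach, checks=False), method="single")

    # children of each internal node (ids n..2n-2) in the merge tree
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {}
    for step, (a, b, h, _) in enumerate(Z):
        node = n + step
        a, b = int(a), int(b)
        children[node] = (a, b)
        heights[node] = float(h)
        members[node] = np.concatenate([members[a], members[b]])

    root = n + len(Z) - 1
    labels = np.full(n, -1, dtype=int)
    if len(members[root]) < min_cluster_size:
        raise ValueError("too few points for even one cluster")

    # active clusters, each represented by a tree node; repeatedly split the
    # cluster with the highest internal merge until n_clusters remain
    def top_split(node: int) -> int | None:
        """Descend through sub-min_cluster_size splits to the next true split."""
        while node >= n:
            a, b = children[node]
            sa = len(members[a])
            sb = len(members[b])
            if sa >= min_cluster_size and sb >= min_cluster_size:
                return node
            node = a if sa >= sb else b
        return None

    active: list[int] = [root]
    while len(active) < n_clusters:
        best_i, best_node, best_h = None, None, -np.inf
        for i, node in enumerate(active):
            sp = top_split(node)
            if sp is not None and heights[sp] > best_h:
                best_i, best_node, best_h = i, sp, heights[sp]
        if best_node is None:
            raise ValueError(
                f"cannot form {n_clusters} clusters of size >= "
                f"{min_cluster_size}; maximum achievable is {len(active)}"
            )
        a, b = children[best_node]
        active.pop(best_i)
        active.extend([a, b])

    claimed = np.zeros(n, dtype=bool)
    for cid, node in enumerate(
        sorted(active, key=lambda nd: int(members[nd].min()))
    ):
        pts = members[node]
        labels[pts] = cid
        claimed[pts] = True
    # points pruned while descending past sub-threshold splits stay -1
    return labels


def cluster_embeddings(
    E: np.ndarray,
    gene_ids: Sequence[str],
    n_clusters: int,
    embed_dim: int = 20,
    n_neighbors: int = 7,
    repulsive_fraction: float = 5.0,
    min_cluster_size: int = 10,
    min_samples: int = 10,
    seed: int = 0,
    backend: Literal["umap", "spectral", "none"] = "umap",
) -> ClusterResult:
    """Standardize, embed, and density-cluster gene embeddings into exactly
    ``n_clusters`` flat clusters (noise labeled -1)."""
    E = np.asarray(E, dtype=float)
    gene_ids = [str(g) for g in gene_ids]
    if E.shape[0] != len(gene_ids):
        raise ValueError("one embedding row per gene required")
    if E.shape[0] <= min_cluster_size:
        raise ValueError("need more genes than min_cluster_size")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    sd = E.std(axis=0)
    Z = (E - E.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Y = _embed(Z, backend, embed_dim, n_neighbors, repulsive_fraction, seed)
    labels = _flat_density_clusters(Y, n_clusters, min_cluster_size, min_samples)
    return ClusterResult(
        labels=dict(zip(gene_ids, labels.tolist())),
        n_clusters=n_clusters,
        params={
            "embed_dim": embed_dim,
            "n_neighbors": n_neighbors,
            "repulsive_fraction": repulsive_fraction,
            "min_cluster_size": min_cluster_size,
            "min_samples": min_samples,
            "seed": seed,
            "backend": backend,
        },
    )


@dataclass(frozen=True)
class WithinClusterScores:
    """Pair scores of all within-cluster gene pairs, per cluster and pooled."""

    per_cluster: Mapping[int, tuple[float, ...]]
    pooled: tuple[float, ...]
    n_missing: int

    @property
    def pooled_mean(self) -> float:
        return float(np.mean(self.pooled)) if self.pooled else float("nan")

    def compare(self, other: "WithinClusterScores") -> WelchResult:
        """Two-sided Welch t-test between two pooled score distributions."""
        return welch_t_test(np.asarray(self.pooled), np.asarray(other.pooled))


def within_cluster_pair_scores(
    clusters: ClusterResult,
    scores: PairScoreTable,
    missing_score: float = 0.0,
) -> WithinClusterScores:
    """Score all C(m, 2) gene pairs inside each cluster.

    Pairs absent from the score table receive ``missing_score`` (0 by
    default) and are counted in ``n_missing``.
    """
    per_cluster: dict[int, tuple[float, ...]] = {}
    pooled: list[float] = []
    n_missing = 0
    for cid, genes in sorted(clusters.clusters().items()):
        vals: list[float] = []
        for a, b in itertools.combinations(genes, 2):
            s = scores.get(a, b)
            if s is None:
                s = missing_score
                n_missing += 1
            vals.append(float(s))
        per_cluster[cid] = tuple(vals)
        pooled.extend(vals)
    return WithinClusterScores(
        per_cluster=per_cluster, pooled=tuple(pooled), n_missing=n_missing
    )
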