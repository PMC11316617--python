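"""Construction, IO, filtering, and randomization of comparison gene networks.

Covers co-expression networks thresholded on absolute Pearson correlation
(with a turning-point heuristic for choosing the threshold), edge-list and
TF-target table loading, universe filtering, random null networks matched in
size, undirected unions, overlap statistics, and gene-level preprocessing
(active/variable gene selection, per-base score aggregation over gene
regions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneNetwork, _norm_edge

__all__ = [
    "coexpression_network",
    "threshold_turning_point",
    "TurningPoint",
    "load_edge_list",
    "load_tf_target",
    "write_edge_list",
    "filter_to_universe",
    "random_network",
    "combine_networks",
    "network_overlap",
    "select_active_variable_genes",
    "aggregate_region_score",
    "load_bedgraph",
    "PairScoreTable",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pair-score tables


class PairScoreTable:
    """Symmetric map from unordered gene pairs to a real score."""

    def __init__(self, scores: Mapping[tuple[str, str], float] | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        if scores:
            for (a, b), s in scores.items():
                self.set(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError("pair scores are defined on distinct genes")
        return (a, b) if a < b else (b, a)

    def set(self, a: str, b: str, score: float) -> None:
        score = float(score)
        if not np.isfinite(score):
            raise ValueError("scores must be finite")
        self._scores[self._key(a, b)] = score

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._scores.get(self._key(a, b), default)

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, pair) -> bool:
        return self._key(*pair) in self._scores

    def items(self):
        return self._scores.items()

    @classmethod
    def from_tsv(cls, path) -> "PairScoreTable":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["a", "b", "score"], dtype={"a": str, "b": str},
        )
        table = cls()
        for row in df.itertuples(index=False):
            table.set(row.a, row.b, row.score)
        return table

    @classmethod
    def from_correlations(cls, X: ExpressionMatrix) -> "PairScoreTable":
        """All-pairs Pearson correlation of gene columns as a score table."""
        corr = np.corrcoef(X.values, rowvar=False)
        table = cls()
        genes = X.gene_ids
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                table.set(genes[i], genes[j], corr[i, j])
        return table


# ---------------------------------------------------------------------------
# Co-expression


def coexpression_network(
    X: ExpressionMatrix, threshold: float
) -> GeneNetwork:
    """Undirected network with an edge where ``|Pearson r| > threshold``.

    Zero-variance genes are dropped with a warning (correlation undefined).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if X.n_conditions < 3:
        raise ValueError("need at least 3 conditions for correlations")
    sd = X.values.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if not keep.all():
        dropped = [g for g, k in zip(X.gene_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}..."
        )
    genes = tuple(g for g, k in zip(X.gene_ids, keep) if k)
    vals = X.values[:, keep]
    corr = np.corrcoef(vals, rowvar=False)
    if corr.ndim == 0:  # single gene
        corr = np.ones((1, 1))
    edges = set()
    d = len(genes)
    for i in range(d):
        for j in range(i + 1, d):
            if abs(corr[i, j]) > threshold:
                edges.add(_norm_edge(genes[i], genes[j], False))
    return GeneNetwork(
        genes=genes, edges=frozenset(edges), provenance=f"coexpr|r|>{threshold}"
    )


@dataclass(frozen=True)
class TurningPoint:
    """Result of the threshold-elbow scan. ``threshold`` is None when the
    edge-count curve has no turning point (monotone second difference)."""

    threshold: float | None
    edge_counts: tuple[int, ...]
    grid: tuple[float, ...]


def threshold_turning_point(
    X: ExpressionMatrix, grid: Sequence[float]
) -> TurningPoint:
    """Pick the co-expression threshold at the elbow of the edge-count curve.

    Edge counts are computed on each grid threshold; the elbow is the grid
    point maximizing the discrete second difference of ``log(1 + count)``.
    When that second difference is monotone (no bend), no turning point is
    reported.
    """
    grid = [float(t) for t in grid]
    if len(grid) < 4:
        raise ValueError("grid needs at least 4 thresholds")
    if sorted(grid) != grid:
        raise ValueError("grid must be sorted ascending")
    corr = np.corrcoef(X.values, rowvar=False)
    absr = np.abs(corr[np.triu_indices_from(corr, k=1)])
    counts = [int((absr > t).sum()) for t in grid]
    y = np.log1p(counts)
    d2 = y[:-2] - 2 * y[1:-1] + y[2:]
    # no elbow when the curvature profile is flat or monotone (no interior peak)
    flat = np.ptp(d2) < 1e-12
    monotone = np.all(np.diff(d2) >= 0) or np.all(np.diff(d2) <= 0)
    if flat or (monotone and len(d2) > 2):
        return TurningPoint(None, tuple(counts), tuple(grid))
    best = int(np.argmax(d2)) + 1
    return TurningPoint(grid[best], tuple(counts), tuple(grid))


# ---------------------------------------------------------------------------
# Edge-list IO


def load_edge_list(path, directed: bool = False) -> GeneNetwork:
    """Read a TSV edge list (``source<TAB>target[<TAB>weight]``, ``#`` comments).

    Duplicate edges are collapsed; self-loops are dropped and counted in the
    log. Malformed rows raise with their line number.
    """
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {line!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            genes.update((u, v))
            key = _norm_edge(u, v, directed)
            edges.add(key)
            if len(parts) >= 3 and parts[2]:
                try:
                    weights[key] = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric weight at line {lineno}: {line!r}"
                    ) from None
    if n_self:
        logger.warning("%s: dropped %d self-loop rows", path, n_self)
    net = GeneNetwork(
        genes=tuple(sorted(genes)),
        edges=frozenset(edges),
        directed=directed,
        weights=weights or None,
        provenance=str(path),
    )
    object.__setattr__(net, "n_self_loops_dropped", n_self)
    return net


def load_tf_target(path) -> GeneNetwork:
    """Read a prepared TF-target table as a directed TF -> target network."""
    return load_edge_list(path, directed=True)


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write the canonical (sorted) edge list; inverse of :func:`load_edge_list`."""
    net.to_tsv(path)


def filter_to_universe(net: GeneNetwork, genes: Iterable[str]) -> GeneNetwork:
    """Restrict the network to edges with both endpoints in ``genes``."""
    allowed = {str(g) for g in genes}
    universe = tuple(sorted(allowed))
    keep = frozenset(e for e in net.edges if e[0] in allowed and e[1] in allowed)
    return GeneNetwork(
        genes=universe,
        edges=keep,
        directed=net.directed,
        provenance=net.provenance,
    )


def random_network(
    n_nodes: int,
    n_edges: int,
    model: Literal["erdos_renyi", "scale_free"] = "erdos_renyi",
    seed: int | None = None,
    genes: Sequence[str] | None = None,
) -> GeneNetwork:
    """Random undirected null network of matched size.

    ``erdos_renyi`` has exactly ``n_edges`` uniform distinct pairs;
    ``scale_free`` uses preferential attachment with an edge count as close
    to ``n_edges`` as the mechanism allows. ``genes`` optionally relabels
    nodes (e.g. with the reference network's universe).
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"infeasible edge count {n_edges} for {n_nodes} nodes")
    if model == "erdos_renyi":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    elif model == "scale_free":
        k = max(1, round(n_edges / max(n_nodes - 1, 1)))
        g = nx.barabasi_albert_graph(n_nodes, min(k, n_nodes - 1), seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    if genes is None:
        labels = [f"n{i}" for i in range(n_nodes)]
    else:
        labels = [str(x) for x in genes]
        if len(labels) != n_nodes:
            raise ValueError("genes must have length n_nodes")
    mapping = dict(zip(range(n_nodes), labels))
    edges = frozenset(
        _norm_edge(mapping[a], mapping[b], False) for a, b in g.edges()
    )
    return GeneNetwork(
        genes=tuple(labels), edges=edges, provenance=f"random-{model}"
    )


def combine_networks(nets: Sequence[GeneNetwork]) -> GeneNetwork:
    """Undirected, deduplicated union over the shared gene universe."""
    if not nets:
        raise ValueError("need at least one network")
    genes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for net in nets:
        genes.update(net.genes)
        for u, v in net.edges:
            edges.add(_norm_edge(u, v, False))
    return GeneNetwork(
        genes=tuple(sorted(genes)),
        edges=frozenset(edges),
        provenance="+".join(n.provenance or "?" for n in nets),
    )


def network_overlap(a: GeneNetwork, b: GeneNetwork) -> dict[str, float]:
    """Undirected edge-set intersection size and Jaccard index."""
    ea = {_norm_edge(u, v, False) for u, v in a.edges}
    eb = {_norm_edge(u, v, False) for u, v in b.edges}
    shared = len(ea & eb)
    union = len(ea | eb)
    return {
        "shared_edges": float(shared),
        "jaccard": shared / union if union else 0.0,
    }


# ---------------------------------------------------------------------------
# Gene-level preprocessing


def select_active_variable_genes(
    expr,
    percentile: float = 95.0,
    mode: Literal["union", "intersection"] = "union",
) -> list[str]:
    """Genes with high mean expression and/or high standard deviation.

    A gene passes the mean filter if its mean across samples exceeds the
    given percentile of per-gene means, likewise for the sd filter; the two
    gene sets are combined by union (default) or intersection.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    if isinstance(expr, ExpressionMatrix):
        means = expr.values.mean(axis=0)
        sds = expr.values.std(axis=0, ddof=1)
        genes = expr.gene_ids
    else:
        df = pd.DataFrame(expr)
        means = df.mean(axis=0).to_numpy()
        sds = df.std(axis=0, ddof=1).to_numpy()
        genes = tuple(df.columns.astype(str))
    if percentile == 0:
        return list(genes)
    mean_cut = np.percentile(means, percentile)
    sd_cut = np.percentile(sds, percentile)
    by_mean = {g for g, v in zip(genes, means) if v > mean_cut}
    by_sd = {g for g, v in zip(genes, sds) if v > sd_cut}
    chosen = by_mean | by_sd if mode == "union" else by_mean & by_sd
    return [g for g in genes if g in chosen]


def load_bedgraph(path) -> dict[tuple[str, int], float]:
    """Expand a bedGraph-style TSV (chrom, start, end, value; 0-based
    half-open) into a per-base score map keyed by ``(chrom, position)``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    scores: dict[tuple[str, int], float] = {}
    for row in df.itertuples(index=False):
        for pos in range(int(row.start), int(row.end)):
            scores[(row.chrom, pos)] = float(row.value)
    return scores


def aggregate_region_score(
    per_base_scores: Mapping,
    gene_intervals: Mapping[str, tuple],
) -> tuple[dict[str, float], list[str]]:
    """Average per-base scores over each gene's region (0-based, half-open).

    ``per_base_scores`` maps positions (ints, or ``(chrom, pos)`` tuples) to
    scores; ``gene_intervals`` maps gene -> ``(start, end)`` or
    ``(chrom, start, end)``. Strand is ignored. Returns the per-gene mean
    score plus the list of genes with no covered base.
    """
    out: dict[str, float] = {}
    missing: list[str] = []
    for gene, iv in gene_intervals.items():
        if len(iv) == 3:
            chrom, start, end = iv
            keys = ((str(chrom), p) for p in range(int(start), int(end)))
        else:
            start, end = iv
            keys = range(int(start), int(end))
        vals = [per_base_scores[k] for k in keys if k in per_base_scores]
        if vals:
            out[str(gene)] = float(np.mean(vals))
        else:
            missing.append(str(gene))
    return out, missing


def minmax_scale_features(X: ExpressionMatrix) -> ExpressionMatrix:
    """Min-max scale each condition (row feature) to [0, 1] across genes kept
    per-column: each gene's feature vector entries are scaled per feature
    dimension so all inputs share the [0, 1] range."""
    vals = X.values
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return ExpressionMatrix(
        values=(vals - lo) / span,
        gene_ids=X.gene_ids,
        condition_ids=X.condition_ids,
    )
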