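"""Structural and statistical analysis of a learned gene network.

Includes CPDAG conversion (compelled edges via v-structures + Meek-rule
closure), Leiden communities, separator genes and the modules they isolate,
partial correlations for conditional-independence checks, betweenness
bottlenecks and neighbor shells, the control-referenced knockout response
z-score, and a permutation-style length-two overlap test against
Erdos-Renyi nulls.

All topological analyses operate on the undirected skeleton of the learned
network; only the CPDAG conversion consumes edge directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as _sps

from .containers import DagNetwork, ExpressionMatrix, GeneNetwork, PerturbationDataset
from .network_io import combine_networks, random_network
from .stats import WelchResult, paired_one_sided_t, welch_t_test

__all__ = [
    "CpdagNetwork",
    "to_cpdag",
    "leiden_communities",
    "SeparatorReport",
    "find_separators",
    "Module",
    "extract_modules",
    "partial_correlation",
    "ModuleIndependenceReport",
    "module_independence_report",
    "betweenness",
    "high_betweenness_genes",
    "neighbor_shells",
    "knockout_response",
    "OverlapTestResult",
    "length_two_overlap_test",
    "rank_by_expression_and_variance",
    "welch_t_test",
]


# ---------------------------------------------------------------------------
# CPDAG


@dataclass(frozen=True)
class CpdagNetwork:
    """Completed partially directed acyclic graph: the compelled (directed)
    and reversible (undirected) edges shared by a DAG's Markov equivalence
    class. The skeleton equals the source DAG's skeleton."""

    gene_ids: tuple[str, ...]
    directed_edges: frozenset[tuple[str, str]]
    undirected_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        und = frozenset(
            (u, v) if u <= v else (v, u) for u, v in self.undirected_edges
        )
        object.__setattr__(self, "undirected_edges", und)
        skel_dir = {(min(u, v), max(u, v)) for u, v in self.directed_edges}
        if skel_dir & set(und):
            raise ValueError("an edge cannot be both compelled and reversible")

    def skeleton_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            {(min(u, v), max(u, v)) for u, v in self.directed_edges}
            | set(self.undirected_edges)
        )


def to_cpdag(dag: DagNetwork) -> CpdagNetwork:
    """Compelled-edge identification by v-structures plus Meek-rule closure.

    An edge is compelled (kept directed) iff it has the same orientation in
    every DAG Markov-equivalent to the input; all other edges are reported
    undirected.
    """
    nodes = list(dag.gene_ids)
    adj: dict[str, set[str]] = {u: set() for u in nodes}
    for u, v in dag.edges:
        adj[u].add(v)
        adj[v].add(u)

    directed: set[tuple[str, str]] = set()
    parents: dict[str, set[str]] = {u: set() for u in nodes}
    for u, v in dag.edges:
        parents[v].add(u)

    # v-structures x -> z <- y with x, y non-adjacent
    for z in nodes:
        ps = sorted(parents[z])
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                x, y = ps[i], ps[j]
                if y not in adj[x]:
                    directed.add((x, z))
                    directed.add((y, z))

    undirected = {
        (min(u, v), max(u, v))
        for u, v in dag.edges
        if (u, v) not in directed
    }

    def orient(u: str, v: str) -> bool:
        key = (min(u, v), max(u, v))
        if key in undirected:
            undirected.discard(key)
            directed.add((u, v))
            return True
        return False

    changed = True
    while changed:
        changed = False
        und_pairs = [(a, b) for a, b in list(undirected)] + [
            (b, a) for a, b in list(undirected)
        ]
        for b, c in und_pairs:
            # R1: a -> b, b - c, a and c non-adjacent  =>  b -> c
            if any(
                (a, b) in directed and c not in adj[a] and a != c
                for a in adj[b]
            ):
                if orient(b, c):
                    changed = True
                    continue
            # R2: b -> a -> c and b - c  =>  b -> c  (avoid a new cycle)
            if any(
                (b, a) in directed and (a, c) in directed for a in adj[b] & adj[c]
            ):
                if orient(b, c):
                    changed = True
                    continue
            # R3: b - a1, b - a2, a1 -> c, a2 -> c, a1,a2 non-adjacent => b -> c
            cands = [
                a
                for a in adj[b] & adj[c]
                if (min(a, b), max(a, b)) in undirected and (a, c) in directed
            ]
            done = False
            for i in range(len(cands)):
                for j in range(i + 1, len(cands)):
                    if cands[j] not in adj[cands[i]]:
                        if orient(b, c):
                            changed = True
                            done = True
                        break
                if done:
                    break
            # Meek's fourth rule is only required with background knowledge;
            # starting from v-structures alone, R1-R3 reach the closure.

    return CpdagNetwork(
        gene_ids=tuple(nodes),
        directed_edges=frozenset(directed),
        undirected_edges=frozenset(undirected),
    )


# ---------------------------------------------------------------------------
# Communities


def leiden_communities(
    net: GeneNetwork, resolution: float = 1.0, seed: int = 0
) -> dict[str, int]:
    """Leiden modularity communities of the undirected network."""
    import igraph as ig
    import leidenalg

    genes = list(net.genes)
    if not genes:
        return {}
    index = {g: i for i, g in enumerate(genes)}
    g = ig.Graph(
        n=len(genes),
        edges=[(index[u], index[v]) for u, v in net.undirected().edges],
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return {genes[i]: int(part.membership[i]) for i in range(len(genes))}


# ---------------------------------------------------------------------------
# Separators and modules


@dataclass(frozen=True)
class SeparatorReport:
    """A gene whose removal splits the main component into >= 2 components
    of at least ``min_component_size`` genes each."""

    gene: str
    components: tuple[frozenset[str], ...]
    min_component_size: int

    @property
    def n_components(self) -> int:
        return len(self.components)


def find_separators(
    net: GeneNetwork, min_component_size: int = 7
) -> list[SeparatorReport]:
    """Scan every gene of the network's main connected component."""
    g = net.undirected().to_networkx()
    if g.number_of_nodes() == 0:
        return []
    main = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    sub = g.subgraph(main).copy()
    out: list[SeparatorReport] = []
    for gene in sorted(main):
        h = sub.copy()
        h.remove_node(gene)
        comps = [frozenset(c) for c in nx.connected_components(h)]
        if len(comps) >= 2 and all(len(c) >= min_component_size for c in comps):
            out.append(
                SeparatorReport(
                    gene=gene,
                    components=tuple(
                        sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))
                    ),
                    min_component_size=min_component_size,
                )
            )
    return out


@dataclass(frozen=True)
class Module:
    """A gene set isolated from the main component by one or more separators."""

    genes: frozenset[str]
    separators: frozenset[str]


def extract_modules(
    net: GeneNetwork, separators: Sequence[SeparatorReport]
) -> list[Module]:
    """Condense the gene sets isolated by separators into modules.

    For each separator, every post-removal component except the largest is a
    module; separators isolating the same component are merged into one
    conditioning set.
    """
    grouped: dict[frozenset[str], set[str]] = {}
    for rep in separators:
        comps = sorted(rep.components, key=len, reverse=True)
        for comp in comps[1:]:
            grouped.setdefault(comp, set()).add(rep.gene)
    return [
        Module(genes=genes, separators=frozenset(seps))
        for genes, seps in sorted(
            grouped.items(), key=lambda kv: sorted(kv[0])[0]
        )
    ]


# ---------------------------------------------------------------------------
# Partial correlation


def _residualize(cols: np.ndarray, design: np.ndarray) -> np.ndarray:
    n = cols.shape[0]
    Z = np.column_stack([np.ones(n), design]) if design.size else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(Z, cols, rcond=None)
    if rank < Z.shape[1]:
        raise ValueError("singular conditioning design (collinear genes)")
    return cols - Z @ coef


def partial_correlation(
    X: ExpressionMatrix, i: str, j: str, conditioning: Iterable[str] = ()
) -> float:
    """Correlation of residuals of genes ``i`` and ``j`` after regressing
    both on the conditioning genes; empty conditioning reduces to Pearson r."""
    cond = [str(g) for g in conditioning]
    if str(i) in cond or str(j) in cond:
        raise ValueError("i and j must not be in the conditioning set")
    n = X.n_conditions
    if len(cond) >= n - 2:
        raise ValueError("conditioning set too large for the sample size")
    xi, xj = X.column(i), X.column(j)
    if not cond:
        return float(np.corrcoef(xi, xj)[0, 1])
    design = np.column_stack([X.column(g) for g in cond])
    resid = _residualize(np.column_stack([xi, xj]), design)
    return float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])


@dataclass(frozen=True)
class ModuleIndependenceReport:
    """Paired plain and separator-conditioned correlations for all
    (in-module, outside) gene pairs."""

    pairs: tuple[tuple[str, str], ...]
    plain_r: np.ndarray
    partial_r: np.ndarray
    separators: tuple[str, ...]

    @property
    def mean_abs_plain(self) -> float:
        return float(np.mean(np.abs(self.plain_r)))

    @property
    def mean_abs_partial(self) -> float:
        return float(np.mean(np.abs(self.partial_r)))

    def paired_reduction_test(self) -> tuple[float, float]:
        """One-sided paired t-test of |plain r| > |partial r|."""
        return paired_one_sided_t(np.abs(self.plain_r), np.abs(self.partial_r))


def module_independence_report(
    X: ExpressionMatrix,
    module: Iterable[str],
    separators: Iterable[str],
    outside: Iterable[str],
) -> ModuleIndependenceReport:
    """Plain vs separator-conditioned correlation for every (module, outside)
    pair; supports multi-gene conditioning sets."""
    module = [str(g) for g in module]
    seps = [str(g) for g in separators]
    outside = [str(g) for g in outside if str(g) not in seps]
    cols = {g: X.column(g) for g in set(module) | set(outside)}
    if seps:
        design = np.column_stack([X.column(g) for g in seps])
        order = sorted(cols)
        resid_mat = _residualize(
            np.column_stack([cols[g] for g in order]), design
        )
        resid = {g: resid_mat[:, k] for k, g in enumerate(order)}
    else:
        resid = cols
    pairs, plain, partial = [], [], []
    for a in module:
        for b in outside:
            if a == b:
                continue
            pairs.append((a, b))
            plain.append(float(np.corrcoef(cols[a], cols[b])[0, 1]))
            partial.append(float(np.corrcoef(resid[a], resid[b])[0, 1]))
    return ModuleIndependenceReport(
        pairs=tuple(pairs),
        plain_r=np.asarray(plain),
        partial_r=np.asarray(partial),
        separators=tuple(seps),
    )


# ---------------------------------------------------------------------------
# Centrality and shells


def betweenness(net: GeneNetwork, normalized: bool = False) -> dict[str, float]:
    """Exact shortest-path betweenness centrality (Brandes accumulation)."""
    g = net.undirected().to_networkx()
    return {
        str(k): float(v)
        for k, v in nx.betweenness_centrality(g, normalized=normalized).items()
    }


def high_betweenness_genes(
    net: GeneNetwork, top_fraction: float = 0.05, normalized: bool = False
) -> list[str]:
    """Top fraction of genes among those with nonzero betweenness."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    bt = betweenness(net, normalized=normalized)
    nonzero = [(g, v) for g, v in bt.items() if v > 0]
    nonzero.sort(key=lambda kv: (-kv[1], kv[0]))
    k = max(1, math.ceil(top_fraction * len(nonzero))) if nonzero else 0
    return [g for g, _ in nonzero[:k]]


def neighbor_shells(
    net: GeneNetwork, seeds: Iterable[str], depth: int = 2
) -> dict[str, str]:
    """Classify genes as seed / shell1 / shell2 / other by set differences:
    shell1 = neighbors of seeds not in seeds; shell2 = neighbors of shell1
    not in seeds or shell1; everything else is 'other'."""
    seeds = {str(g) for g in seeds}
    labels = {g: "other" for g in net.genes}
    for g in seeds:
        if g in labels:
            labels[g] = "seed"
    frontier = set(seeds)
    assigned = set(seeds)
    for k in range(1, depth + 1):
        nxt: set[str] = set()
        for g in frontier:
            nxt |= net.neighbors(g)
        nxt -= assigned
        for g in nxt:
            labels[g] = f"shell{k}"
        assigned |= nxt
        frontier = nxt
    return labels


# ---------------------------------------------------------------------------
# Knockout response


def knockout_response(
    pdset: PerturbationDataset, target_gene: str, knocked_gene: str
) -> float:
    """Control-referenced z-score of the target gene's mean expression under
    knockdown of another gene:
    ``Z(A|B) = (Expression(A|B) - Mean(A|Ctrl)) / Std(A|Ctrl)``."""
    ai = pdset.gene_index(target_gene)
    mu = float(pdset.control[:, ai].mean())
    sd = float(pdset.control[:, ai].std(ddof=1))
    if sd == 0:
        raise ValueError(f"zero control standard deviation for {target_gene!r}")
    expr = float(pdset.condition_means[str(knocked_gene)][ai])
    return (expr - mu) / sd


# ---------------------------------------------------------------------------
# Length-two overlap test


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_one_sided: float
    null_values: tuple[int, ...]


def overlap_z_p(observed: float, null_mean: float, null_sd: float) -> tuple[float, float]:
    """Z-score of the observed overlap count against the sampled null, with
    its upper-tail standard-normal one-sided p-value."""
    if null_sd == 0:
        raise ValueError("degenerate null distribution (zero standard deviation)")
    z = (observed - null_mean) / null_sd
    return float(z), float(_sps.norm.sf(z))


def _length_two_overlap_count(
    combined: GeneNetwork, latentdag: GeneNetwork
) -> int:
    adj: dict[str, set[str]] = {}
    for u, v in combined.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    count = 0
    for a, c in latentdag.undirected().edges:
        if adj.get(a, set()) & adj.get(c, set()):
            count += 1
    return count


def length_two_overlap_test(
    base: GeneNetwork,
    replaceable: GeneNetwork,
    latentdag: GeneNetwork,
    n_random: int = 50,
    seed: int | None = None,
) -> OverlapTestResult:
    """Are learned edges enriched for endpoints of length-two paths?

    A learned edge (a, c) counts as an overlap when the combined network
    contains a length-two path a - b - c. The null replaces the replaceable
    component network with an Erdos-Renyi graph of the same node and edge
    count, ``n_random`` times; the z-score of the observed count against the
    null mean/sd gives a one-sided normal p-value.
    """
    observed = _length_two_overlap_count(
        combine_networks([base, replaceable]), latentdag
    )
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_random):
        rand = random_network(
            replaceable.n_genes,
            replaceable.n_edges,
            "erdos_renyi",
            seed=int(rng.integers(2**31)),
            genes=replaceable.genes,
        )
        nulls.append(
            _length_two_overlap_count(combine_networks([base, rand]), latentdag)
        )
    null_mean = float(np.mean(nulls))
    null_sd = float(np.std(nulls, ddof=1))
    z, p = overlap_z_p(observed, null_mean, null_sd)
    return OverlapTestResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_one_sided=p,
        null_values=tuple(nulls),
    )


# ---------------------------------------------------------------------------
# Gene ranking


def rank_by_expression_and_variance(X: ExpressionMatrix) -> list[str]:
    """Rank genes by combining absolute mean expression and variance.

    Each gene gets a descending rank on mean |expression| and on variance;
    the two ranks are summed and genes sorted ascending by rank-sum (rank 1 =
    strongest). Ties are broken by gene id.
    """
    mean_abs = np.abs(X.values).mean(axis=0)
    var = X.values.var(axis=0, ddof=1)
    order_mean = _sps.rankdata(-mean_abs, method="average")
    order_var = _sps.rankdata(-var, method="average")
    ranksum = order_mean + order_var
    keyed = sorted(zip(ranksum, X.gene_ids))
    return [g for _, g in keyed]
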