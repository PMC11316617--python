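"""Core in-memory containers shared across the pipeline.

Orientation convention, enforced everywhere: expression matrices are
*conditions x genes* (rows are samples/conditions, columns are genes), and a
directed edge ``i -> j`` means gene *i* is a parent of gene *j*, i.e. the SEM
coefficient ``w_ij`` is nonzero and samples satisfy ``X ~ X W``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass(frozen=True)
class ExpressionMatrix:
    """A conditions-by-genes real matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_conditions, n_genes)`` float array; must be finite.
    gene_ids
        Unique gene labels, one per column.
    condition_ids
        Condition labels, one per row (auto-generated when omitted).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        n, d = values.shape
        if d != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {d} columns"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene ids must be unique")
        if not self.condition_ids:
            object.__setattr__(
                self, "condition_ids", tuple(f"c{i}" for i in range(n))
            )
        else:
            object.__setattr__(
                self, "condition_ids", tuple(map(str, self.condition_ids))
            )
        if len(self.condition_ids) != n:
            raise ValueError(
                f"{len(self.condition_ids)} condition ids for {n} rows"
            )

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(str(gene))
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.condition_ids), columns=list(self.gene_ids)
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "condition"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, genes_as_rows: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if genes_as_rows:
            df = df.T
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=tuple(df.columns.astype(str)),
            condition_ids=tuple(df.index.astype(str)),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=tuple(df.columns.astype(str)),
            condition_ids=tuple(df.index.astype(str)),
        )


# ---------------------------------------------------------------------------
# Weighted adjacency (SEM coefficients)


@dataclass(frozen=True)
class WeightedAdjacency:
    """A ``d x d`` matrix of linear-SEM coefficients with zero diagonal."""

    weights: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.gene_ids):
            raise ValueError("gene ids do not match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.any(np.diagonal(w) != 0.0):
            raise ValueError("diagonal must be exactly zero (no self-loops)")

    @property
    def d(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.weights, index=list(self.gene_ids), columns=list(self.gene_ids)
        )
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene networks


def _norm_edge(u: str, v: str, directed: bool) -> tuple[str, str]:
    return (u, v) if directed or u <= v else (v, u)


@dataclass(frozen=True)
class GeneNetwork:
    """A simple graph over a gene universe.

    Undirected by default; edges are stored as canonical ordered pairs
    (lexicographically sorted endpoints when undirected). Self-loops and
    duplicate edges are rejected at construction.
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    directed: bool = False
    weights: Mapping[tuple[str, str], float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        genes = tuple(map(str, self.genes))
        universe = set(genes)
        if len(universe) != len(genes):
            raise ValueError("duplicate genes in universe")
        canon = set()
        for u, v in self.edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in universe or v not in universe:
                raise ValueError(f"edge endpoint outside universe: {(u, v)}")
            canon.add(_norm_edge(u, v, self.directed))
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset(canon))
        if self.weights is not None:
            w = {
                _norm_edge(str(u), str(v), self.directed): float(s)
                for (u, v), s in self.weights.items()
            }
            object.__setattr__(self, "weights", w)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return _norm_edge(str(u), str(v), self.directed) in self.edges

    def neighbors(self, gene: str) -> set[str]:
        gene = str(gene)
        out = set()
        for u, v in self.edges:
            if u == gene:
                out.add(v)
            elif v == gene:
                out.add(u)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g

    def undirected(self) -> "GeneNetwork":
        """Drop directions (idempotent for undirected networks)."""
        if not self.directed:
            return self
        return GeneNetwork(
            genes=self.genes,
            edges=frozenset(_norm_edge(u, v, False) for u, v in self.edges),
            directed=False,
            provenance=self.provenance,
        )

    def to_tsv(self, path) -> None:
        rows = sorted(self.edges)
        with open(path, "w") as fh:
            for u, v in rows:
                if self.weights is not None and (u, v) in self.weights:
                    fh.write(f"{u}\t{v}\t{self.weights[(u, v)]:g}\n")
                else:
                    fh.write(f"{u}\t{v}\n")


@dataclass(frozen=True)
class DagNetwork:
    """A directed acyclic graph over genes, with provenance of the threshold
    used to extract it from a weighted adjacency."""

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    threshold_used: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        edges = frozenset((str(u), str(v)) for u, v in self.edges)
        universe = set(self.gene_ids)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in universe or v not in universe:
                raise ValueError(f"edge endpoint outside universe: {(u, v)}")
        object.__setattr__(self, "edges", edges)
        import networkx as nx

        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("edge set contains a directed cycle")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(self.edges)
        return g

    def skeleton(self) -> GeneNetwork:
        """The undirected skeleton as a :class:`GeneNetwork`."""
        return GeneNetwork(
            genes=self.gene_ids,
            edges=frozenset(_norm_edge(u, v, False) for u, v in self.edges),
            directed=False,
            provenance="dag-skeleton",
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.edges):
                fh.write(f"{u}\t{v}\n")


@dataclass(frozen=True)
class PerturbationDataset:
    """Control expression samples plus per-gene-knockdown condition means.

    ``condition_means[g]`` is the length-``d`` vector of mean expression of
    every gene under knockdown of gene ``g``.
    """

    gene_ids: tuple[str, ...]
    control: np.ndarray
    condition_means: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        ctrl = np.asarray(self.control, dtype=float)
        object.__setattr__(self, "control", ctrl)
        if ctrl.ndim != 2 or ctrl.shape[1] != len(self.gene_ids):
            raise ValueError("control must be (n_ctrl, d)")
        means = {str(g): np.asarray(v, dtype=float) for g, v in self.condition_means.items()}
        for g, v in means.items():
            if v.shape != (len(self.gene_ids),):
                raise ValueError(f"condition mean for {g!r} has wrong length")
        object.__setattr__(self, "condition_means", means)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(str(gene))
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def control_mean(self) -> np.ndarray:
        return self.control.mean(axis=0)

    def control_sd(self) -> np.ndarray:
        return self.control.std(axis=0, ddof=1)

    def z_matrix(self) -> pd.DataFrame:
        """Control-referenced z-scores: rows = knocked gene, cols = target gene."""
        mu = self.control_mean()
        sd = self.control_sd()
        if np.any(sd == 0):
            raise ValueError("zero control standard deviation")
        rows = sorted(self.condition_means)
        mat = np.vstack([(self.condition_means[g] - mu) / sd for g in rows])
        return pd.DataFrame(mat, index=rows, columns=list(self.gene_ids))
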