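"""Sparse linear-SEM structure learning under a continuous acyclicity constraint.

The model is a linear structural equation model over ``d`` genes: each sample
``x`` satisfies ``x = W^T x + e`` with exogenous noise ``e``, so a
conditions-by-genes matrix satisfies ``X ~ X W``. The coefficient matrix ``W``
is estimated by penalized least squares

    min_W  (1/2n) ||X - XW||_F^2 + lambda1 ||W||_1

subject to the smooth acyclicity constraint

    h(W) = -log det(s I - W o W) + d log s = 0,

where ``o`` is the element-wise (Hadamard) product. ``h`` is zero exactly when
the support of ``W`` is acyclic and positive for any in-domain ``W`` whose
support contains a directed cycle. The constrained problem is solved with a
path-following scheme: a sequence of unconstrained problems
``mu_k * (score + L1) + h(W)`` with ``mu_k`` shrinking geometrically, each
warm-started from the previous solution. A binary DAG is then extracted with
an adaptive threshold that decreases until the thresholded graph stops being
acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .containers import DagNetwork, ExpressionMatrix, WeightedAdjacency

__all__ = [
    "LearnerConfig",
    "acyclicity_logdet",
    "acyclicity_logdet_gradient",
    "acyclicity_expm",
    "fit_linear_sem",
    "binarize",
    "adaptive_threshold",
    "is_dag",
]


class AcyclicityDomainError(ValueError):
    """Raised when ``s I - W o W`` is not a positive-determinant M-matrix,
    i.e. the iterate left the domain where the log-det constraint is defined."""


class OptimizationError(RuntimeError):
    """Raised when the path-following solver cannot recover a valid iterate.
    Carries the last in-domain iterate in ``last_valid``."""

    def __init__(self, message: str, last_valid: np.ndarray | None = None):
        super().__init__(message)
        self.last_valid = last_valid


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the penalized SEM fit.

    lambda1 : L1 penalty weight (>= 0). With ``scale_penalty`` the weight
        multiplies each predictor's standard deviation, making the selection
        threshold scale-free; 0.1 then sits 2-3x above the noise scale of
        partial covariances at n ~ 1000.
    s : log-det constraint parameter (> 0, 1 by default).
    path_stages : number of decreasing-mu stages (>= 1).
    mu_init, mu_decay : path schedule; stage k uses ``mu_init * mu_decay**k``.
    inner_max_iter : iteration cap per stage.
    step_size : Adam learning rate; halved on domain violations.
    tol : relative objective-change stopping tolerance per stage.
    seed : initialization seed (the default zero start is deterministic; the
        seed only matters for ``warm_start='random'``).
    """

    lambda1: float = 0.1
    s: float = 1.0
    path_stages: int = 4
    mu_init: float = 1.0
    mu_decay: float = 0.1
    inner_max_iter: int = 8000
    step_size: float = 0.01
    tol: float = 1e-9
    seed: int = 0
    scale_penalty: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.path_stages < 1:
            raise ValueError("path_stages must be >= 1")
        if self.mu_init <= 0:
            raise ValueError("mu_init must be positive")
        if not 0 < self.mu_decay < 1:
            raise ValueError("mu_decay must be in (0, 1)")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, WeightedAdjacency):
        return W.weights
    return np.asarray(W, dtype=float)


def _logdet_M(W: np.ndarray, s: float) -> tuple[float, np.ndarray]:
    d = W.shape[0]
    M = s * np.eye(d) - W * W
    sign, logabsdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise AcyclicityDomainError(
            "s*I - W*W has non-positive determinant: the spectral radius of "
            "W o W reaches s, so the log-det acyclicity function is undefined"
        )
    return logabsdet, M


def acyclicity_logdet(W, s: float = 1.0) -> float:
    """Log-determinant acyclicity function ``-log det(sI - W o W) + d log s``.

    Zero exactly when the support of ``W`` is acyclic; strictly positive for
    in-domain ``W`` whose support contains a directed cycle.
    """
    W = _as_matrix(W)
    if s <= 0:
        raise ValueError("s must be positive")
    logabsdet, _ = _logdet_M(W, s)
    return float(-logabsdet + W.shape[0] * np.log(s))


def acyclicity_logdet_gradient(W, s: float = 1.0) -> np.ndarray:
    """Analytic gradient ``2 (sI - W o W)^{-T} o W`` of :func:`acyclicity_logdet`."""
    W = _as_matrix(W)
    if s <= 0:
        raise ValueError("s must be positive")
    _, M = _logdet_M(W, s)
    return 2.0 * np.linalg.inv(M).T * W


def acyclicity_expm(W) -> float:
    """Trace-of-matrix-exponential acyclicity function ``tr exp(W o W) - d``.

    An alternative smooth constraint, defined for every ``W``; zero iff the
    support of ``W`` is acyclic.
    """
    from scipy.linalg import expm

    W = _as_matrix(W)
    d = W.shape[0]
    return float(np.trace(expm(W * W)) - d)


def is_dag(graph) -> bool:
    """True iff the directed graph has no directed cycle.

    Accepts a networkx DiGraph, a :class:`DagNetwork`, or an edge iterable.
    """
    if isinstance(graph, DagNetwork):
        return True
    if isinstance(graph, nx.DiGraph):
        g = graph
    else:
        g = nx.DiGraph()
        g.add_edges_from(graph)
    return nx.is_directed_acyclic_graph(g)


def binarize(W, threshold: float = 0.0):
    """Directed graph with an edge ``i -> j`` iff ``|w_ij| > threshold``.

    No acyclicity is guaranteed. Returns a networkx DiGraph over the gene ids
    (or integer indices for a bare matrix). Entries exactly equal to the
    threshold are excluded (strict inequality).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    mat = _as_matrix(W)
    labels = (
        list(W.gene_ids)
        if isinstance(W, WeightedAdjacency)
        else list(range(mat.shape[0]))
    )
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    # deterministic column-major scan
    for j in range(mat.shape[1]):
        for i in range(mat.shape[0]):
            if i != j and abs(mat[i, j]) > threshold:
                g.add_edge(labels[i], labels[j])
    return g


def adaptive_threshold(
    W,
    t_start: float = 0.3,
    t_step: float = 0.01,
    t_floor: float = 1e-4,
) -> DagNetwork:
    """Extract a binary DAG by decreasing the threshold until a cycle forms.

    Scans thresholds ``t_start, t_start - t_step, ...`` down to ``t_floor``
    and returns the binarized graph at the last threshold whose graph is
    still acyclic (i.e. the threshold immediately before the first cyclic
    graph, or ``t_floor`` when no cycle ever forms).
    """
    if not (t_start > t_floor >= 0):
        raise ValueError("need t_start > t_floor >= 0")
    if t_step <= 0:
        raise ValueError("t_step must be positive")
    mat = _as_matrix(W)
    labels = (
        tuple(W.gene_ids)
        if isinstance(W, WeightedAdjacency)
        else tuple(str(i) for i in range(mat.shape[0]))
    )
    thresholds = list(np.arange(t_start, t_floor, -t_step))
    if not thresholds or thresholds[-1] > t_floor:
        thresholds.append(t_floor)

    last_good: float | None = None
    last_edges: frozenset | None = None
    for t in thresholds:
        mask = np.abs(mat) > t
        np.fill_diagonal(mask, False)
        g = nx.DiGraph()
        g.add_nodes_from(range(mat.shape[0]))
        ii, jj = np.nonzero(mask)
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        if nx.is_directed_acyclic_graph(g):
            last_good = t
            last_edges = frozenset(
                (labels[i], labels[j]) for i, j in zip(ii.tolist(), jj.tolist())
            )
        else:
            break
    if last_good is None:
        raise ValueError(
            f"graph already cyclic at t_start={t_start}: increase t_start"
        )
    return DagNetwork(gene_ids=labels, edges=last_edges, threshold_used=float(last_good))


def _stage_minimize(
    W0: np.ndarray,
    X: np.ndarray,
    mu: float,
    cfg: LearnerConfig,
    trace: list,
    pen: np.ndarray,
) -> np.ndarray:
    """Minimize ``mu*(score + weighted L1) + h`` by Adam with domain
    backtracking; ``pen`` is the per-entry L1 weight matrix."""
    n = X.shape[0]
    gram = X.T @ X / n  # reused every iteration
    W = W0.copy()
    lr = cfg.step_size
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def objective(Wc):
        resid = X - X @ Wc
        score = 0.5 / n * np.sum(resid * resid)
        return mu * (score + cfg.lambda1 * (pen * np.abs(Wc)).sum()), score

    obj_prev, _ = objective(W)
    obj_prev += acyclicity_logdet(W, cfg.s)
    halvings = 0
    t = 0
    it = 0
    while it < cfg.inner_max_iter:
        it += 1
        try:
            _, M = _logdet_M(W, cfg.s)
            grad_h = 2.0 * np.linalg.inv(M).T * W
        except AcyclicityDomainError:
            # should not happen: W is only accepted in-domain below
            raise OptimizationError("iterate left the constraint domain", W0)
        grad_score = gram @ W - gram
        grad = mu * grad_score + grad_h
        np.fill_diagonal(grad, 0.0)

        t += 1
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad * grad
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        scale = lr / (np.sqrt(vhat) + eps)
        step = scale * mhat
        # proximal handling of the L1 term: soft-threshold by the effective
        # per-coordinate step size, yielding exact zeros
        W_new = W - step
        W_new = np.sign(W_new) * np.maximum(
            np.abs(W_new) - scale * mu * cfg.lambda1 * pen, 0.0
        )
        np.fill_diagonal(W_new, 0.0)

        # backtracking: halve the step until the iterate is in-domain
        ok = False
        for _ in range(30):
            try:
                _logdet_M(W_new, cfg.s)
                ok = True
                break
            except AcyclicityDomainError:
                scale *= 0.5
                lr *= 0.5
                halvings += 1
                W_new = W - scale * mhat
                W_new = np.sign(W_new) * np.maximum(
                    np.abs(W_new) - scale * mu * cfg.lambda1 * pen, 0.0
                )
                np.fill_diagonal(W_new, 0.0)
        if not ok:
            raise OptimizationError(
                "could not recover an in-domain iterate after 30 halvings", W
            )
        W = W_new

        if it % 100 == 0 or it == cfg.inner_max_iter:
            obj_pen, score = objective(W)
            obj = obj_pen + acyclicity_logdet(W, cfg.s)
            trace.append(
                {"mu": mu, "iter": it, "objective": float(obj), "score": float(score)}
            )
            if abs(obj_prev - obj) <= cfg.tol * (abs(obj_prev) + 1.0):
                break
            obj_prev = obj
    return W


def fit_linear_sem(
    X: ExpressionMatrix,
    cfg: LearnerConfig | None = None,
) -> WeightedAdjacency:
    """Fit the penalized, acyclicity-constrained linear SEM to ``X``.

    Returns the weighted adjacency of the final path stage. The per-stage
    objective trace is attached as ``result.trace`` (list of dicts), and is
    non-increasing across stages up to solver tolerance.
    """
    cfg = cfg or LearnerConfig()
    vals = X.values
    n, d = vals.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if d == 1:
        out = WeightedAdjacency(np.zeros((1, 1)), X.gene_ids)
        object.__setattr__(out, "trace", [])
        return out

    W = np.zeros((d, d))
    trace: list = []
    if cfg.scale_penalty:
        # weight each coefficient's L1 penalty by its predictor's standard
        # deviation: equivalent to the lasso on standardized predictors while
        # keeping the equal-variance least-squares score, so the selection
        # threshold is scale-free across genes
        pen = np.repeat(vals.std(axis=0)[:, None], d, axis=1)
    else:
        pen = np.ones((d, d))
    for k in range(cfg.path_stages):
        mu = cfg.mu_init * cfg.mu_decay**k
        W = _stage_minimize(W, vals, mu, cfg, trace, pen)

    result = WeightedAdjacency(W, X.gene_ids)
    object.__setattr__(result, "trace", trace)
    return result
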