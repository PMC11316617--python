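"""Benchmarking gene networks by graph-convolutional node regression.

The protocol compares candidate gene networks by how much they help predict a
per-gene scalar property from expression features: genes are split
70/20/10 into train/validation/test (stratified on membership in a reference
network), hyperparameters are tuned on the validation set by seeded random
search, the tuned model is retrained on train+validation, and test MSE and
Pearson r are recorded. The whole process is replicated over multiple splits
and random initializations (5 x 10 = 50 runs by default) to give a mean and
standard error per network, with pairwise Welch t-tests between networks.

Node features are the gene's expression values across conditions; the
propagation operator is the symmetric normalized adjacency
``D^{-1/2} (A + I) D^{-1/2}``, with genes absent from a network included as
isolated nodes carrying a self-loop so their features pass through. An MLP
with the same hidden-layer structure serves as the graph-free baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam, Tensor, leaky_relu, relu
from .containers import ExpressionMatrix, GeneNetwork
from .stats import WelchResult, standard_error, welch_t_test

__all__ = [
    "SplitSpec",
    "GnnConfig",
    "EvalReport",
    "stratified_split",
    "normalize_adjacency",
    "neighbor_mean_matrix",
    "NodeRegressor",
    "train",
    "evaluate",
    "hyperparameter_search",
    "default_search_space",
    "run_protocol",
]

Variant = Literal[
    "gcn2", "gcn3", "gcn4", "attention", "simplified_k2", "sage_inductive", "mlp"
]


# ---------------------------------------------------------------------------
# Splits


@dataclass(frozen=True)
class SplitSpec:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    strata: Mapping[str, int]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("splits must be disjoint")


def stratified_split(
    genes: Sequence[str],
    strata: Mapping[str, int] | None = None,
    fractions: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Deterministic per-stratum proportional train/val/test allocation."""
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three numbers summing to 1")
    genes = [str(g) for g in genes]
    strata = {str(g): int((strata or {}).get(g, 0)) for g in genes}
    rng = np.random.default_rng(seed)
    groups: dict[int, list[str]] = {}
    for g in genes:
        groups.setdefault(strata[g], []).append(g)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for label in sorted(groups):
        members = sorted(groups[label])
        rng.shuffle(members)
        n = len(members)
        n_train = round(fractions[0] * n)
        n_val = round(fractions[1] * n)
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) < 1:
            raise ValueError(
                f"stratum {label} with {n} genes is too small for a "
                f"{fractions} split"
            )
        train += members[:n_train]
        val += members[n_train : n_train + n_val]
        test += members[n_train + n_val :]
    return SplitSpec(
        train=tuple(train), val=tuple(val), test=tuple(test),
        strata=strata, seed=seed,
    )


# ---------------------------------------------------------------------------
# Propagation operators


def normalize_adjacency(
    net: GeneNetwork | None, universe: Sequence[str]
) -> np.ndarray:
    """Symmetric GCN propagation operator ``D^{-1/2} (A + I) D^{-1/2}``.

    ``universe`` fixes row/column order; genes missing from the network are
    isolated nodes whose row is the unit self-entry. ``net=None`` gives the
    identity (the MLP limit)."""
    universe = [str(g) for g in universe]
    d = len(universe)
    A = np.eye(d)
    if net is not None:
        index = {g: i for i, g in enumerate(universe)}
        for u, v in net.undirected().edges:
            if u in index and v in index:
                A[index[u], index[v]] = 1.0
                A[index[v], index[u]] = 1.0
    deg = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    return A * dinv[:, None] * dinv[None, :]


def neighbor_mean_matrix(
    net: GeneNetwork | None, universe: Sequence[str]
) -> np.ndarray:
    """Row-normalized adjacency without self-loops (neighbor-mean operator);
    isolated nodes get an all-zero row."""
    universe = [str(g) for g in universe]
    d = len(universe)
    A = np.zeros((d, d))
    if net is not None:
        index = {g: i for i, g in enumerate(universe)}
        for u, v in net.undirected().edges:
            if u in index and v in index:
                A[index[u], index[v]] = 1.0
                A[index[v], index[u]] = 1.0
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    return A * inv[:, None]


# ---------------------------------------------------------------------------
# Models


@dataclass(frozen=True)
class GnnConfig:
    """Architecture and training hyperparameters of one model."""

    hidden: tuple[int, int, int] = (64, 32, 16)
    learning_rate: float = 1e-2
    epochs: int = 100
    variant: Variant = "gcn2"
    feature_scaling: Literal["none", "minmax"] = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) != 3 or any(h < 1 for h in self.hidden):
            raise ValueError("hidden must be three positive sizes")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class NodeRegressor:
    """A node-level regressor over a fixed propagation operator.

    Variants: ``gcn2`` (two conv blocks + dense head), ``gcn3``/``gcn4``
    (one/two extra conv blocks), ``attention`` (learned per-edge attention
    in place of the fixed operator), ``simplified_k2`` (squared operator with
    one affine map), ``sage_inductive`` (separate self/neighbor affines over
    neighbor means; supports training on an induced subgraph), ``mlp`` (no
    propagation).
    """

    def __init__(self, cfg: GnnConfig, in_dim: int):
        self.cfg = cfg
        self.in_dim = in_dim
        rng = np.random.default_rng(cfg.seed)
        h1, h2, h3 = cfg.hidden
        p: dict[str, Tensor] = {}
        v = cfg.variant

        def lin(name: str, fi: int, fo: int) -> None:
            p[f"{name}_W"] = ad.parameter(_glorot(rng, fi, fo))
            p[f"{name}_b"] = ad.parameter(np.zeros(fo))

        if v == "mlp":
            lin("l1", in_dim, h1)
            lin("l2", h1, h2)
        elif v in ("gcn2", "gcn3", "gcn4", "attention"):
            lin("conv1", in_dim, h1)
            lin("conv2", h1, h2)
            n_extra = {"gcn2": 0, "attention": 0, "gcn3": 1, "gcn4": 2}[v]
            for k in range(n_extra):
                lin(f"conv{3 + k}", h2, h2)
            if v == "attention":
                p["att_a1"] = ad.parameter(rng.normal(0, 0.1, size=(h1, 1)))
                p["att_a2"] = ad.parameter(rng.normal(0, 0.1, size=(h2, 1)))
        elif v == "simplified_k2":
            lin("conv1", in_dim, h2)
        elif v == "sage_inductive":
            p["s1_Wself"] = ad.parameter(_glorot(rng, in_dim, h1))
            p["s1_Wneigh"] = ad.parameter(_glorot(rng, in_dim, h1))
            p["s1_b"] = ad.parameter(np.zeros(h1))
            p["s2_Wself"] = ad.parameter(_glorot(rng, h1, h2))
            p["s2_Wneigh"] = ad.parameter(_glorot(rng, h1, h2))
            p["s2_b"] = ad.parameter(np.zeros(h2))
        else:
            raise ValueError(f"unknown variant {v!r}")
        lin("dense", h2 if v != "mlp" else h2, h3)
        lin("out", h3, 1)
        self.params = p

    # -- forward ------------------------------------------------------------

    def _attention_prop(self, H: Tensor, mask: np.ndarray, which: int) -> Tensor:
        a = self.params[f"att_a{which}"]
        U = H  # already W-transformed by the caller
        S = U.expand_dims(1) + U.expand_dims(0)  # (n, n, k)
        E = (leaky_relu(S, 0.2) @ a).reshape(mask.shape)
        neg = Tensor((1.0 - mask) * -1e9)
        E = E * Tensor(mask) + neg
        # row-constant shift: softmax is invariant, so the detached max is exact
        shifted = E - Tensor(E.data.max(axis=1, keepdims=True))
        expE = shifted.exp() * Tensor(mask)
        return expE / expE.sum(axis=1, keepdims=True)

    def conv_output(self, features: np.ndarray, prop: np.ndarray) -> Tensor:
        """Post-activation output of the last graph-convolution stage (the
        node embedding used downstream)."""
        p = self.params
        H = Tensor(features)
        P = Tensor(prop)
        v = self.cfg.variant
        if v == "mlp":
            H = relu(H @ p["l1_W"] + p["l1_b"])
            return relu(H @ p["l2_W"] + p["l2_b"])
        if v == "simplified_k2":
            return Tensor(prop @ prop) @ H @ p["conv1_W"] + p["conv1_b"]
        if v == "sage_inductive":
            for layer in ("s1", "s2"):
                H = relu(
                    H @ p[f"{layer}_Wself"]
                    + (P @ H) @ p[f"{layer}_Wneigh"]
                    + p[f"{layer}_b"]
                )
            return H
        # gcn2 / gcn3 / gcn4 / attention
        mask = (prop != 0).astype(float) if v == "attention" else None
        H1 = H @ p["conv1_W"]
        if v == "attention":
            H1 = self._attention_prop(H1, mask, 1) @ H1
        else:
            H1 = P @ H1
        H = relu(H1 + p["conv1_b"])
        H2 = H @ p["conv2_W"]
        if v == "attention":
            H2 = self._attention_prop(H2, mask, 2) @ H2
        else:
            H2 = P @ H2
        H = relu(H2 + p["conv2_b"])
        n_extra = {"gcn2": 0, "attention": 0, "gcn3": 1, "gcn4": 2}[v]
        for k in range(n_extra):
            H = relu(P @ (H @ p[f"conv{3 + k}_W"]) + p[f"conv{3 + k}_b"])
        return H

    def forward(self, features: np.ndarray, prop: np.ndarray) -> Tensor:
        p = self.params
        H = self.conv_output(features, prop)
        H = relu(H @ p["dense_W"] + p["dense_b"])
        return (H @ p["out_W"] + p["out_b"]).reshape(-1)

    def predict(self, features: np.ndarray, prop: np.ndarray) -> np.ndarray:
        return self.forward(features, prop).data


def _propagation_for(
    cfg: GnnConfig, net: GeneNetwork | None, universe: Sequence[str]
) -> np.ndarray:
    if cfg.variant == "sage_inductive":
        return neighbor_mean_matrix(net, universe)
    return normalize_adjacency(net, universe)


# ---------------------------------------------------------------------------
# Training and evaluation


def train(
    cfg: GnnConfig,
    features: np.ndarray,
    y: np.ndarray,
    prop: np.ndarray,
    train_genes: Sequence[int],
    val_genes: Sequence[int] = (),
) -> tuple[NodeRegressor, float | None]:
    """Full-batch Adam on the masked train-gene MSE.

    Only train-gene targets enter the loss; validation/test targets cannot
    influence the parameters. Returns the model and the final validation MSE
    (None when no validation genes are given).
    """
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    model = NodeRegressor(cfg, features.shape[1])
    mask = np.zeros(len(y))
    mask[list(train_genes)] = 1.0
    n_train = mask.sum()
    opt = Adam(model.params, lr=cfg.learning_rate)
    y_t = Tensor(y)
    mask_t = Tensor(mask)
    for epoch in range(cfg.epochs):
        preds = model.forward(features, prop)
        loss = (((preds - y_t) * mask_t) ** 2).sum() * (1.0 / n_train)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged (non-finite loss) with {cfg}")
        loss.backward()
        opt.step()
    val_mse = None
    if len(val_genes):
        preds = model.predict(features, prop)
        idx = list(val_genes)
        val_mse = float(np.mean((preds[idx] - y[idx]) ** 2))
    return model, val_mse


def evaluate(predictions, truth) -> dict[str, float | None]:
    """Test-set MSE and Pearson r; r is None for constant predictions."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mse = float(np.mean((predictions - truth) ** 2))
    r: float | None = None
    if len(truth) >= 2 and predictions.std() > 0 and truth.std() > 0:
        r = float(np.corrcoef(predictions, truth)[0, 1])
    return {"mse": mse, "pearson_r": r}


# ---------------------------------------------------------------------------
# Hyperparameter search


def default_search_space() -> dict:
    """Random-search space: hidden sizes, log-uniform learning rate, epochs."""
    return {
        "hidden": [16, 32, 64, 128],
        "learning_rate": (1e-4, 3e-2),
        "epochs": [30, 50, 100, 150],
    }


def _sample_config(
    rng: np.random.Generator, space: dict, base: GnnConfig
) -> GnnConfig:
    hidden = tuple(int(rng.choice(space["hidden"])) for _ in range(3))
    lo, hi = space["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    epochs = int(rng.choice(space["epochs"]))
    return replace(base, hidden=hidden, learning_rate=lr, epochs=epochs)


def hyperparameter_search(
    space: dict,
    budget: int,
    features: np.ndarray,
    y: np.ndarray,
    prop: np.ndarray,
    split_idx: tuple[Sequence[int], Sequence[int]],
    seed: int,
    base: GnnConfig | None = None,
) -> tuple[GnnConfig, list[dict]]:
    """Seeded random search; returns the config with the lowest validation
    MSE plus the full trial table."""
    base = base or GnnConfig()
    rng = np.random.default_rng(seed)
    train_idx, val_idx = split_idx
    trials: list[dict] = []
    best_cfg, best_mse = None, np.inf
    for trial in range(budget):
        cfg = replace(_sample_config(rng, space, base), seed=int(rng.integers(2**31)))
        try:
            _, val_mse = train(cfg, features, y, prop, train_idx, val_idx)
        except RuntimeError:
            val_mse = np.inf
        trials.append({"trial": trial, "config": cfg, "val_mse": val_mse})
        if val_mse is not None and val_mse < best_mse:
            best_cfg, best_mse = cfg, val_mse
    if best_cfg is None:
        raise RuntimeError("every search trial diverged")
    return best_cfg, trials


# ---------------------------------------------------------------------------
# Full protocol


@dataclass
class EvalReport:
    """Per-run test metrics over replicated splits and initializations."""

    network: str
    runs: list[dict]
    mean_mse: float
    se_mse: float | None
    mean_r: float | None
    se_r: float | None
    welch_vs_first: WelchResult | None = None
    best_model: NodeRegressor | None = None
    best_run: dict | None = None

    @property
    def mses(self) -> np.ndarray:
        return np.asarray([r["mse"] for r in self.runs])


def _make_report(name: str, runs: list[dict], models: list[NodeRegressor]) -> EvalReport:
    mses = np.asarray([r["mse"] for r in runs])
    rs = [r["pearson_r"] for r in runs if r["pearson_r"] is not None]
    best_i = int(np.argmin(mses))
    return EvalReport(
        network=name,
        runs=runs,
        mean_mse=float(mses.mean()),
        se_mse=standard_error(mses),
        mean_r=float(np.mean(rs)) if rs else None,
        se_r=standard_error(rs) if len(rs) > 1 else None,
        best_model=models[best_i] if models else None,
        best_run=runs[best_i],
    )


def run_protocol(
    networks: Mapping[str, GeneNetwork | None],
    X: ExpressionMatrix,
    y: Mapping[str, float],
    n_splits: int = 5,
    n_inits: int = 10,
    budget: int = 20,
    seed: int = 0,
    strata: Mapping[str, int] | None = None,
    base: GnnConfig | None = None,
    space: dict | None = None,
) -> dict[str, EvalReport]:
    """The full split x init x search protocol for every named network.

    ``networks[name] = None`` runs the MLP baseline. Splits are stratified on
    ``strata`` (by convention, membership in the reference network). For each
    of the ``n_splits * n_inits`` runs the tuned model is retrained on
    train+validation and scored on the held-out test genes. Reports include a
    two-sided Welch t-test of each network's per-run MSEs against the
    first-listed network's.
    """
    universe = list(X.gene_ids)
    features = X.values.T  # genes x conditions
    targets = np.asarray([float(y[g]) for g in universe])
    space = space or default_search_space()
    ss = np.random.SeedSequence(seed)
    split_seeds = [int(s) for s in ss.generate_state(n_splits) % (2**31)]
    idx = {g: i for i, g in enumerate(universe)}

    reports: dict[str, EvalReport] = {}
    for name, net in networks.items():
        base_cfg = base or GnnConfig()
        if net is None:
            base_cfg = replace(base_cfg, variant="mlp")
        feats = features
        if base_cfg.feature_scaling == "minmax":
            lo, hi = feats.min(axis=0), feats.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            feats = (feats - lo) / span
        prop = _propagation_for(base_cfg, net, universe)
        runs: list[dict] = []
        models: list[NodeRegressor] = []
        for si, split_seed in enumerate(split_seeds):
            split = stratified_split(universe, strata, seed=split_seed)
            tr = [idx[g] for g in split.train]
            va = [idx[g] for g in split.val]
            te = [idx[g] for g in split.test]
            init_seeds = np.random.SeedSequence([seed, si, 7]).generate_state(n_inits)
            for ii, init_seed in enumerate(int(s) % (2**31) for s in init_seeds):
                cfg, _ = hyperparameter_search(
                    space, budget, feats, targets, prop, (tr, va),
                    seed=init_seed, base=base_cfg,
                )
                model, _ = train(cfg, feats, targets, prop, tr + va)
                preds = model.predict(feats, prop)
                metrics = evaluate(preds[te], targets[te])
                runs.append(
                    {"split": si, "init": ii, "config": cfg, **metrics}
                )
                models.append(model)
        reports[name] = _make_report(name, runs, models)

    names = list(reports)
    if len(names) > 1:
        ref = reports[names[0]].mses
        if len(ref) >= 2:
            for name in names[1:]:
                reports[name].welch_vs_first = welch_t_test(reports[name].mses, ref)
    return reports
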