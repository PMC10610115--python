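"""Graph-attention regression network in pure NumPy.

The model stacks multi-head graph attention (GAT) layers over the heavy-atom
graph, a permutation-invariant readout over nodes, and a single MLP head that
emits one regression value per molecule.  Attention per directed edge j->i is

    e_ij = LeakyReLU(a_src . W h_j + a_dst . W h_i)
    alpha_ij = softmax_j(e_ij)        (over in-neighbours of i, incl. self)
    h_i' = ELU( concat_heads( sum_j alpha_ij W h_j ) + b )

Gradients are computed by hand-written reverse-mode passes; a finite
difference check in the test suite pins their correctness.  Everything runs
on CPU and is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for the GAT regressor."""

    n_gat_layers: int = 3
    attention_heads: int = 4
    hidden_dim: int = 64
    mlp_dims: tuple = (64, 32)
    dropout: float = 0.0
    readout: str = "mean"

    def __post_init__(self):
        if self.n_gat_layers < 1 or self.attention_heads < 1 or self.hidden_dim < 1:
            raise ValueError("layer count, heads and hidden dim must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if any(d <= 0 for d in self.mlp_dims):
            raise ValueError("mlp dims must be positive")


@dataclass
class PackedBatch:
    """A set of graphs packed into one disjoint union.

    ``src``/``dst`` are directed edges (both bond directions plus one
    self-loop per node); ``graph_id`` maps each node to its graph.  The
    ``*_order``/``*_starts`` arrays sort edges by endpoint so segment
    reductions run via ``ufunc.reduceat`` (every node has a self-loop, so
    no segment is empty).
    """

    X: np.ndarray         # (N, d)
    src: np.ndarray       # (E,)
    dst: np.ndarray       # (E,)
    graph_id: np.ndarray  # (N,)
    n_graphs: int
    counts: np.ndarray    # nodes per graph, (n_graphs,)
    src_order: np.ndarray = None
    src_starts: np.ndarray = None
    dst_order: np.ndarray = None
    dst_starts: np.ndarray = None

    def __post_init__(self):
        n = self.X.shape[0]
        if self.src_order is None:
            self.src_order = np.argsort(self.src, kind="stable")
            self.src_starts = np.searchsorted(self.src[self.src_order], np.arange(n))
            self.dst_order = np.argsort(self.dst, kind="stable")
            self.dst_starts = np.searchsorted(self.dst[self.dst_order], np.arange(n))


def _seg_sum(values: np.ndarray, order: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum edge values into node bins using a pre-sorted edge order."""
    return np.add.reduceat(values[order], starts, axis=0)


def _seg_max(values: np.ndarray, order: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.maximum.reduceat(values[order], starts, axis=0)


def pack_graphs(graphs: Sequence) -> PackedBatch:
    """Pack MolGraphs into a single batch with symmetric closure + self-loops."""
    xs, srcs, dsts, gids, counts = [], [], [], [], []
    offset = 0
    for g_idx, g in enumerate(graphs):
        n = g.node_features.shape[0]
        xs.append(g.node_features)
        if len(g.edges):
            i = g.edges[:, 0] + offset
            j = g.edges[:, 1] + offset
            srcs += [i, j]
            dsts += [j, i]
        loops = np.arange(offset, offset + n)
        srcs.append(loops)
        dsts.append(loops)
        gids.append(np.full(n, g_idx))
        counts.append(n)
        offset += n
    return PackedBatch(
        X=np.vstack(xs),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
        counts=np.asarray(counts),
    )


def _leaky(x):
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def _leaky_grad(x):
    return np.where(x > 0, 1.0, LEAKY_SLOPE)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.clip(x, None, 0.0)))


def _segment_softmax(e: np.ndarray, batch: PackedBatch):
    """Softmax of edge scores over incoming edges of each dst node."""
    m = _seg_max(e, batch.dst_order, batch.dst_starts)
    ex = np.exp(e - m[batch.dst])
    denom = _seg_sum(ex, batch.dst_order, batch.dst_starts)
    return ex / denom[batch.dst]


def init_params(cfg: ModelConfig, in_dim: int, rng: np.random.Generator) -> dict:
    """Glorot-initialized parameter dict for the full network."""
    params: dict[str, np.ndarray] = {}
    H, F = cfg.attention_heads, cfg.hidden_dim
    d = in_dim
    for layer in range(cfg.n_gat_layers):
        s = np.sqrt(6.0 / (d + F))
        params[f"gat{layer}_W"] = rng.uniform(-s, s, size=(H, d, F))
        params[f"gat{layer}_asrc"] = rng.uniform(-s, s, size=(H, F))
        params[f"gat{layer}_adst"] = rng.uniform(-s, s, size=(H, F))
        params[f"gat{layer}_b"] = np.zeros(H * F)
        d = H * F
    dims = [d, *cfg.mlp_dims, 1]
    for k in range(len(dims) - 1):
        s = np.sqrt(6.0 / (dims[k] + dims[k + 1]))
        params[f"mlp{k}_W"] = rng.uniform(-s, s, size=(dims[k], dims[k + 1]))
        params[f"mlp{k}_b"] = np.zeros(dims[k + 1])
    return params


def _gat_forward(X, batch: PackedBatch, W, a_src, a_dst, b):
    H, _, F = W.shape
    N = X.shape[0]
    src, dst = batch.src, batch.dst
    cache = {"X": X}
    out = np.empty((N, H * F))
    cache["heads"] = []
    for h in range(H):
        Z = X @ W[h]                       # (N, F)
        s_s = Z @ a_src[h]                 # (N,)
        s_d = Z @ a_dst[h]
        e_pre = s_s[src] + s_d[dst]        # (E,)
        e = _leaky(e_pre)
        alpha = _segment_softmax(e, batch)
        agg = _seg_sum(alpha[:, None] * Z[src], batch.dst_order, batch.dst_starts)
        out[:, h * F:(h + 1) * F] = agg
        cache["heads"].append({"Z": Z, "e_pre": e_pre, "alpha": alpha})
    pre = out + b
    cache["pre"] = pre
    return _elu(pre), cache


def _gat_backward(dY, cache, batch: PackedBatch, W, a_src, a_dst):
    H, d_in, F = W.shape
    X = cache["X"]
    src, dst = batch.src, batch.dst
    dPre = dY * _elu_grad(cache["pre"])
    grads = {
        "W": np.zeros_like(W),
        "asrc": np.zeros_like(a_src),
        "adst": np.zeros_like(a_dst),
        "b": dPre.sum(axis=0),
    }
    dX = np.zeros_like(X)
    for h in range(H):
        hc = cache["heads"][h]
        Z, e_pre, alpha = hc["Z"], hc["e_pre"], hc["alpha"]
        dOut = dPre[:, h * F:(h + 1) * F]
        dOut_dst = dOut[dst]
        Z_src = Z[src]
        dZ = _seg_sum(alpha[:, None] * dOut_dst, batch.src_order, batch.src_starts)
        dAlpha = np.einsum("ef,ef->e", dOut_dst, Z_src)
        # softmax backward per dst segment
        seg_dot = _seg_sum(alpha * dAlpha, batch.dst_order, batch.dst_starts)
        dE = alpha * (dAlpha - seg_dot[dst])
        dEpre = dE * _leaky_grad(e_pre)
        ds_s = _seg_sum(dEpre, batch.src_order, batch.src_starts)
        ds_d = _seg_sum(dEpre, batch.dst_order, batch.dst_starts)
        grads["asrc"][h] = Z.T @ ds_s
        grads["adst"][h] = Z.T @ ds_d
        dZ += np.outer(ds_s, a_src[h]) + np.outer(ds_d, a_dst[h])
        grads["W"][h] = X.T @ dZ
        dX += dZ @ W[h].T
    return dX, grads


def _readout_forward(Hn, batch: PackedBatch, kind: str):
    G = batch.n_graphs
    if kind in ("mean", "sum"):
        # nodes are packed contiguously per graph
        starts = np.concatenate([[0], np.cumsum(batch.counts)[:-1]])
        R = np.add.reduceat(Hn, starts, axis=0)
        if kind == "mean":
            R = R / batch.counts[:, None]
        return R, None
    # max readout: per-graph argmax bookkeeping for the backward pass
    R = np.full((G, Hn.shape[1]), -np.inf)
    arg = np.zeros((G, Hn.shape[1]), dtype=int)
    for g in range(G):
        idx = np.flatnonzero(batch.graph_id == g)
        sub = Hn[idx]
        a = sub.argmax(axis=0)
        R[g] = sub[a, np.arange(sub.shape[1])]
        arg[g] = idx[a]
    return R, arg


def _readout_backward(dR, batch: PackedBatch, kind: str, n_nodes: int, arg):
    dH = np.zeros((n_nodes, dR.shape[1]))
    if kind == "mean":
        dH = dR[batch.graph_id] / batch.counts[batch.graph_id][:, None]
    elif kind == "sum":
        dH = dR[batch.graph_id]
    else:
        for g in range(dR.shape[0]):
            dH[arg[g], np.arange(dR.shape[1])] += dR[g]
    return dH


def forward(
    params: dict,
    cfg: ModelConfig,
    batch: PackedBatch,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full forward pass; returns (predictions (G,), cache)."""
    cache: dict = {"gat": [], "drop": []}
    Hn = batch.X
    for layer in range(cfg.n_gat_layers):
        Hn, c = _gat_forward(
            Hn, batch,
            params[f"gat{layer}_W"], params[f"gat{layer}_asrc"],
            params[f"gat{layer}_adst"], params[f"gat{layer}_b"],
        )
        if train and cfg.dropout > 0.0:
            mask = (rng.random(Hn.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            Hn = Hn * mask
            cache["drop"].append(mask)
        else:
            cache["drop"].append(None)
        cache["gat"].append(c)
    R, arg = _readout_forward(Hn, batch, cfg.readout)
    cache["readout_arg"] = arg
    cache["n_nodes"] = Hn.shape[0]
    cache["mlp"] = []
    A = R
    n_mlp = len(cfg.mlp_dims) + 1
    for k in range(n_mlp):
        pre = A @ params[f"mlp{k}_W"] + params[f"mlp{k}_b"]
        cache["mlp"].append({"A": A, "pre": pre})
        A = np.maximum(pre, 0.0) if k < n_mlp - 1 else pre
    return A[:, 0], cache


def backward(params: dict, cfg: ModelConfig, batch: PackedBatch, cache: dict, dPred: np.ndarray):
    """Reverse pass; returns parameter-gradient dict matching ``params``."""
    grads: dict[str, np.ndarray] = {}
    n_mlp = len(cfg.mlp_dims) + 1
    dA = dPred[:, None]
    for k in reversed(range(n_mlp)):
        mc = cache["mlp"][k]
        dPre = dA if k == n_mlp - 1 else dA * (mc["pre"] > 0)
        grads[f"mlp{k}_W"] = mc["A"].T @ dPre
        grads[f"mlp{k}_b"] = dPre.sum(axis=0)
        dA = dPre @ params[f"mlp{k}_W"].T
    dH = _readout_backward(dA, batch, cfg.readout, cache["n_nodes"], cache["readout_arg"])
    for layer in reversed(range(cfg.n_gat_layers)):
        if cache["drop"][layer] is not None:
            dH = dH * cache["drop"][layer]
        dH, g = _gat_backward(
            dH, cache["gat"][layer], batch,
            params[f"gat{layer}_W"], params[f"gat{layer}_asrc"], params[f"gat{layer}_adst"],
        )
        grads[f"gat{layer}_W"] = g["W"]
        grads[f"gat{layer}_asrc"] = g["asrc"]
        grads[f"gat{layer}_adst"] = g["adst"]
        grads[f"gat{layer}_b"] = g["b"]
    return grads


def mse_loss_and_grads(params, cfg, batch, y, rng=None, train=True):
    """Mean-squared-error loss over one packed batch plus its gradients."""
    pred, cache = forward(params, cfg, batch, train=train, rng=rng)
    resid = pred - y
    loss = float(np.mean(resid**2))
    dPred = 2.0 * resid / len(y)
    grads = backward(params, cfg, batch, cache, dPred)
    return loss, grads, pred


@dataclass
class Adam:
    """Adam optimizer over a parameter dict."""

    lr: float = 5e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
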