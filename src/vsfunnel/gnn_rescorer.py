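"""Training and application of the GAT+MLP pIC50 rescorer.

The rescorer learns a regression from score-augmented molecular graphs to
pIC50 under an 8:1:1 train/validation/test split, minimizing mean-squared
error with early stopping on the validation split, and reports R-squared on
all three splits.  Everything is seeded: two runs with the same seed produce
identical splits, initial parameters, batch orders, and hence identical fit
reports on CPU.
"""

from __future__ import annotations

import copy
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .mol_graph import FeatureScaler, MolGraph
from .nn import Adam, ModelConfig, PackedBatch, pack_graphs


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``split_ratio`` is interpreted as fractions."""

    split_ratio: tuple = (8, 1, 1)
    seed: int = 0
    epochs: int = 200
    learning_rate: float = 5e-3
    batch_size: int = 128
    #: epochs without val improvement before stopping; None disables early
    #: stopping entirely (the final-epoch parameters are kept).
    early_stop_patience: int | None = 30


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple


@dataclass
class FitReport:
    r2_train: float
    r2_val: float
    r2_test: float
    loss_curve: list
    best_epoch: int


@dataclass
class GATRescorer:
    """A trained model handle: parameters, architecture, optional scaler."""

    params: dict
    config: ModelConfig
    in_dim: int
    scaler: FeatureScaler | None = None
    split: SplitAssignment | None = None


def split_dataset(ids: Sequence[str], ratio: tuple = (8, 1, 1), seed: int = 0) -> SplitAssignment:
    """Seeded shuffle into train/val/test.

    Validation and test each get ``floor(n * r / sum(ratio))`` entries; the
    remainder goes to train.  With the default (8, 1, 1) ratio, n = 10 gives
    (8, 1, 1) and n = 1072 gives (858, 107, 107).
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 ids for an 8:1:1 split, got {n}")
    if len(ratio) != 3 or any(r <= 0 for r in ratio):
        raise ValueError("ratio must be three positive numbers")
    total = sum(ratio)
    n_val = int(n * ratio[1] / total)
    n_test = int(n * ratio[2] / total)
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = n - n_val - n_test
    return SplitAssignment(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train:n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val:]),
    )


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: zero variance in y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _predict_packed(params, cfg, batch: PackedBatch) -> np.ndarray:
    pred, _ = nn.forward(params, cfg, batch, train=False)
    return pred


def train_model(
    graphs: Sequence[MolGraph],
    labels: Mapping[str, float],
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    split: SplitAssignment | None = None,
    scaler: FeatureScaler | None = None,
) -> tuple[GATRescorer, FitReport]:
    """Fit the GAT regressor on pIC50-labelled graphs.

    The split is computed internally from the graph ids (or taken from
    ``split`` when the caller already fitted a scaler on its training part).
    Raises if the training labels have zero variance (R-squared undefined).
    """
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    if not graphs:
        raise ValueError("no graphs")
    by_id = {g.mol_id: g for g in graphs}
    y_all = {i: float(labels[i]) for i in by_id}
    if not all(np.isfinite(v) for v in y_all.values()):
        raise ValueError("non-finite label")
    if split is None:
        split = split_dataset(sorted(by_id), ratio=tcfg.split_ratio, seed=tcfg.seed)

    def subset(idlist):
        gs = [by_id[i] for i in idlist]
        ys = np.array([y_all[i] for i in idlist])
        return gs, ys

    train_g, train_y = subset(split.train_ids)
    val_g, val_y = subset(split.val_ids)
    test_g, test_y = subset(split.test_ids)
    if np.var(train_y) == 0.0:
        raise ValueError("zero label variance in training split")

    in_dim = train_g[0].node_features.shape[1]
    if any(g.node_features.shape[1] != in_dim for g in graphs):
        raise ValueError("inconsistent feature dimensions across graphs")

    rng = np.random.default_rng(tcfg.seed)
    params = nn.init_params(mcfg, in_dim, rng)
    opt = Adam(lr=tcfg.learning_rate)

    val_batch = pack_graphs(val_g) if val_g else None
    loss_curve: list[float] = []
    best = {"val": np.inf, "epoch": 0, "params": copy.deepcopy(params)}
    n_train = len(train_g)

    for epoch in range(tcfg.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            batch = pack_graphs([train_g[i] for i in idx])
            loss, grads, _ = nn.mse_loss_and_grads(
                params, mcfg, batch, train_y[idx], rng=rng, train=True
            )
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        loss_curve.append(epoch_loss / n_train)

        if tcfg.early_stop_patience is None:
            best = {"val": loss_curve[-1], "epoch": epoch, "params": params}
        elif val_batch is not None and len(val_y) >= 1:
            val_mse = float(np.mean((_predict_packed(params, mcfg, val_batch) - val_y) ** 2))
            if val_mse < best["val"] - 1e-12:
                best = {"val": val_mse, "epoch": epoch, "params": copy.deepcopy(params)}
            elif epoch - best["epoch"] >= tcfg.early_stop_patience:
                break
        else:
            best = {"val": loss_curve[-1], "epoch": epoch, "params": params}

    params = best["params"]
    model = GATRescorer(params=params, config=mcfg, in_dim=in_dim, scaler=scaler, split=split)

    def r2_of(gs, ys):
        if len(gs) < 2 or np.var(ys) == 0.0:
            return float("nan")
        return r_squared(ys, predict(model, gs))

    report = FitReport(
        r2_train=r2_of(train_g, train_y),
        r2_val=r2_of(val_g, val_y),
        r2_test=r2_of(test_g, test_y),
        loss_curve=loss_curve,
        best_epoch=int(best["epoch"]),
    )
    return model, report


def predict(model: GATRescorer, graphs: Sequence[MolGraph]) -> np.ndarray:
    """Deterministic predictions, one per graph, in input order."""
    if len(graphs) == 0:
        return np.empty(0)
    dims = {g.node_features.shape[1] for g in graphs}
    if dims != {model.in_dim}:
        raise ValueError(f"feature dimension {dims} != model dimension {model.in_dim}")
    return _predict_packed(model.params, model.config, pack_graphs(graphs))


def hyperparameter_search(
    space: Mapping[str, Sequence],
    budget: int,
    seed: int,
    graphs: Sequence[MolGraph],
    labels: Mapping[str, float],
    tcfg: TrainConfig | None = None,
) -> tuple[ModelConfig, list]:
    """Seeded random search over a discrete config space, maximizing val R^2.

    ``space`` maps ModelConfig field names to candidate value lists.  Returns
    the best config and the full trial log (config, r2_val pairs).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    trials = []
    base = tcfg or TrainConfig()
    for _ in range(budget):
        choice = {k: v[rng.integers(len(v))] for k, v in space.items()}
        if "mlp_dims" in choice:
            choice["mlp_dims"] = tuple(choice["mlp_dims"])
        cfg = ModelConfig(**choice)
        _, report = train_model(graphs, labels, cfg, base)
        trials.append({"config": cfg, "r2_val": report.r2_val})
    # undefined val R^2 (val split too small for variance) ranks last
    best = max(
        trials,
        key=lambda t: (-np.inf if np.isnan(t["r2_val"]) else t["r2_val"], -trials.index(t)),
    )
    return best["config"], trials


def save_model(model: GATRescorer, path: str | Path) -> None:
    """Persist a model directory: architecture JSON + weights npz (+ scaler)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "config": {
            "n_gat_layers": model.config.n_gat_layers,
            "attention_heads": model.config.attention_heads,
            "hidden_dim": model.config.hidden_dim,
            "mlp_dims": list(model.config.mlp_dims),
            "dropout": model.config.dropout,
            "readout": model.config.readout,
        },
        "in_dim": model.in_dim,
        "scaler": json.loads(model.scaler.to_json()) if model.scaler else None,
        "split": {
            "train_ids": list(model.split.train_ids),
            "val_ids": list(model.split.val_ids),
            "test_ids": list(model.split.test_ids),
        } if model.split else None,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    np.savez(path / "weights.npz", **model.params)


def load_model(path: str | Path) -> GATRescorer:
    path = Path(path)
    try:
        meta = json.loads((path / "model.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported model format {meta.get('format_version')}")
        cfg = ModelConfig(
            n_gat_layers=meta["config"]["n_gat_layers"],
            attention_heads=meta["config"]["attention_heads"],
            hidden_dim=meta["config"]["hidden_dim"],
            mlp_dims=tuple(meta["config"]["mlp_dims"]),
            dropout=meta["config"]["dropout"],
            readout=meta["config"]["readout"],
        )
        with np.load(path / "weights.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        expected = set(nn.init_params(cfg, meta["in_dim"], np.random.default_rng(0)))
        if set(params) != expected:
            raise ValueError("weight file does not match architecture")
    except (OSError, json.JSONDecodeError, KeyError, zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupt or incomplete model at {path}: {exc}") from exc
    scaler = FeatureScaler.from_json(json.dumps(meta["scaler"])) if meta["scaler"] else None
    split = (
        SplitAssignment(
            tuple(meta["split"]["train_ids"]),
            tuple(meta["split"]["val_ids"]),
            tuple(meta["split"]["test_ids"]),
        )
        if meta["split"]
        else None
    )
    return GATRescorer(params=params, config=cfg, in_dim=meta["in_dim"], scaler=scaler, split=split)
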