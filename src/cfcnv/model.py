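"""Training harness for the CNN+attention classifier.

Provides dataset splitting (largest-remainder 75/5/20 apportionment), model
construction, fixed-epoch Adam training with binary cross-entropy, prediction
with a strict 0.5 threshold, window-level attention attribution, and an
exhaustive grid-search harness.

One master seed derives the split, weight-initialization, shuffle, and
dropout streams via ``numpy.random.SeedSequence(seed).spawn(4)``, in that
order.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .nn import Adam, CNNAttentionNet, NetSpec, bce_loss

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SplitSpec",
    "TrainedModel",
    "split_dataset",
    "build_model",
    "train",
    "predict",
    "attention_weights",
    "grid_search",
]

DEFAULT_FRACTIONS = (0.75, 0.05, 0.20)


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its training loop."""

    conv1_filters: int = 32
    conv1_kernel: int = 8
    pool1: int = 4
    conv2_filters: int = 64
    conv2_kernel: int = 8
    pool2: int = 4
    attention_dim: int = 64
    dense1_units: int = 64
    dense2_units: int = 16
    dropout_rate: float = 0.4
    learning_rate: float = 1e-5
    batch_size: int = 512
    epochs: int = 100
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("conv1_filters", "conv1_kernel", "pool1", "conv2_filters",
                     "conv2_kernel", "pool2", "attention_dim", "dense1_units",
                     "dense2_units", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def net_spec(self, n_windows: int) -> NetSpec:
        return NetSpec(
            n_windows=n_windows,
            conv1_filters=self.conv1_filters,
            conv1_kernel=self.conv1_kernel,
            pool1=self.pool1,
            conv2_filters=self.conv2_filters,
            conv2_kernel=self.conv2_kernel,
            pool2=self.pool2,
            attention_dim=self.attention_dim,
            dense1_units=self.dense1_units,
            dense2_units=self.dense2_units,
            dropout_rate=self.dropout_rate,
        )

    def derived_seeds(self) -> dict[str, np.random.SeedSequence]:
        split, init, shuffle, dropout = np.random.SeedSequence(self.seed).spawn(4)
        return {"split": split, "init": init, "shuffle": shuffle, "dropout": dropout}


@dataclass
class SplitSpec:
    """Train/validation/test partition of 0..n-1."""

    n: int
    fractions: tuple[float, float, float]
    seed: int
    sizes: tuple[int, int, int]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def apportion(n: int, fractions=DEFAULT_FRACTIONS) -> tuple[int, ...]:
    """Largest-remainder apportionment of n into len(fractions) parts.

    Floors first, then hands leftover units to the largest remainders; ties
    are broken by position (train > val > test for the default fractions).
    """
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    leftover = n - sum(sizes)
    # stable sort on -remainder keeps earlier positions first on ties
    order = sorted(range(len(fractions)), key=lambda i: -remainders[i])
    for i in order[:leftover]:
        sizes[i] += 1
    return tuple(sizes)


def split_dataset(n: int, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> SplitSpec:
    """Random disjoint train/val/test split with largest-remainder sizes."""
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    sizes = apportion(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val, n_test = sizes
    return SplitSpec(
        n=n,
        fractions=tuple(fractions),
        seed=seed,
        sizes=sizes,
        train_idx=perm[:n_train],
        val_idx=perm[n_train:n_train + n_val],
        test_idx=perm[n_train + n_val:],
    )


def build_model(cfg: ModelConfig, n_windows: int,
                init_seed: int | np.random.SeedSequence | None = None) -> CNNAttentionNet:
    """Instantiate an untrained network for ``n_windows`` input features."""
    spec = cfg.net_spec(n_windows)
    spec.validate()
    if init_seed is None:
        init_seed = cfg.derived_seeds()["init"]
    net = CNNAttentionNet(spec, seed=init_seed)
    logger.info("built model with %d parameters, pooled length %d",
                net.n_parameters, spec.pooled_length)
    return net


@dataclass
class TrainedModel:
    """A trained network plus its config and per-epoch history."""

    net: CNNAttentionNet
    config: ModelConfig
    history: pd.DataFrame
    n_windows: int

    def save(self, model_dir) -> None:
        os.makedirs(model_dir, exist_ok=True)
        with open(os.path.join(model_dir, "config.json"), "w") as fh:
            json.dump({**asdict(self.config), "n_windows": self.n_windows}, fh, indent=2)
        self.history.to_csv(os.path.join(model_dir, "history.tsv"), sep="\t", index=False)
        state = self.net.state_dict()
        np.savez(os.path.join(model_dir, "params.npz"), **state)

    @classmethod
    def load(cls, model_dir) -> "TrainedModel":
        with open(os.path.join(model_dir, "config.json")) as fh:
            meta = json.load(fh)
        n_windows = meta.pop("n_windows")
        cfg = ModelConfig(**meta)
        net = build_model(cfg, n_windows)
        with np.load(os.path.join(model_dir, "params.npz")) as npz:
            net.load_state_dict({k: npz[k] for k in npz.files})
        history = pd.read_csv(os.path.join(model_dir, "history.tsv"), sep="\t")
        return cls(net=net, config=cfg, history=history, n_windows=n_windows)


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: ModelConfig | None = None,
    net: CNNAttentionNet | None = None,
) -> TrainedModel:
    """Fixed-epoch Adam training with binary cross-entropy.

    No early stopping: validation data, when given, is only monitored into
    the history.  Dropout is active only during training batches.
    """
    cfg = cfg or ModelConfig()
    X_train = np.asarray(X_train, dtype=np.float32)
    y_train = np.asarray(y_train)
    if set(np.unique(y_train)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    seeds = cfg.derived_seeds()
    if net is None:
        net = build_model(cfg, X_train.shape[1], init_seed=seeds["init"])
    shuffle_rng = np.random.default_rng(seeds["shuffle"])
    dropout_rng = np.random.default_rng(seeds["dropout"])
    opt = Adam(net.params, lr=cfg.learning_rate)

    rows = []
    n = len(X_train)
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            cache = net.forward(X_train[idx], train=True, dropout_rng=dropout_rng)
            grads = net.backward(cache, y_train[idx])
            opt.step(grads)
            epoch_loss += bce_loss(cache["prob"], y_train[idx]) * len(idx)
            correct += int(((cache["prob"] > cfg.threshold) == (y_train[idx] == 1)).sum())
        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "train_accuracy": correct / n,
        }
        if X_val is not None and len(X_val):
            pv = net.predict_proba(np.asarray(X_val, dtype=np.float32))
            row["val_loss"] = bce_loss(pv, y_val)
            row["val_accuracy"] = float(((pv > cfg.threshold) == (np.asarray(y_val) == 1)).mean())
        rows.append(row)
    history = pd.DataFrame(rows)
    return TrainedModel(net=net, config=cfg, history=history,
                        n_windows=X_train.shape[1])


def predict(tm: TrainedModel, X: np.ndarray,
            return_labels: bool = False) -> np.ndarray:
    """Sigmoid probabilities; hard labels use the strict ``p > threshold`` rule."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != tm.n_windows:
        raise ValueError(f"expected shape (B, {tm.n_windows}), got {X.shape}")
    prob = tm.net.predict_proba(X)
    if return_labels:
        return (prob > tm.config.threshold).astype(int)
    return prob


def attention_weights(tm: TrainedModel, X_ref: np.ndarray) -> np.ndarray:
    """Per-window attention attribution, a 1 x N non-negative array summing to 1.

    Attention scores over pooled positions are averaged across the reference
    samples, then each position's weight is spread uniformly over the input
    windows in its receptive field; the result is renormalized.
    """
    X_ref = np.asarray(X_ref, dtype=np.float32)
    if X_ref.ndim != 2 or len(X_ref) == 0:
        raise ValueError("reference set must be a non-empty 2D matrix")
    if X_ref.shape[1] != tm.n_windows:
        raise ValueError(f"expected {tm.n_windows} columns, got {X_ref.shape[1]}")
    att = tm.net.attention_scores(X_ref)          # (B, Lp)
    pos_weights = att.mean(axis=0)
    jump, size = tm.net.spec.receptive_field()
    n = tm.n_windows
    out = np.zeros(n)
    for j, w in enumerate(pos_weights):
        lo = j * jump
        hi = min(lo + size, n)
        out[lo:hi] += w / (hi - lo)
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate attention weights")
    return out / total


def grid_search(
    space: dict[str, list],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    base_cfg: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustively evaluate a hyperparameter grid by validation AUC.

    Ties are broken by smaller parameter count.  Returns the winning config
    and the full score table.
    """
    from .evaluate import roc_auc

    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty grid")
    base_cfg = base_cfg or ModelConfig()
    names = sorted(space)
    rows = []
    best = None
    for combo in itertools.product(*(space[k] for k in names)):
        overrides = dict(zip(names, combo))
        cfg = replace(base_cfg, **overrides)
        try:
            tm = train(X_train, y_train, X_val, y_val, cfg=cfg)
        except ValueError as exc:
            rows.append({**overrides, "val_auc": np.nan, "n_parameters": np.nan,
                         "error": str(exc)})
            continue
        auc = roc_auc(y_val, predict(tm, X_val)).auc
        n_params = tm.net.n_parameters
        rows.append({**overrides, "val_auc": auc, "n_parameters": n_params,
                     "error": ""})
        key = (-auc, n_params)
        if best is None or key < best[0]:
            best = (key, cfg)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every grid point failed to build/train")
    return best[1], table
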