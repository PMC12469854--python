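"""Attention-based synergy-score regressor.

The fused row [x_A | x_B | x_cell] is split into its three semantic blocks,
each linearly embedded (plus a learned token-type offset) into a 3-token
sequence; two post-norm multi-head self-attention blocks (8 heads, inner
feed-forward width 4*d_model, dropout 0.3) process the sequence; tokens are
mean-pooled and a 256 -> 128 -> 1 ReLU head emits the scalar score. Training
uses Adam on MSE with drug-order swap augmentation and patience-based early
stopping on a held-out validation split; prediction averages both drug
orders so scores are exactly order-symmetric.

Implemented in NumPy with hand-written backprop (see ``_nn``): single
threaded, bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .feature_fusion import (
    CellLineProfile,
    DrugRecord,
    FeatureSpace,
    Standardizer,
    fuse,
)
from .geneset_assembly import GeneUniverse

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "SynergyModel",
    "EarlyStopper",
    "build_model",
    "train",
    "predict_pair",
]


@dataclass
class ModelConfig:
    d_model: int = 128
    n_heads: int = 8
    n_blocks: int = 2
    head_hidden: tuple[int, int] = (256, 128)
    dropout: float = 0.3
    learning_rate: float = 0.003
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model <= 0 or self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be positive and divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class TrainingHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


class EarlyStopper:
    """Patience-based early stopping on validation loss (strict improvement)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch (1-indexed); returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since = 0
        else:
            self.since += 1
        return self.since >= self.patience


class SynergyModel:
    """The regressor: parameters, forward, backward, (de)serialization."""

    def __init__(self, config: ModelConfig, universe_size: int):
        if universe_size <= 0:
            raise ValueError("universe_size must be positive")
        self.config = config
        self.universe_size = universe_size
        self.standardizer: Standardizer | None = None
        self.universe_hash: str | None = None
        rng = np.random.default_rng([config.seed, 0])
        self.params = self._init_params(rng)

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c, U, d = self.config, self.universe_size, self.config.d_model
        p: dict[str, np.ndarray] = {}
        for t in range(3):
            p[f"embed.{t}.W"] = _nn.glorot(rng, U, d)
            p[f"embed.{t}.b"] = np.zeros(d)
            p[f"embed.{t}.tau"] = rng.normal(0.0, 0.02, size=d)
        for i in range(c.n_blocks):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"blk{i}.att.{w}"] = _nn.glorot(rng, d, d)
            for b in ("bq", "bk", "bv", "bo"):
                p[f"blk{i}.att.{b}"] = np.zeros(d)
            p[f"blk{i}.ffn.W1"] = _nn.glorot(rng, d, 4 * d)
            p[f"blk{i}.ffn.b1"] = np.zeros(4 * d)
            p[f"blk{i}.ffn.W2"] = _nn.glorot(rng, 4 * d, d)
            p[f"blk{i}.ffn.b2"] = np.zeros(d)
            for ln in ("ln1", "ln2"):
                p[f"blk{i}.{ln}.gamma"] = np.ones(d)
                p[f"blk{i}.{ln}.beta"] = np.zeros(d)
        h1, h2 = c.head_hidden
        p["head.W1"] = _nn.glorot(rng, d, h1)
        p["head.b1"] = np.zeros(h1)
        p["head.W2"] = _nn.glorot(rng, h1, h2)
        p["head.b2"] = np.zeros(h2)
        p["head.W3"] = _nn.glorot(rng, h2, 1)
        p["head.b3"] = np.zeros(1)
        return p

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list]:
        c, U, p = self.config, self.universe_size, self.params
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 3 * U:
            raise ValueError(f"expected rows of width {3 * U}, got {X.shape[1]}")
        rate = c.dropout
        cache: list = []

        tokens, emb_caches = [], []
        for t in range(3):
            xt = X[:, t * U : (t + 1) * U]
            ht, ce = _nn.linear_fwd(xt, p[f"embed.{t}.W"], p[f"embed.{t}.b"])
            tokens.append(ht + p[f"embed.{t}.tau"])
            emb_caches.append(ce)
        h = np.stack(tokens, axis=1)  # (B, 3, d)
        cache.append(emb_caches)

        for i in range(c.n_blocks):
            a, catt = _nn.attention_fwd(h, p, f"blk{i}.att", c.n_heads)
            a, keep1 = _nn.dropout_fwd(a, rate, train, rng)
            h1, cln1 = _nn.layernorm_fwd(
                h + a, p[f"blk{i}.ln1.gamma"], p[f"blk{i}.ln1.beta"]
            )
            f, cf1 = _nn.linear_fwd(h1, p[f"blk{i}.ffn.W1"], p[f"blk{i}.ffn.b1"])
            r, mrelu = _nn.relu_fwd(f)
            f2, cf2 = _nn.linear_fwd(r, p[f"blk{i}.ffn.W2"], p[f"blk{i}.ffn.b2"])
            f2, keep2 = _nn.dropout_fwd(f2, rate, train, rng)
            h, cln2 = _nn.layernorm_fwd(
                h1 + f2, p[f"blk{i}.ln2.gamma"], p[f"blk{i}.ln2.beta"]
            )
            cache.append((catt, keep1, cln1, cf1, mrelu, cf2, keep2, cln2))

        pool = h.mean(axis=1)  # (B, d)
        z1, ch1 = _nn.linear_fwd(pool, p["head.W1"], p["head.b1"])
        r1, m1 = _nn.relu_fwd(z1)
        r1, k1 = _nn.dropout_fwd(r1, rate, train, rng)
        z2, ch2 = _nn.linear_fwd(r1, p["head.W2"], p["head.b2"])
        r2, m2 = _nn.relu_fwd(z2)
        r2, k2 = _nn.dropout_fwd(r2, rate, train, rng)
        y, ch3 = _nn.linear_fwd(r2, p["head.W3"], p["head.b3"])
        cache.append((ch1, m1, k1, ch2, m2, k2, ch3, h.shape[1]))
        return y[:, 0], cache

    def backward(self, dy: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        c, p = self.config, self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        ch1, m1, k1, ch2, m2, k2, ch3, n_tokens = cache[-1]
        d, dW, db = _nn.linear_bwd(dy[:, None], ch3)
        grads["head.W3"] += dW
        grads["head.b3"] += db
        d = _nn.relu_bwd(_nn.dropout_bwd(d, k2), m2)
        d, dW, db = _nn.linear_bwd(d, ch2)
        grads["head.W2"] += dW
        grads["head.b2"] += db
        d = _nn.relu_bwd(_nn.dropout_bwd(d, k1), m1)
        dpool, dW, db = _nn.linear_bwd(d, ch1)
        grads["head.W1"] += dW
        grads["head.b1"] += db
        dh = np.repeat(dpool[:, None, :], n_tokens, axis=1) / n_tokens

        for i in reversed(range(c.n_blocks)):
            catt, keep1, cln1, cf1, mrelu, cf2, keep2, cln2 = cache[1 + i]
            dsum, dg, dbta = _nn.layernorm_bwd(dh, cln2)
            grads[f"blk{i}.ln2.gamma"] += dg
            grads[f"blk{i}.ln2.beta"] += dbta
            df2 = _nn.dropout_bwd(dsum, keep2)
            dr, dW, db = _nn.linear_bwd(df2, cf2)
            grads[f"blk{i}.ffn.W2"] += dW
            grads[f"blk{i}.ffn.b2"] += db
            df = _nn.relu_bwd(dr, mrelu)
            dh1_ffn, dW, db = _nn.linear_bwd(df, cf1)
            grads[f"blk{i}.ffn.W1"] += dW
            grads[f"blk{i}.ffn.b1"] += db
            dh1 = dsum + dh1_ffn
            dsum1, dg, dbta = _nn.layernorm_bwd(dh1, cln1)
            grads[f"blk{i}.ln1.gamma"] += dg
            grads[f"blk{i}.ln1.beta"] += dbta
            da = _nn.dropout_bwd(dsum1, keep1)
            dh = dsum1 + _nn.attention_bwd(da, catt, grads, f"blk{i}.att")

        emb_caches = cache[0]
        for t in range(3):
            _, dW, db = _nn.linear_bwd(dh[:, t, :], emb_caches[t])
            grads[f"embed.{t}.W"] += dW
            grads[f"embed.{t}.b"] += db
            grads[f"embed.{t}.tau"] += dh[:, t, :].sum(axis=0)
        return grads

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-disabled) forward pass on standardized rows."""
        y, _ = self.forward(X, train=False)
        return y

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "config": {**asdict(self.config), "head_hidden": list(self.config.head_hidden)},
            "universe_size": self.universe_size,
            "universe_hash": self.universe_hash,
            "standardizer": (
                json.loads(self.standardizer.to_json()) if self.standardizer else None
            ),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SynergyModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = meta["config"]
            cfg["head_hidden"] = tuple(cfg["head_hidden"])
            model = cls(ModelConfig(**cfg), meta["universe_size"])
            model.params = {k: z[k].copy() for k in z.files if k != "__meta__"}
        model.universe_hash = meta["universe_hash"]
        if meta["standardizer"] is not None:
            model.standardizer = Standardizer.from_json(json.dumps(meta["standardizer"]))
        return model


def universe_hash(universe: GeneUniverse) -> str:
    return hashlib.sha256("\n".join(universe.genes).encode()).hexdigest()


def build_model(config: ModelConfig, universe_size: int) -> SynergyModel:
    return SynergyModel(config, universe_size)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(
    model: SynergyModel,
    combos: Sequence,
    features: FeatureSpace,
    config: ModelConfig | None = None,
) -> tuple[SynergyModel, TrainingHistory]:
    """Fit the model on labelled combination records.

    Splits combos into train/validation (seeded, at the combination level),
    augments every training row with its drug-swapped copy, fits the
    Standardizer on the augmented training matrix only, and runs Adam/MSE
    with early stopping; best-epoch weights are restored. Validation loss is
    computed with the same order-symmetrized prediction used at inference.
    """
    config = config or model.config
    labels = np.array([c.score for c in combos], dtype=float)
    if len(combos) < 2:
        raise ValueError("need at least 2 labelled combos")
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")

    rng = np.random.default_rng([config.seed, 1])
    n = len(combos)
    n_val = int(n * config.val_fraction)
    if n_val < 1 or n - n_val < 1:
        raise ValueError(
            "validation split is empty; provide a larger dataset or val_fraction"
        )
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    def rows(idx, swapped: bool) -> np.ndarray:
        out = np.empty((len(idx), 3 * len(features.universe)))
        for j, i in enumerate(idx):
            c = combos[i]
            a, b = (c.drugB, c.drugA) if swapped else (c.drugA, c.drugB)
            out[j] = features.row(a, b, c.cell_line)
        return out

    X_tr = np.vstack([rows(tr_idx, False), rows(tr_idx, True)])
    y_tr = np.concatenate([labels[tr_idx], labels[tr_idx]])
    std = Standardizer().fit(X_tr)
    model.standardizer = std
    model.universe_hash = universe_hash(features.universe)
    X_tr = std.transform(X_tr)
    X_val_f = std.transform(rows(val_idx, False))
    X_val_r = std.transform(rows(val_idx, True))
    y_val = labels[val_idx]

    opt = _nn.Adam(model.params, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    history = TrainingHistory()
    best_params = {k: v.copy() for k, v in model.params.items()}

    m = X_tr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(m)
        sse = 0.0
        for start in range(0, m, config.batch_size):
            batch = order[start : start + config.batch_size]
            yb = y_tr[batch]
            pred, cache = model.forward(X_tr[batch], train=True, rng=rng)
            err = pred - yb
            sse += float(np.sum(err**2))
            grads = model.backward(2.0 * err / len(batch), cache)
            opt.step(model.params, grads)
        train_mse = sse / m
        val_pred = 0.5 * (model.predict_rows(X_val_f) + model.predict_rows(X_val_r))
        val_mse = _mse(val_pred, y_val)
        history.train_mse.append(train_mse)
        history.val_mse.append(val_mse)
        if stopper.best_epoch == 0 or val_mse < stopper.best:
            best_params = {k: v.copy() for k, v in model.params.items()}
        if stopper.update(epoch, val_mse):
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs

    history.best_epoch = stopper.best_epoch
    model.params = best_params
    return model, history


def predict_pair(
    model: SynergyModel,
    drugA: DrugRecord,
    drugB: DrugRecord,
    cell: CellLineProfile,
    universe: GeneUniverse,
    standardizer: Standardizer | None = None,
) -> float:
    """Order-symmetric score: mean of the model on both drug orderings."""
    std = standardizer or model.standardizer
    if std is None or not std.fitted:
        raise RuntimeError("model has no fitted standardizer; train first")
    X = np.vstack(
        [fuse(drugA, drugB, cell, universe), fuse(drugB, drugA, cell, universe)]
    )
    return float(model.predict_rows(std.transform(X)).mean())
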