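"""Training: base-resolution MSE objective with L2 penalty, Adam with
per-epoch exponential learning-rate decay, and random hyperparameter search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import ModelConfig, SignalModel
from .seqdata import DatasetSplit

__all__ = [
    "LossSpec",
    "TrainConfig",
    "TrainingHistory",
    "mse_loss",
    "learning_rate_at",
    "train_model",
    "hyperparameter_search",
    "stack_samples",
    "LEARNING_RATE_GRID",
    "BETA1_GRID",
    "ALPHA_GRID",
    "DROPOUT_GRID",
]

LEARNING_RATE_GRID = (0.01, 0.001, 0.0001)
BETA1_GRID = (0.9, 0.99, 0.999)
ALPHA_GRID = (0.0, 0.001)
DROPOUT_GRID = (0.2, 0.5)


@dataclass
class LossSpec:
    alpha: float = 0.0
    N: int = 1
    L: int = 1


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    alpha: float = 0.0
    dropout: float = 0.2
    batch_size: int = 500
    lr_decay: float = 0.9
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def mse_loss(pred, target, weights_norm_sq: float = 0.0, alpha: float = 0.0) -> float:
    """(1/(N*L)) * sum((pred - target)^2) + alpha * ||w||^2."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2) + alpha * weights_norm_sq)


def learning_rate_at(lr0: float, epoch: int, decay: float = 0.9) -> float:
    return lr0 * decay**epoch


class AdamOptimizer:
    def __init__(self, params: dict, lr, beta1, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def stack_samples(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Samples -> (X (N,4,L), Y (N,L), labels (N,)) channels-first float32."""
    X = np.stack([s.x.matrix.T for s in samples]).astype(np.float32)
    Y = np.stack([s.y.values for s in samples]).astype(np.float32)
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return X, Y, labels


@dataclass
class TrainingHistory:
    epochs: list = None
    initial_val_loss: float = float("nan")  # untrained-model validation loss

    def __post_init__(self):
        self.epochs = self.epochs or []

    def record(self, epoch, train_loss, val_loss, lr):
        self.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr}
        )

    def best_val_loss(self) -> float:
        return min(e["val_loss"] for e in self.epochs)

    def to_tsv(self) -> str:
        lines = ["epoch\ttrain_loss\tval_loss\tlr"]
        for e in self.epochs:
            lines.append(
                f"{e['epoch']}\t{e['train_loss']:.6g}\t{e['val_loss']:.6g}\t{e['lr']:.6g}"
            )
        return "\n".join(lines) + "\n"


def _batched_prediction(model, X, batch=200):
    outs = [model.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def validation_loss(model, X_val, Y_val) -> float:
    return mse_loss(_batched_prediction(model, X_val), Y_val)


def train_model(
    split: DatasetSplit,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> tuple[SignalModel, TrainingHistory]:
    """Fit the network on a prepared split; returns the best-validation model.

    Both positive and negative samples contribute to the regression loss
    with their true (low) signals.  Determinism is controlled entirely by
    ``config.seed``: model initialization, dropout masks and shuffling all
    derive from it.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    if model_config is None:
        model_config = ModelConfig()
    model_config = replace(model_config, dropout_rate=config.dropout)
    model = SignalModel(model_config, seed=config.seed)

    X, Y, _ = stack_samples(split.train)
    X_val, Y_val, _ = stack_samples(split.validation)
    n, L = X.shape[0], X.shape[2]
    batch_size = min(config.batch_size, n)
    rng = np.random.default_rng(config.seed + 1000)

    optimizer = AdamOptimizer(
        model.params(),
        config.learning_rate,
        config.adam_beta1,
        config.adam_beta2,
        config.adam_eps,
    )
    history = TrainingHistory()
    history.initial_val_loss = validation_loss(model, X_val, Y_val)
    best = {"val": np.inf, "params": None, "bn": None, "epoch": -1}
    stale = 0

    for epoch in range(config.max_epochs):
        optimizer.lr = learning_rate_at(config.learning_rate, epoch, config.lr_decay)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = X[idx], Y[idx]
            model.zero_grad()
            pred = model.forward(xb, training=True)
            loss = mse_loss(pred, yb, model.weights_norm_sq(), config.alpha)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // batch_size}; "
                    "reduce the learning rate"
                )
            dout = (2.0 / pred.size) * (pred - yb)
            model.backward(dout)
            grads = model.grads()
            if config.alpha > 0:
                params = model.params()
                for name in model.weight_names():
                    grads[name] += (2.0 * config.alpha) * params[name]
            optimizer.step(model.params(), grads)
            epoch_loss += loss
            n_batches += 1

        val = validation_loss(model, X_val, Y_val)
        history.record(epoch, epoch_loss / n_batches, val, optimizer.lr)
        if val < best["val"]:
            best.update(
                val=val,
                params={k: v.copy() for k, v in model.params().items()},
                bn=[
                    (s.bn.running_mean.copy(), s.bn.running_var.copy())
                    for s in model.dec
                ],
                epoch=epoch,
            )
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best["params"] is not None:
        params = model.params()
        for k in params:
            params[k][...] = best["params"][k]
        for stage, (rm, rv) in zip(model.dec, best["bn"]):
            stage.bn.running_mean[...] = rm
            stage.bn.running_var[...] = rv
    return model, history


def hyperparameter_search(
    split: DatasetSplit,
    n_draws: int = 15,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    base_config: TrainConfig | None = None,
) -> tuple[TrainConfig, list[dict]]:
    """Sample configs uniformly (with replacement) from the stated grids.

    Every draw is trained; the config minimizing validation loss wins,
    ties broken by earliest draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or TrainConfig(seed=seed)
    report = []
    best_cfg, best_val = None, np.inf
    for draw in range(n_draws):
        cfg = replace(
            base,
            learning_rate=float(rng.choice(LEARNING_RATE_GRID)),
            adam_beta1=float(rng.choice(BETA1_GRID)),
            alpha=float(rng.choice(ALPHA_GRID)),
            dropout=float(rng.choice(DROPOUT_GRID)),
        )
        _, history = train_model(split, cfg, model_config)
        val = history.best_val_loss()
        report.append(
            {
                "draw": draw,
                "learning_rate": cfg.learning_rate,
                "adam_beta1": cfg.adam_beta1,
                "alpha": cfg.alpha,
                "dropout": cfg.dropout,
                "val_loss": val,
            }
        )
        if val < best_val:  # strict: ties keep the earliest draw
            best_cfg, best_val = cfg, val
    return best_cfg, report
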