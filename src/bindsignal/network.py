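"""Symmetric encoder/decoder network for base-resolution signal regression.

The encoder stacks three conv/ReLU/maxpool/dropout blocks, a
bidirectional GRU at the bottleneck, and a global average pooling whose
context vector is broadcast-added back onto the bottleneck feature map.
The decoder restores the input length with four bilinear-upsample +
blending (BN -> ReLU -> conv) stages; the first three receive additive
skip connections from the encoder blocks at the same resolution.  The
output head is linear, one value per input base.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .nnops import (
    BiGRU,
    BatchNorm1d,
    BilinearUpsample1d,
    Conv1d,
    Dropout,
    MaxPool1d,
    ReLU,
    global_average_context,
)

__all__ = [
    "ModelConfig",
    "EncoderBlock",
    "DecoderStage",
    "SignalModel",
    "encoder_block",
    "decoder_stage",
    "model_forward",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``blend_channels`` are the output channel counts of the four decoder
    blending convolutions; the first two must mirror encoder channels so
    the additive skips line up, and the last must be 1 (the signal head).
    """

    conv_channels: tuple[int, int, int] = (64, 96, 128)
    kernel_sizes: tuple[int, int, int] = (15, 5, 3)
    pool_sizes: tuple[int, int, int] = (5, 5, 5)
    dropout_rate: float = 0.2
    gru_hidden: int = 128
    blend_channels: tuple[int, int, int, int] = (96, 64, 64, 1)
    blend_kernel: int = 3
    dtype: str = "float32"

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.kernel_sizes) or self.blend_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.blend_channels[-1] != 1:
            raise ValueError("final blending stage must output 1 channel")
        if self.gru_hidden != self.conv_channels[2]:
            raise ValueError(
                "gru_hidden must equal the last encoder channel count "
                "(additive skip at the bottleneck)"
            )
        if self.blend_channels[0] != self.conv_channels[1]:
            raise ValueError("blend_channels[0] must equal conv_channels[1]")
        if self.blend_channels[1] != self.conv_channels[0]:
            raise ValueError("blend_channels[1] must equal conv_channels[0]")

    @property
    def input_len_multiple(self) -> int:
        return int(np.prod(self.pool_sizes))


class EncoderBlock:
    """conv -> ReLU -> maxpool -> dropout  (one encoder level)."""

    def __init__(self, in_ch, out_ch, kernel, pool, dropout, rng, drop_rng, dtype):
        self.conv = Conv1d(in_ch, out_ch, kernel, rng, dtype)
        self.relu = ReLU()
        self.pool = MaxPool1d(pool)
        self.drop = Dropout(dropout, drop_rng)
        self._layers = [self.conv, self.relu, self.pool, self.drop]

    def forward(self, x, training=False):
        for layer in self._layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self._layers):
            dout = layer.backward(dout)
        return dout


class DecoderStage:
    """bilinear upsample -> (+ skip) -> BN -> ReLU -> conv blending."""

    def __init__(self, scale, in_ch, out_ch, kernel, rng, dtype):
        self.up = BilinearUpsample1d(scale)
        self.bn = BatchNorm1d(in_ch, dtype=dtype)
        self.relu = ReLU()
        self.conv = Conv1d(in_ch, out_ch, kernel, rng, dtype)
        self.has_skip = False  # set by the model

    def forward(self, y, skip=None, training=False):
        z = self.up.forward(y, training)
        if skip is not None:
            if skip.shape != z.shape:
                raise ValueError(
                    f"skip shape {skip.shape} does not match upsampled {z.shape}"
                )
            z = z + skip
        z = self.bn.forward(z, training)
        z = self.relu.forward(z, training)
        return self.conv.forward(z, training)

    def backward(self, dout):
        dz = self.conv.backward(dout)
        dz = self.relu.backward(dz)
        dz = self.bn.backward(dz)
        dskip = dz if self.has_skip else None
        return self.up.backward(dz), dskip


class SignalModel:
    """The full network; ``forward`` maps (N, 4, L) to (N, L)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.np_dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        cc, ks, ps = config.conv_channels, config.kernel_sizes, config.pool_sizes
        self.enc = [
            EncoderBlock(
                4 if i == 0 else cc[i - 1],
                cc[i],
                ks[i],
                ps[i],
                config.dropout_rate,
                rng,
                self.dropout_rng,
                self.np_dtype,
            )
            for i in range(3)
        ]
        self.gru = BiGRU(cc[2], config.gru_hidden, rng, self.np_dtype)
        bc = config.blend_channels
        in_ch = (config.gru_hidden, bc[0], bc[1], bc[2])
        scales = (1, ps[2], ps[1], ps[0])
        self.dec = [
            DecoderStage(scales[i], in_ch[i], bc[i], config.blend_kernel, rng, self.np_dtype)
            for i in range(4)
        ]
        for stage in self.dec[:3]:
            stage.has_skip = True
        # zero-initialized output head: the first prediction is flat, which
        # keeps early optimization from chasing the decoder's random state
        # and markedly speeds up convergence at desk scale
        self.dec[3].conv.params["W"][...] = 0.0

    # -- parameter plumbing --------------------------------------------------

    def _layer_items(self):
        for i, block in enumerate(self.enc):
            yield f"enc{i}.conv", block.conv
        yield "gru", self.gru
        for i, stage in enumerate(self.dec):
            yield f"dec{i}.bn", stage.bn
            yield f"dec{i}.conv", stage.conv

    def params(self) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.{k}": arr
            for prefix, layer in self._layer_items()
            for k, arr in layer.params.items()
        }

    def grads(self) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.{k}": arr
            for prefix, layer in self._layer_items()
            for k, arr in layer.grads.items()
        }

    def zero_grad(self):
        for _, layer in self._layer_items():
            layer.zero_grad()

    def weight_names(self) -> list[str]:
        """Parameters subject to the L2 penalty (weight matrices only)."""
        return [
            name
            for name in self.params()
            if not name.endswith((".b", ".beta", ".gamma"))
        ]

    def weights_norm_sq(self) -> float:
        p = self.params()
        return float(sum(np.sum(p[n].astype(np.float64) ** 2) for n in self.weight_names()))

    def param_digest(self) -> str:
        """SHA-256 over all parameters and BN running statistics."""
        h = hashlib.sha256()
        for name, arr in sorted(self.params().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        for i, stage in enumerate(self.dec):
            h.update(np.ascontiguousarray(stage.bn.running_mean).tobytes())
            h.update(np.ascontiguousarray(stage.bn.running_var).tobytes())
        return h.hexdigest()

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.np_dtype)
        if x.ndim == 2:
            x = x[None]
        N, C, L = x.shape
        multiple = self.config.input_len_multiple
        if L % multiple != 0:
            raise ValueError(
                f"input length {L} not divisible by {multiple}; pad the sequence"
            )
        e1 = self.enc[0].forward(x, training)
        e2 = self.enc[1].forward(e1, training)
        e3 = self.enc[2].forward(e2, training)
        h = self.gru.forward(e3, training)
        ctx = global_average_context(h)
        b = h + ctx[:, :, None]
        self._T = h.shape[2]
        d0 = self.dec[0].forward(b, skip=e3, training=training)
        d1 = self.dec[1].forward(d0, skip=e2, training=training)
        d2 = self.dec[2].forward(d1, skip=e1, training=training)
        d3 = self.dec[3].forward(d2, skip=None, training=training)
        return d3[:, 0, :]

    def backward(self, dout: np.ndarray):
        """Backprop from d(loss)/d(output); call right after ``forward``."""
        dd3 = dout[:, None, :].astype(self.np_dtype)
        dd2, _ = self.dec[3].backward(dd3)
        dd1, de1 = self.dec[2].backward(dd2)
        dd0, de2 = self.dec[1].backward(dd1)
        db, de3 = self.dec[0].backward(dd0)
        # b = h + mean_T(h) broadcast: dh = db + (1/T) * sum_T(db)
        dh = db + db.mean(axis=2, keepdims=True)
        de3 = de3 + self.gru.backward(dh)
        de2 = de2 + self.enc[2].backward(de3)
        de1 = de1 + self.enc[1].backward(de2)
        return self.enc[0].backward(de1)


# -- functional views used by the operation-level contracts -----------------


def encoder_block(x, params, pool, dropout=0.0, training=False, rng=None):
    """Dropout(MaxPool(ReLU(conv(x) + b))) on a (C, L) or (N, C, L) map."""
    x = np.asarray(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    W, b = np.asarray(params["W"]), np.asarray(params["b"])
    conv = Conv1d(W.shape[1], W.shape[0], W.shape[2], dtype=W.dtype.type)
    conv.params["W"], conv.params["b"] = W, b
    block_rng = rng if rng is not None else np.random.default_rng(0)
    out = Dropout(dropout, block_rng).forward(
        MaxPool1d(pool).forward(ReLU().forward(conv.forward(x))), training
    )
    return out[0] if squeeze else out


def decoder_stage(y, skip, scale, bn, conv_params, training=False):
    """Functional Eq-style decoder stage used in tests; see DecoderStage."""
    y = np.asarray(y)
    squeeze = y.ndim == 2
    if squeeze:
        y = y[None]
        skip = None if skip is None else np.asarray(skip)[None]
    W, b = np.asarray(conv_params["W"]), np.asarray(conv_params["b"])
    stage = DecoderStage(scale, W.shape[1], W.shape[0], W.shape[2], None, W.dtype.type)
    stage.conv.params["W"], stage.conv.params["b"] = W, b
    if bn is not None:
        stage.bn = bn
    out = stage.forward(y, skip=skip, training=training)
    return out[0] if squeeze else out


def model_forward(x, model: SignalModel, training: bool = False) -> np.ndarray:
    out = model.forward(x, training)
    return out[0] if np.asarray(x).ndim == 2 else out


# -- serialization ----------------------------------------------------------


def save_checkpoint(model: SignalModel, path, metadata: dict | None = None):
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "metadata": metadata or {},
    }
    arrays = {f"param/{k}": v for k, v in model.params().items()}
    for i, stage in enumerate(model.dec):
        arrays[f"bn{i}/running_mean"] = stage.bn.running_mean
        arrays[f"bn{i}/running_var"] = stage.bn.running_var
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[SignalModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {meta.get('schema')}")
        cfg_dict = meta["config"]
        for key in ("conv_channels", "kernel_sizes", "pool_sizes", "blend_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = SignalModel(ModelConfig(**cfg_dict))
        params = model.params()
        for k in params:
            params[k][...] = data[f"param/{k}"]
        for i, stage in enumerate(model.dec):
            stage.bn.running_mean[...] = data[f"bn{i}/running_mean"]
            stage.bn.running_var[...] = data[f"bn{i}/running_var"]
    return model, meta["metadata"]
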