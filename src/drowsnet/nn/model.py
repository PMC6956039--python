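"""Hybrid spatio-temporal convolutional / bidirectional-LSTM classifier.

The architecture is a stack of five valid-convolution blocks (temporal 1x5
filters, then spatial 5x1 and 3x1 filters with channel-axis pooling), whose
output sequence feeds four bidirectional LSTM layers (256, 256, 128, 128
hidden units; the last one many-to-one) and a three-layer fully connected
head ending in a softmax.  With a 30-channel, 100-sample input the tensor
chain is:

    30x100 -> 30x32x92 -> 30x64x84 -> 30x128x76 -> 18x128x76 -> 9x128x76
    -> 3x256x76 -> 1x256x76 -> 512x76 -> 512x76 -> 256x76 -> 256x1
    -> 128x1 -> 64x1 -> n_classes

(valid convolutions only; no padding anywhere).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import AvgPoolChan, BatchNorm2d, Conv2dValid, Dense, Dropout, ELU, Layer, MaxPoolChan, Param
from .losses import softmax, softmax_cross_entropy
from .lstm import BiLSTMLayer


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: repeated valid convolutions, optional
    channel-axis pooling, batch-norm, activation, dropout."""

    n_layers: int
    filter: tuple[int, int]  # (channel extent, time extent)
    feature_maps: int
    pool: tuple[str, int] | None = None  # ("max"|"avg", size)
    batchnorm: bool = True
    activation: str | None = "elu"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        kc, kt = self.filter
        if kc < 1 or kt < 1 or self.n_layers < 1 or self.feature_maps < 1:
            raise ValueError("filter extents, layer count, and maps must be >= 1")
        if self.pool is not None and self.pool[0] not in ("max", "avg"):
            raise ValueError(f"unknown pool kind {self.pool[0]!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Complete layer specification of the classifier."""

    conv_blocks: tuple[ConvBlockSpec, ...]
    bilstm: tuple[tuple[int, str], ...]  # (hidden units, "seq2seq"|"final")
    head: tuple[int, ...]  # hidden widths of the fully connected layers
    n_classes: int
    input_shape: tuple[int, int] = (30, 100)
    bilstm_dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.bilstm or self.bilstm[-1][1] != "final":
            raise ValueError("the last recurrent layer must use 'final' (many-to-one) mode")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["conv_blocks"] = tuple(
            ConvBlockSpec(
                n_layers=b["n_layers"], filter=tuple(b["filter"]),
                feature_maps=b["feature_maps"],
                pool=tuple(b["pool"]) if b["pool"] else None,
                batchnorm=b["batchnorm"], activation=b["activation"],
                dropout=b["dropout"],
            )
            for b in d["conv_blocks"]
        )
        d["bilstm"] = tuple((int(h), m) for h, m in d["bilstm"])
        d["head"] = tuple(d["head"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


def default_spec(n_classes: int = 5, elu_everywhere: bool = True) -> ModelSpec:
    """The full-size published parameterization.

    ``elu_everywhere=False`` restricts the ELU activation to block V only
    (the strictly literal reading); the default activates every block, since
    a purely linear convolutional stack would collapse to one linear map.
    """
    act = "elu" if elu_everywhere else None
    blocks = (
        ConvBlockSpec(2, (1, 5), 32, activation=act),
        ConvBlockSpec(2, (1, 5), 64, activation=act),
        ConvBlockSpec(2, (1, 5), 128, activation=act),
        ConvBlockSpec(3, (5, 1), 128, pool=("max", 2), activation=act),
        ConvBlockSpec(3, (3, 1), 256, pool=("avg", 3), activation="elu", dropout=0.5),
    )
    bilstm = ((256, "seq2seq"), (256, "seq2seq"), (128, "seq2seq"), (128, "final"))
    return ModelSpec(conv_blocks=blocks, bilstm=bilstm, head=(128, 64), n_classes=n_classes)


def small_spec(n_classes: int = 5) -> ModelSpec:
    """A reduced-width variant with the same geometry, for CPU-scale runs."""
    blocks = (
        ConvBlockSpec(1, (1, 5), 4),
        ConvBlockSpec(1, (1, 7), 8),
        ConvBlockSpec(3, (5, 1), 8, pool=("max", 2)),
        ConvBlockSpec(3, (3, 1), 16, pool=("avg", 3), dropout=0.25),
    )
    bilstm = ((8, "seq2seq"), (8, "final"))
    return ModelSpec(conv_blocks=blocks, bilstm=bilstm, head=(16,), n_classes=n_classes,
                     bilstm_dropout=0.25)


def infer_shapes(spec: ModelSpec, input_shape: tuple[int, int] | None = None) -> list[tuple[str, tuple[int, ...]]]:
    """Walk the layer chain and return every intermediate tensor shape.

    Convolutional shapes are (channel extent, feature maps, time extent);
    recurrent and head shapes are (width, steps).  Raises ``ValueError``
    naming the first layer whose output extent would be non-positive.
    """
    c, t = input_shape or spec.input_shape
    shapes: list[tuple[str, tuple[int, ...]]] = [("input", (c, t))]
    f = 1
    for b, block in enumerate(spec.conv_blocks, start=1):
        kc, kt = block.filter
        for layer in range(block.n_layers):
            c = c - kc + 1
            t = t - kt + 1
            if c < 1 or t < 1:
                raise ValueError(
                    f"block {b} convolution {layer + 1} exhausts the input "
                    f"(extent becomes {c} x {t})"
                )
        f = block.feature_maps
        shapes.append((f"block{b}_conv", (c, f, t)))
        if block.pool is not None:
            kind, size = block.pool
            if c % size != 0:
                raise ValueError(f"block {b} {kind}-pool size {size} does not divide extent {c}")
            c //= size
            shapes.append((f"block{b}_pool", (c, f, t)))
    d = c * f
    for i, (hidden, mode) in enumerate(spec.bilstm, start=1):
        if mode == "seq2seq":
            shapes.append((f"bilstm{i}", (2 * hidden, t)))
        else:
            shapes.append((f"bilstm{i}", (2 * hidden, 1)))
        d = 2 * hidden
    for i, width in enumerate(spec.head, start=1):
        shapes.append((f"fc{i}", (width, 1)))
    shapes.append((f"fc{len(spec.head) + 1}", (spec.n_classes, 1)))
    return shapes


class _ToSequence(Layer):
    """(N, F, C, T) -> (N, T, F*C) so the recurrent block sees time steps."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        n, f, c, t = x.shape
        return x.reshape(n, f * c, t).transpose(0, 2, 1)

    def backward(self, dy):
        n, f, c, t = self._shape
        return dy.transpose(0, 2, 1).reshape(n, f, c, t)


class _EluVec(ELU):
    """ELU applied to flat (N, D) activations in the head."""


class ConvBiLSTM:
    """The full classifier: conv feature extractor + bi-LSTM + dense head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        infer_shapes(spec)  # validates the geometry up front
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []

        fin = 1
        c, t = spec.input_shape
        for block in spec.conv_blocks:
            kc, kt = block.filter
            for _ in range(block.n_layers):
                self.layers.append(Conv2dValid(fin, block.feature_maps, kc, kt, rng))
                fin = block.feature_maps
                c, t = c - kc + 1, t - kt + 1
            if block.pool is not None:
                kind, size = block.pool
                self.layers.append(MaxPoolChan(size) if kind == "max" else AvgPoolChan(size))
                c //= size
            if block.batchnorm:
                self.layers.append(BatchNorm2d(block.feature_maps))
            if block.activation == "elu":
                self.layers.append(ELU())
            if block.dropout > 0:
                self.layers.append(Dropout(block.dropout))

        self.layers.append(_ToSequence())
        d = fin * c
        for hidden, mode in spec.bilstm:
            self.layers.append(BiLSTMLayer(d, hidden, mode=mode, rng=rng))
            d = 2 * hidden
        if spec.bilstm_dropout > 0:
            self.layers.append(Dropout(spec.bilstm_dropout))
        for width in spec.head:
            self.layers.append(Dense(d, width, rng))
            self.layers.append(_EluVec())
            d = width
        self.layers.append(Dense(d, spec.n_classes, rng))

    # -- parameter access ---------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state):
            p.value[...] = v
        extra = state[len(params):]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2

    # -- forward / backward -------------------------------------------------
    def _prepare(self, x: np.ndarray) -> np.ndarray:
        c, t = self.spec.input_shape
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[1:] != (1, c, t):
            raise ValueError(f"expected input ({c}, {t}) per sample, got {x.shape[1:]}")
        return x

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits of shape (N, n_classes)."""
        out = self._prepare(np.asarray(x, dtype=float))
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, training: bool = True,
                      rng: np.random.Generator | None = None) -> float:
        logits = self.forward(x, training=training, rng=rng)
        loss, dlogits = softmax_cross_entropy(logits, y)
        self.backward(dlogits)
        return loss

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            return softmax(self.forward(x))[0]
        outs = [softmax(self.forward(x[i : i + batch_size]))
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return np.argmax(self.predict_proba(x, batch_size=batch_size), axis=-1)

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (npz) with the spec JSON alongside."""
        path = Path(path)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ConvBiLSTM":
        path = Path(path)
        spec = ModelSpec.from_json(path.with_suffix(".json").read_text())
        model = cls(spec)
        with np.load(path.with_suffix(".npz")) as data:
            state = [data[f"arr_{i}"] for i in range(len(data.files))]
        model.set_state(state)
        return model
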