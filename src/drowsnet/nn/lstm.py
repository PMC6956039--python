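"""LSTM cell and bidirectional recurrent layers.

The memory cell follows the classic gate formulation: at step t, forget gate
f, input gate i, and output gate o are logistic functions of affine maps of
(h_{t-1}, x_t); the candidate state is a tanh of the same form; the cell
state is c_t = f*c_{t-1} + i*candidate, and h_t = o*tanh(c_t).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .layers import Layer, Param


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMCellParams:
    """Weights and biases of one LSTM cell.

    ``W_*h`` are (H, H) recurrent matrices, ``W_*x`` are (H, D) input
    matrices, biases have length H; the suffixes f/i/o/c name the forget,
    input, output, and candidate paths.
    """

    W_fh: np.ndarray
    W_fx: np.ndarray
    b_f: np.ndarray
    W_ih: np.ndarray
    W_ix: np.ndarray
    b_i: np.ndarray
    W_oh: np.ndarray
    W_ox: np.ndarray
    b_o: np.ndarray
    W_ch: np.ndarray
    W_cx: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_fx.shape
        for name in ("W_fh", "W_ih", "W_oh", "W_ch"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must be ({h}, {h})")
        for name in ("W_fx", "W_ix", "W_ox", "W_cx"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must be ({h}, {d})")
        for name in ("b_f", "b_i", "b_o", "b_c"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have length {h}")

    @property
    def hidden_size(self) -> int:
        return self.W_fh.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_fx.shape[1]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator) -> "LSTMCellParams":
        h, d = hidden_size, input_size
        bh = np.sqrt(1.0 / h)
        bd = np.sqrt(1.0 / d)
        def rec() -> np.ndarray:
            return rng.uniform(-bh, bh, size=(h, h))
        def inp() -> np.ndarray:
            return rng.uniform(-bd, bd, size=(h, d))
        return cls(
            W_fh=rec(), W_fx=inp(), b_f=np.zeros(h),
            W_ih=rec(), W_ix=inp(), b_i=np.zeros(h),
            W_oh=rec(), W_ox=inp(), b_o=np.zeros(h),
            W_ch=rec(), W_cx=inp(), b_c=np.zeros(h),
        )

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LSTMCellParams":
        h, d = hidden_size, input_size
        z = np.zeros
        return cls(
            W_fh=z((h, h)), W_fx=z((h, d)), b_f=z(h),
            W_ih=z((h, h)), W_ix=z((h, d)), b_i=z(h),
            W_oh=z((h, h)), W_ox=z((h, d)), b_o=z(h),
            W_ch=z((h, h)), W_cx=z((h, d)), b_c=z(h),
        )


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMCellParams
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update; accepts (D,)/(H,) vectors or (N, D)/(N, H) batches."""
    p = params
    if x_t.shape[-1] != p.input_size or h_prev.shape[-1] != p.hidden_size:
        raise ValueError(
            f"dimension mismatch: x_t {x_t.shape}, h_prev {h_prev.shape}, "
            f"expected D={p.input_size}, H={p.hidden_size}"
        )
    f = _sigmoid(h_prev @ p.W_fh.T + x_t @ p.W_fx.T + p.b_f)
    i = _sigmoid(h_prev @ p.W_ih.T + x_t @ p.W_ix.T + p.b_i)
    o = _sigmoid(h_prev @ p.W_oh.T + x_t @ p.W_ox.T + p.b_o)
    g = np.tanh(h_prev @ p.W_ch.T + x_t @ p.W_cx.T + p.b_c)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class LSTMDirection(Layer):
    """A single-direction LSTM over (N, T, D) returning all hidden states."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None,
                 cell: LSTMCellParams | None = None):
        if cell is None:
            if rng is None:
                raise ValueError("provide rng or cell parameters")
            cell = LSTMCellParams.init(input_size, hidden_size, rng)
        self.cell = cell
        self._params = [Param(f"lstm.{f.name}", getattr(cell, f.name)) for f in fields(cell)]
        self._cache = None

    def params(self):
        return self._params

    def forward(self, x, training=False, rng=None):
        p = self.cell
        n, t_steps, _ = x.shape
        h = np.zeros((n, p.hidden_size))
        c = np.zeros((n, p.hidden_size))
        hs = np.empty((n, t_steps, p.hidden_size))
        cache = []
        for t in range(t_steps):
            x_t = x[:, t, :]
            f = _sigmoid(h @ p.W_fh.T + x_t @ p.W_fx.T + p.b_f)
            i = _sigmoid(h @ p.W_ih.T + x_t @ p.W_ix.T + p.b_i)
            o = _sigmoid(h @ p.W_oh.T + x_t @ p.W_ox.T + p.b_o)
            g = np.tanh(h @ p.W_ch.T + x_t @ p.W_cx.T + p.b_c)
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x_t, h, c, f, i, o, g, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (cache, x.shape)
        return hs

    def backward(self, dhs):
        p = self.cell
        cache, x_shape = self._cache
        n, t_steps, _ = x_shape
        grads = {f.name: g for f, g in zip(fields(p), (pp.grad for pp in self._params))}
        dx = np.empty(x_shape)
        dh_rec = np.zeros((n, p.hidden_size))
        dc_rec = np.zeros((n, p.hidden_size))
        for t in reversed(range(t_steps)):
            x_t, h_prev, c_prev, f, i, o, g, tanh_c = cache[t]
            dh = dhs[:, t, :] + dh_rec
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_rec
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_rec = dc * f
            dz_f = df * f * (1.0 - f)
            dz_i = di * i * (1.0 - i)
            dz_o = do * o * (1.0 - o)
            dz_g = dg * (1.0 - g**2)
            grads["W_fh"] += dz_f.T @ h_prev
            grads["W_ih"] += dz_i.T @ h_prev
            grads["W_oh"] += dz_o.T @ h_prev
            grads["W_ch"] += dz_g.T @ h_prev
            grads["W_fx"] += dz_f.T @ x_t
            grads["W_ix"] += dz_i.T @ x_t
            grads["W_ox"] += dz_o.T @ x_t
            grads["W_cx"] += dz_g.T @ x_t
            grads["b_f"] += dz_f.sum(axis=0)
            grads["b_i"] += dz_i.sum(axis=0)
            grads["b_o"] += dz_o.sum(axis=0)
            grads["b_c"] += dz_g.sum(axis=0)
            dx[:, t, :] = dz_f @ p.W_fx + dz_i @ p.W_ix + dz_o @ p.W_ox + dz_g @ p.W_cx
            dh_rec = dz_f @ p.W_fh + dz_i @ p.W_ih + dz_o @ p.W_oh + dz_g @ p.W_ch
        return dx


class BiLSTMLayer(Layer):
    """Paired forward/backward LSTM passes over a sequence.

    ``seq2seq`` mode emits, at every step, the concatenation of the two
    directions' hidden states (N, T, 2H).  ``final`` mode emits only the
    concatenation of each direction's last hidden state (N, 2H).
    """

    def __init__(self, input_size: int, hidden_size: int, mode: str = "seq2seq",
                 rng: np.random.Generator | None = None,
                 fwd: LSTMDirection | None = None, bwd: LSTMDirection | None = None):
        if mode not in ("seq2seq", "final"):
            raise ValueError(f"mode must be 'seq2seq' or 'final', got {mode!r}")
        self.mode = mode
        self.hidden_size = hidden_size
        self.fwd = fwd or LSTMDirection(input_size, hidden_size, rng=rng)
        self.bwd = bwd or LSTMDirection(input_size, hidden_size, rng=rng)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False, rng=None):
        if x.ndim != 3 or x.shape[1] < 1:
            raise ValueError("input must be (N, T, D) with T >= 1")
        hf = self.fwd.forward(x, training, rng)
        hb = self.bwd.forward(x[:, ::-1, :], training, rng)
        if self.mode == "seq2seq":
            return np.concatenate([hf, hb[:, ::-1, :]], axis=2)
        return np.concatenate([hf[:, -1, :], hb[:, -1, :]], axis=1)

    def backward(self, dy):
        h = self.hidden_size
        if self.mode == "seq2seq":
            dhf = dy[:, :, :h]
            dhb = dy[:, ::-1, h:]
        else:
            n = dy.shape[0]
            t_steps = self.fwd._cache[1][1]
            dhf = np.zeros((n, t_steps, h))
            dhb = np.zeros((n, t_steps, h))
            dhf[:, -1, :] = dy[:, :h]
            dhb[:, -1, :] = dy[:, h:]
        dxf = self.fwd.backward(dhf)
        dxb = self.bwd.backward(dhb)
        return dxf + dxb[:, ::-1, :]


def bilstm_layer(sequence: np.ndarray, fwd_params: LSTMCellParams,
                 bwd_params: LSTMCellParams, mode: str = "seq2seq") -> np.ndarray:
    """Functional bidirectional pass over a single (T, D) sequence."""
    if sequence.ndim != 2 or sequence.shape[0] < 1:
        raise ValueError("sequence must be (T, D) with T >= 1")
    layer = BiLSTMLayer(
        fwd_params.input_size, fwd_params.hidden_size, mode=mode,
        fwd=LSTMDirection(fwd_params.input_size, fwd_params.hidden_size, cell=fwd_params),
        bwd=LSTMDirection(bwd_params.input_size, bwd_params.hidden_size, cell=bwd_params),
    )
    out = layer.forward(sequence[None])
    return out[0]
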