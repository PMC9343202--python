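"""Recurrent classifiers over (miRNA, candidate target site) pairs.

The centrepiece is a two-branch stacked bidirectional LSTM: each branch runs
a BiLSTM (hidden 50) over one padded 30-nt encoded sequence, the two
30-step feature maps are concatenated along the time axis into a 60-step
map, a second BiLSTM (hidden 32) reads the joint map, its final forward and
backward hidden states are concatenated (64 features) and reduced by two
linear layers (64 -> 32 -> 2) with a softmax head — the 50-32-32-2 layout.

The LSTM cell follows the standard gate equations

    f_t = sigma(W_f . [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i . [h_{t-1}, x_t] + b_i)
    c_temp = tanh(W_c . [h_{t-1}, x_t] + b_c)
    c_t = f_t * c_{t-1} + i_t * c_temp
    o_t = sigma(W_o . [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(c_t)

with elementwise products.  Vanilla-RNN and GRU cells and a 1-d CNN are
provided as ablation baselines.  Everything is plain numpy with hand-written
reverse-mode gradients; gradient-check tests validate them against central
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

ARCHITECTURES = ("RNN", "GRU", "LSTM", "BiLSTM")

# ---------------------------------------------------------------------------
# Elementary activations
# ---------------------------------------------------------------------------


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Single-example LSTM cell (the reference-equation implementation)
# ---------------------------------------------------------------------------


@dataclass
class LSTMCellParams:
    """Gate weight matrices (hidden x (hidden + input)) and bias vectors.

    Each gate weight multiplies the concatenation [h_{t-1}, x_t].
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        mats = [self.W_f, self.W_i, self.W_c, self.W_o]
        vecs = [self.b_f, self.b_i, self.b_c, self.b_o]
        shapes = {np.asarray(m).shape for m in mats}
        if len(shapes) != 1:
            raise ValueError("all four gate matrices must share one shape")
        lens = {np.asarray(v).shape for v in vecs}
        if len(lens) != 1:
            raise ValueError("all four gate biases must share one length")
        (h, hx) = next(iter(shapes))
        if next(iter(lens)) != (h,):
            raise ValueError("bias length must equal the hidden size")
        if hx <= h:
            raise ValueError("gate matrices must be hidden x (hidden + input)")
        for a in mats + vecs:
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite cell parameter")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


@dataclass
class LSTMState:
    """Hidden state h_t and cell state c_t (both zero at t = 0)."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden: int) -> "LSTMState":
        return cls(h=np.zeros(hidden), c=np.zeros(hidden))


def lstm_cell_step(x_t: np.ndarray, state: LSTMState, params: LSTMCellParams) -> LSTMState:
    """One LSTM time step on a single (unbatched) input vector."""
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape != (params.input_size,):
        raise ValueError(
            f"input has shape {x_t.shape}, expected ({params.input_size},)"
        )
    if state.h.shape != (params.hidden_size,):
        raise ValueError("state size does not match the cell parameters")
    z = np.concatenate([state.h, x_t])
    f_t = sigmoid(params.W_f @ z + params.b_f)
    i_t = sigmoid(params.W_i @ z + params.b_i)
    c_temp = np.tanh(params.W_c @ z + params.b_c)
    c_t = f_t * state.c + i_t * c_temp
    o_t = sigmoid(params.W_o @ z + params.b_o)
    h_t = o_t * np.tanh(c_t)
    return LSTMState(h=h_t, c=c_t)


def bilstm_forward(
    seq: np.ndarray, fwd: LSTMCellParams, bwd: LSTMCellParams
) -> np.ndarray:
    """Bidirectional LSTM feature map for one encoded sequence.

    Row t of the output is [h_fwd_t ; h_bwd_t]: the backward LSTM consumes
    the sequence reversed and its hidden states are re-reversed so that both
    halves align by position.  Initial states are zero in both directions.
    """
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("expected a non-empty (length x dim) encoded sequence")
    length = seq.shape[0]
    hs_f = np.zeros((length, fwd.hidden_size))
    state = LSTMState.zeros(fwd.hidden_size)
    for t in range(length):
        state = lstm_cell_step(seq[t], state, fwd)
        hs_f[t] = state.h
    hs_b = np.zeros((length, bwd.hidden_size))
    state = LSTMState.zeros(bwd.hidden_size)
    for t in range(length - 1, -1, -1):
        state = lstm_cell_step(seq[t], state, bwd)
        hs_b[t] = state.h
    return np.concatenate([hs_f, hs_b], axis=1)


# ---------------------------------------------------------------------------
# Batched recurrent layers with reverse-mode gradients
# ---------------------------------------------------------------------------
# Parameters live in a flat {name: array} dict.  Per cell type and prefix:
#   LSTM: <p>.W_f .W_i .W_c .W_o .b_f .b_i .b_c .b_o
#   GRU:  <p>.W_z .W_r .W_h .b_z .b_r .b_h
#   RNN:  <p>.W .b
# All gate matrices are hidden x (hidden + input) over [h_{t-1}, x_t]; the
# GRU candidate matrix W_h acts on [r_t * h_{t-1}, x_t].


def _init_gate(rng, hidden, input_size):
    bound = 1.0 / np.sqrt(hidden + input_size)
    return rng.uniform(-bound, bound, size=(hidden, hidden + input_size))


def _init_cell(rng, cell: str, hidden: int, input_size: int) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    if cell == "LSTM":
        for g in ("f", "i", "c", "o"):
            p[f"W_{g}"] = _init_gate(rng, hidden, input_size)
        for g in ("f", "i", "c", "o"):
            p[f"b_{g}"] = np.zeros(hidden)
        p["b_f"] = np.ones(hidden)  # forget-gate bias 1: remember by default
    elif cell == "GRU":
        for g in ("z", "r", "h"):
            p[f"W_{g}"] = _init_gate(rng, hidden, input_size)
            p[f"b_{g}"] = np.zeros(hidden)
    elif cell == "RNN":
        p["W"] = _init_gate(rng, hidden, input_size)
        p["b"] = np.zeros(hidden)
    else:
        raise ValueError(f"unknown cell type {cell!r}")
    return p


def _lstm_seq_forward(p, prefix, x):
    B, T, _ = x.shape
    H = p[f"{prefix}.b_f"].shape[0]
    Wf, Wi, Wc, Wo = (p[f"{prefix}.W_{g}"] for g in "fico")
    bf, bi, bc, bo = (p[f"{prefix}.b_{g}"] for g in "fico")
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    steps = []
    for t in range(T):
        z = np.concatenate([h, x[:, t]], axis=1)
        f = sigmoid(z @ Wf.T + bf)
        i = sigmoid(z @ Wi.T + bi)
        g = np.tanh(z @ Wc.T + bc)
        o = sigmoid(z @ Wo.T + bo)
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        steps.append((z, f, i, g, o, c_prev, tc))
    return hs, steps


def _lstm_seq_backward(p, prefix, d_hs, steps, grads, x_shape):
    B, T, D = x_shape
    H = p[f"{prefix}.b_f"].shape[0]
    Wf, Wi, Wc, Wo = (p[f"{prefix}.W_{g}"] for g in "fico")
    dx = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    gWf = grads.setdefault(f"{prefix}.W_f", np.zeros_like(Wf))
    gWi = grads.setdefault(f"{prefix}.W_i", np.zeros_like(Wi))
    gWc = grads.setdefault(f"{prefix}.W_c", np.zeros_like(Wc))
    gWo = grads.setdefault(f"{prefix}.W_o", np.zeros_like(Wo))
    gbf = grads.setdefault(f"{prefix}.b_f", np.zeros(H))
    gbi = grads.setdefault(f"{prefix}.b_i", np.zeros(H))
    gbc = grads.setdefault(f"{prefix}.b_c", np.zeros(H))
    gbo = grads.setdefault(f"{prefix}.b_o", np.zeros(H))
    for t in range(T - 1, -1, -1):
        z, f, i, g, o, c_prev, tc = steps[t]
        dh = d_hs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_g = dg * (1.0 - g * g)
        da_o = do * o * (1.0 - o)
        gWf += da_f.T @ z
        gWi += da_i.T @ z
        gWc += da_g.T @ z
        gWo += da_o.T @ z
        gbf += da_f.sum(axis=0)
        gbi += da_i.sum(axis=0)
        gbc += da_g.sum(axis=0)
        gbo += da_o.sum(axis=0)
        dz = da_f @ Wf + da_i @ Wi + da_g @ Wc + da_o @ Wo
        dh_next = dz[:, :H]
        dx[:, t] = dz[:, H:]
        dc_next = dc * f
    return dx


def _gru_seq_forward(p, prefix, x):
    B, T, _ = x.shape
    H = p[f"{prefix}.b_z"].shape[0]
    Wz, Wr, Wh = (p[f"{prefix}.W_{g}"] for g in "zrh")
    bz, br, bh = (p[f"{prefix}.b_{g}"] for g in "zrh")
    h = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    steps = []
    for t in range(T):
        zc = np.concatenate([h, x[:, t]], axis=1)
        zg = sigmoid(zc @ Wz.T + bz)
        rg = sigmoid(zc @ Wr.T + br)
        zn = np.concatenate([rg * h, x[:, t]], axis=1)
        n = np.tanh(zn @ Wh.T + bh)
        h_prev = h
        h = (1.0 - zg) * h_prev + zg * n
        hs[:, t] = h
        steps.append((zc, zg, rg, zn, n, h_prev))
    return hs, steps


def _gru_seq_backward(p, prefix, d_hs, steps, grads, x_shape):
    B, T, D = x_shape
    H = p[f"{prefix}.b_z"].shape[0]
    Wz, Wr, Wh = (p[f"{prefix}.W_{g}"] for g in "zrh")
    dx = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    gWz = grads.setdefault(f"{prefix}.W_z", np.zeros_like(Wz))
    gWr = grads.setdefault(f"{prefix}.W_r", np.zeros_like(Wr))
    gWh = grads.setdefault(f"{prefix}.W_h", np.zeros_like(Wh))
    gbz = grads.setdefault(f"{prefix}.b_z", np.zeros(H))
    gbr = grads.setdefault(f"{prefix}.b_r", np.zeros(H))
    gbh = grads.setdefault(f"{prefix}.b_h", np.zeros(H))
    for t in range(T - 1, -1, -1):
        zc, zg, rg, zn, n, h_prev = steps[t]
        dh = d_hs[:, t] + dh_next
        dn = dh * zg
        dzg = dh * (n - h_prev)
        dh_prev = dh * (1.0 - zg)
        da_n = dn * (1.0 - n * n)
        gWh += da_n.T @ zn
        gbh += da_n.sum(axis=0)
        dzn = da_n @ Wh
        drh = dzn[:, :H]
        dx[:, t] = dzn[:, H:]
        drg = drh * h_prev
        dh_prev = dh_prev + drh * rg
        da_z = dzg * zg * (1.0 - zg)
        da_r = drg * rg * (1.0 - rg)
        gWz += da_z.T @ zc
        gWr += da_r.T @ zc
        gbz += da_z.sum(axis=0)
        gbr += da_r.sum(axis=0)
        dzc = da_z @ Wz + da_r @ Wr
        dh_prev = dh_prev + dzc[:, :H]
        dx[:, t] += dzc[:, H:]
        dh_next = dh_prev
    return dx


def _rnn_seq_forward(p, prefix, x):
    B, T, _ = x.shape
    H = p[f"{prefix}.b"].shape[0]
    W = p[f"{prefix}.W"]
    b = p[f"{prefix}.b"]
    h = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    steps = []
    for t in range(T):
        z = np.concatenate([h, x[:, t]], axis=1)
        h = np.tanh(z @ W.T + b)
        hs[:, t] = h
        steps.append((z, h))
    return hs, steps


def _rnn_seq_backward(p, prefix, d_hs, steps, grads, x_shape):
    B, T, D = x_shape
    H = p[f"{prefix}.b"].shape[0]
    W = p[f"{prefix}.W"]
    dx = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    gW = grads.setdefault(f"{prefix}.W", np.zeros_like(W))
    gb = grads.setdefault(f"{prefix}.b", np.zeros(H))
    for t in range(T - 1, -1, -1):
        z, h = steps[t]
        dh = d_hs[:, t] + dh_next
        da = dh * (1.0 - h * h)
        gW += da.T @ z
        gb += da.sum(axis=0)
        dz = da @ W
        dh_next = dz[:, :H]
        dx[:, t] = dz[:, H:]
    return dx


_SEQ_FWD = {"LSTM": _lstm_seq_forward, "GRU": _gru_seq_forward, "RNN": _rnn_seq_forward}
_SEQ_BWD = {"LSTM": _lstm_seq_backward, "GRU": _gru_seq_backward, "RNN": _rnn_seq_backward}


def _layer_forward(p, prefix, cell, bidirectional, x):
    """One (possibly bidirectional) recurrent layer over a (B,T,D) batch."""
    fwd = _SEQ_FWD[cell]
    hs_f, steps_f = fwd(p, f"{prefix}.fwd", x)
    if not bidirectional:
        return hs_f, (steps_f, None)
    hs_b, steps_b = fwd(p, f"{prefix}.bwd", x[:, ::-1])
    out = np.concatenate([hs_f, hs_b[:, ::-1]], axis=2)
    return out, (steps_f, steps_b)


def _layer_backward(p, prefix, cell, bidirectional, d_out, caches, grads, x_shape):
    bwd = _SEQ_BWD[cell]
    steps_f, steps_b = caches
    if not bidirectional:
        return bwd(p, f"{prefix}.fwd", d_out, steps_f, grads, x_shape)
    H = d_out.shape[2] // 2
    dx_f = bwd(p, f"{prefix}.fwd", d_out[:, :, :H], steps_f, grads, x_shape)
    dx_b = bwd(p, f"{prefix}.bwd", d_out[:, ::-1, H:], steps_b, grads, x_shape)
    return dx_f + dx_b[:, ::-1]


# ---------------------------------------------------------------------------
# The two-branch stacked classifier
# ---------------------------------------------------------------------------


def _parse_arch(name: str) -> tuple[str, bool]:
    if name not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURES}")
    return ("LSTM", True) if name == "BiLSTM" else (name, False)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the two-branch stacked recurrent classifier.

    Defaults give the 50-32-32-2 layout: branch recurrent layers with 50
    units, a joint layer with 32 units, a 32-unit linear layer, 2 outputs.
    ``share_branches`` ties the miRNA- and CTS-branch layer-1 parameters
    (separate by default).  ``mask_pad`` zeroes layer-1 feature rows at
    all-zero (PAD) input positions before the joint layer; off by default —
    PAD rows are plain zero vectors fed through the recurrence.
    """

    input_dim: int = 50
    layer1: str = "BiLSTM"
    layer2: str = "BiLSTM"
    hidden1: int = 50
    hidden2: int = 32
    linear1_units: int = 32
    share_branches: bool = False
    mask_pad: bool = False
    pool: str = "max"

    def __post_init__(self) -> None:
        if self.pool not in ("max", "last"):
            raise ValueError("pool must be 'max' (over time) or 'last' (final states)")

    @property
    def layer1_width(self) -> int:
        _, bi = _parse_arch(self.layer1)
        return self.hidden1 * (2 if bi else 1)

    @property
    def pooled_width(self) -> int:
        _, bi = _parse_arch(self.layer2)
        return self.hidden2 * (2 if bi else 1)


class SequenceClassifier:
    """Two-branch stacked recurrent classifier with manual backprop.

    Parameters are a flat name -> array dict (float64); ``forward`` returns
    logits plus a cache consumed by ``backward``, which returns gradients
    keyed like the parameters.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, params=None):
        self.config = config
        cell1, bi1 = _parse_arch(config.layer1)
        cell2, bi2 = _parse_arch(config.layer2)
        self._cell1, self._bi1 = cell1, bi1
        self._cell2, self._bi2 = cell2, bi2
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        branch_prefixes = ["branch_l1"] if config.share_branches else ["mirna_l1", "cts_l1"]
        for bp in branch_prefixes:
            for direction in (("fwd", "bwd") if bi1 else ("fwd",)):
                for k, v in _init_cell(rng, cell1, config.hidden1, config.input_dim).items():
                    p[f"{bp}.{direction}.{k}"] = v
        for direction in (("fwd", "bwd") if bi2 else ("fwd",)):
            for k, v in _init_cell(rng, cell2, config.hidden2, config.layer1_width).items():
                p[f"l2.{direction}.{k}"] = v
        pooled = config.pooled_width
        bound1 = 1.0 / np.sqrt(pooled)
        p["linear1.W"] = rng.uniform(-bound1, bound1, size=(config.linear1_units, pooled))
        p["linear1.b"] = np.zeros(config.linear1_units)
        bound2 = 1.0 / np.sqrt(config.linear1_units)
        p["linear2.W"] = rng.uniform(-bound2, bound2, size=(2, config.linear1_units))
        p["linear2.b"] = np.zeros(2)
        self.params = p

    def _branch_prefix(self, which: str) -> str:
        if self.config.share_branches:
            return "branch_l1"
        return "mirna_l1" if which == "mirna" else "cts_l1"

    def forward(self, mirna: np.ndarray, cts: np.ndarray):
        """Batched forward pass.

        ``mirna`` and ``cts`` are (B, 30, d) encoded batches.  Returns
        ``(logits (B, 2), cache)``.
        """
        mirna = np.asarray(mirna, dtype=np.float64)
        cts = np.asarray(cts, dtype=np.float64)
        if mirna.ndim != 3 or cts.ndim != 3:
            raise ValueError("expected (batch, length, dim) encoded inputs")
        if mirna.shape[2] != self.config.input_dim or cts.shape[2] != self.config.input_dim:
            raise ValueError(
                f"input dim mismatch: model expects {self.config.input_dim}, "
                f"got {mirna.shape[2]} / {cts.shape[2]}"
            )
        p = self.params
        m1, cache_m = _layer_forward(p, self._branch_prefix("mirna"), self._cell1, self._bi1, mirna)
        c1, cache_c = _layer_forward(p, self._branch_prefix("cts"), self._cell1, self._bi1, cts)
        masks = None
        if self.config.mask_pad:
            mask_m = np.any(mirna != 0.0, axis=2)[:, :, None].astype(np.float64)
            mask_c = np.any(cts != 0.0, axis=2)[:, :, None].astype(np.float64)
            m1 = m1 * mask_m
            c1 = c1 * mask_c
            masks = (mask_m, mask_c)
        joint = np.concatenate([m1, c1], axis=1)  # (B, 60, layer1_width)
        h2, cache_2 = _layer_forward(p, "l2", self._cell2, self._bi2, joint)
        H2 = self.config.hidden2
        if self.config.pool == "max":
            pool_arg = np.argmax(h2, axis=1)  # (B, width)
            pooled = np.take_along_axis(h2, pool_arg[:, None, :], axis=1)[:, 0]
        else:
            pool_arg = None
            if self._bi2:
                pooled = np.concatenate([h2[:, -1, :H2], h2[:, 0, H2:]], axis=1)
            else:
                pooled = h2[:, -1, :]
        a1 = pooled @ p["linear1.W"].T + p["linear1.b"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ p["linear2.W"].T + p["linear2.b"]
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite activation in the classifier head")
        cache = (mirna.shape, cts.shape, cache_m, cache_c, masks, joint.shape,
                 cache_2, h2.shape, pool_arg, pooled, a1, r1)
        return logits, cache

    def backward(self, d_logits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``d_logits`` is dLoss/dlogits for the batch (already summed over
        examples downstream, i.e. gradients accumulate across the batch).
        """
        (m_shape, c_shape, cache_m, cache_c, masks, joint_shape,
         cache_2, h2_shape, pool_arg, pooled, a1, r1) = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        d_logits = np.asarray(d_logits, dtype=np.float64)
        grads["linear2.W"] = d_logits.T @ r1
        grads["linear2.b"] = d_logits.sum(axis=0)
        d_r1 = d_logits @ p["linear2.W"]
        d_a1 = d_r1 * (a1 > 0.0)
        grads["linear1.W"] = d_a1.T @ pooled
        grads["linear1.b"] = d_a1.sum(axis=0)
        d_pooled = d_a1 @ p["linear1.W"]
        B, T2, W2 = h2_shape
        d_h2 = np.zeros((B, T2, W2))
        H2 = self.config.hidden2
        if pool_arg is not None:
            np.put_along_axis(d_h2, pool_arg[:, None, :], d_pooled[:, None, :], axis=1)
        elif self._bi2:
            d_h2[:, -1, :H2] = d_pooled[:, :H2]
            d_h2[:, 0, H2:] = d_pooled[:, H2:]
        else:
            d_h2[:, -1, :] = d_pooled
        d_joint = _layer_backward(p, "l2", self._cell2, self._bi2, d_h2, cache_2, grads, joint_shape)
        T1 = m_shape[1]
        d_m1 = d_joint[:, :T1]
        d_c1 = d_joint[:, T1:]
        if masks is not None:
            d_m1 = d_m1 * masks[0]
            d_c1 = d_c1 * masks[1]
        _layer_backward(p, self._branch_prefix("mirna"), self._cell1, self._bi1,
                        d_m1, cache_m, grads, m_shape)
        _layer_backward(p, self._branch_prefix("cts"), self._cell1, self._bi1,
                        d_c1, cache_c, grads, c_shape)
        return grads

    def predict_proba(self, mirna: np.ndarray, cts: np.ndarray) -> np.ndarray:
        """Class probabilities (non-binding, binding), rows summing to 1."""
        logits, _ = self.forward(mirna, cts)
        return softmax(logits)


def make_variant(arch: tuple[str, str]):
    """Constructor for the two-branch topology with substituted cells.

    ``arch`` names the recurrent unit of each of the two layers, e.g.
    ``("BiLSTM", "BiLSTM")`` (the reference model) or ``("GRU", "GRU")``.
    Returns ``constructor(input_dim, seed, **overrides) -> SequenceClassifier``.
    """
    layer1, layer2 = arch
    _parse_arch(layer1)
    _parse_arch(layer2)

    def construct(input_dim: int, seed: int = 0, **overrides) -> SequenceClassifier:
        cfg = ModelConfig(input_dim=input_dim, layer1=layer1, layer2=layer2, **overrides)
        return SequenceClassifier(cfg, seed=seed)

    return construct


# ---------------------------------------------------------------------------
# Spec-level functional surface over explicit parameter structures
# ---------------------------------------------------------------------------


@dataclass
class ClassProbabilities:
    """Softmax output (P(non-binding), P(binding))."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (2,):
            raise ValueError("expected a 2-class probability vector")
        if abs(float(self.p.sum()) - 1.0) > 1e-9 or np.any(self.p < -1e-12):
            raise ValueError("probabilities must be in [0,1] and sum to 1")

    @property
    def binding(self) -> float:
        return float(self.p[1])


@dataclass
class StackedModelParams:
    """Explicit parameters of the default 50-32-32-2 two-branch BiLSTM.

    Layer-1 cells take the d-dimensional embedding; the joint layer-2 cells
    take the 100-wide bidirectional layer-1 output; linear1 maps the 64-wide
    pooled summary to 32 units and linear2 to the 2 classes.
    """

    branch_mirna_l1: tuple[LSTMCellParams, LSTMCellParams]
    branch_cts_l1: tuple[LSTMCellParams, LSTMCellParams]
    shared_l2: tuple[LSTMCellParams, LSTMCellParams]
    linear1: tuple[np.ndarray, np.ndarray]
    linear2: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        h1 = self.branch_mirna_l1[0].hidden_size
        if self.shared_l2[0].input_size != 2 * h1:
            raise ValueError("layer-2 input size must be twice the layer-1 hidden size")
        pooled = 2 * self.shared_l2[0].hidden_size
        if self.linear1[0].shape[1] != pooled:
            raise ValueError("linear1 input width must match the pooled summary")
        if self.linear2[0].shape[0] != 2:
            raise ValueError("linear2 must output 2 classes")
        if self.linear2[0].shape[1] != self.linear1[0].shape[0]:
            raise ValueError("linear2 input width must match linear1 output")

    def to_flat(self) -> tuple[ModelConfig, dict[str, np.ndarray]]:
        cfg = ModelConfig(
            input_dim=self.branch_mirna_l1[0].input_size,
            hidden1=self.branch_mirna_l1[0].hidden_size,
            hidden2=self.shared_l2[0].hidden_size,
            linear1_units=self.linear1[0].shape[0],
        )
        flat: dict[str, np.ndarray] = {}
        named = [("mirna_l1", self.branch_mirna_l1), ("cts_l1", self.branch_cts_l1),
                 ("l2", self.shared_l2)]
        for prefix, (fwd, bwd) in named:
            for direction, cell in (("fwd", fwd), ("bwd", bwd)):
                for g in "fico":
                    flat[f"{prefix}.{direction}.W_{g}"] = getattr(cell, f"W_{g}")
                    flat[f"{prefix}.{direction}.b_{g}"] = getattr(cell, f"b_{g}")
        flat["linear1.W"], flat["linear1.b"] = self.linear1
        flat["linear2.W"], flat["linear2.b"] = self.linear2
        return cfg, flat

    @classmethod
    def from_classifier(cls, model: SequenceClassifier) -> "StackedModelParams":
        if (model.config.layer1, model.config.layer2) != ("BiLSTM", "BiLSTM"):
            raise ValueError("explicit parameter view exists only for the BiLSTM stack")
        p = model.params

        def cell(prefix: str) -> LSTMCellParams:
            return LSTMCellParams(**{
                f"{k}_{g}": p[f"{prefix}.{k}_{g}"] for k in ("W", "b") for g in "fico"
            })

        def pair(prefix: str) -> tuple[LSTMCellParams, LSTMCellParams]:
            return (cell(f"{prefix}.fwd"), cell(f"{prefix}.bwd"))

        b1 = "branch_l1" if model.config.share_branches else "mirna_l1"
        b2 = "branch_l1" if model.config.share_branches else "cts_l1"
        return cls(
            branch_mirna_l1=pair(b1),
            branch_cts_l1=pair(b2),
            shared_l2=pair("l2"),
            linear1=(p["linear1.W"], p["linear1.b"]),
            linear2=(p["linear2.W"], p["linear2.b"]),
        )


def stacked_forward(
    mirna_enc: np.ndarray, cts_enc: np.ndarray, params: StackedModelParams
) -> tuple[np.ndarray, ClassProbabilities]:
    """Classify one encoded (miRNA, CTS) pair with the two-branch stack.

    Both encodings must be padded to 30 rows of the same embedding
    dimension.  Returns (logits, class probabilities).
    """
    mirna_enc = np.asarray(mirna_enc, dtype=np.float64)
    cts_enc = np.asarray(cts_enc, dtype=np.float64)
    if mirna_enc.shape != cts_enc.shape or mirna_enc.ndim != 2:
        raise ValueError("encodings must be two (30 x d) matrices of equal shape")
    cfg, flat = params.to_flat()
    model = SequenceClassifier(cfg, params=flat)
    logits, _ = model.forward(mirna_enc[None], cts_enc[None])
    return logits[0], ClassProbabilities(p=softmax(logits[0]))


# ---------------------------------------------------------------------------
# CNN1d baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    """1-d CNN baseline: two conv+ReLU+max-pool blocks and a linear head.

    Convolutions run along the 60-step concatenated time axis (kernel 5,
    stride 1, valid padding; 32 then 64 filters; pool width 2).
    """

    input_dim: int = 50
    seq_len: int = 60
    filters1: int = 32
    filters2: int = 64
    kernel: int = 5
    pool: int = 2


def _conv1d_forward(x, W, b):
    # x (B, T, D), W (F, K, D) -> out (B, T-K+1, F)
    B, T, D = x.shape
    F, K, _ = W.shape
    L = T - K + 1
    cols = np.zeros((B, L, K * D))
    for k in range(K):
        cols[:, :, k * D:(k + 1) * D] = x[:, k:k + L]
    out = cols @ W.reshape(F, K * D).T + b
    return out, cols


def _conv1d_backward(d_out, cols, W, x_shape):
    B, T, D = x_shape
    F, K, _ = W.shape
    L = T - K + 1
    dW = np.einsum("blf,blc->fc", d_out, cols).reshape(F, K, D)
    db = d_out.sum(axis=(0, 1))
    d_cols = d_out @ W.reshape(F, K * D)
    dx = np.zeros((B, T, D))
    for k in range(K):
        dx[:, k:k + L] += d_cols[:, :, k * D:(k + 1) * D]
    return dx, dW, db


def _maxpool_forward(x, width):
    B, T, F = x.shape
    L = T // width
    xr = x[:, : L * width].reshape(B, L, width, F)
    idx = np.argmax(xr, axis=2)
    out = np.max(xr, axis=2)
    return out, (idx, x.shape, L, width)


def _maxpool_backward(d_out, cache):
    idx, x_shape, L, width = cache
    B, T, F = x_shape
    dx = np.zeros((B, L, width, F))
    bi, li, fi = np.meshgrid(np.arange(B), np.arange(L), np.arange(F), indexing="ij")
    dx[bi, li, idx, fi] = d_out
    dx = dx.reshape(B, L * width, F)
    if L * width < T:
        dx = np.concatenate([dx, np.zeros((B, T - L * width, F))], axis=1)
    return dx


class CNN1d:
    """Baseline convolutional classifier over the concatenated pair."""

    def __init__(self, config: CNNConfig, seed: int = 0, params=None):
        self.config = config
        c = config
        l1 = (c.seq_len - c.kernel + 1) // c.pool
        l2 = (l1 - c.kernel + 1) // c.pool
        if l2 < 1:
            raise ValueError("sequence too short for the configured CNN")
        self._flat = l2 * c.filters2
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(seed)

        def u(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        self.params = {
            "conv1.W": u((c.filters1, c.kernel, c.input_dim), c.kernel * c.input_dim),
            "conv1.b": np.zeros(c.filters1),
            "conv2.W": u((c.filters2, c.kernel, c.filters1), c.kernel * c.filters1),
            "conv2.b": np.zeros(c.filters2),
            "head.W": u((2, self._flat), self._flat),
            "head.b": np.zeros(2),
        }

    def forward(self, mirna: np.ndarray, cts: np.ndarray):
        x = np.concatenate([np.asarray(mirna, dtype=np.float64),
                            np.asarray(cts, dtype=np.float64)], axis=1)
        if x.shape[1] != self.config.seq_len or x.shape[2] != self.config.input_dim:
            raise ValueError("encoded pair does not match the CNN configuration")
        p = self.params
        a1, cols1 = _conv1d_forward(x, p["conv1.W"], p["conv1.b"])
        r1 = np.maximum(a1, 0.0)
        m1, mp1 = _maxpool_forward(r1, self.config.pool)
        a2, cols2 = _conv1d_forward(m1, p["conv2.W"], p["conv2.b"])
        r2 = np.maximum(a2, 0.0)
        m2, mp2 = _maxpool_forward(r2, self.config.pool)
        flat = m2.reshape(m2.shape[0], -1)
        logits = flat @ p["head.W"].T + p["head.b"]
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite activation in the CNN head")
        cache = (x.shape, cols1, a1, mp1, m1.shape, cols2, a2, mp2, m2.shape, flat)
        return logits, cache

    def backward(self, d_logits, cache):
        (x_shape, cols1, a1, mp1, m1_shape, cols2, a2, mp2, m2_shape, flat) = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["head.W"] = np.asarray(d_logits).T @ flat
        grads["head.b"] = np.asarray(d_logits).sum(axis=0)
        d_flat = np.asarray(d_logits) @ p["head.W"]
        d_m2 = d_flat.reshape(m2_shape)
        d_r2 = _maxpool_backward(d_m2, mp2)
        d_a2 = d_r2 * (a2 > 0.0)
        d_m1, grads["conv2.W"], grads["conv2.b"] = _conv1d_backward(
            d_a2, cols2, p["conv2.W"], m1_shape)
        d_r1 = _maxpool_backward(d_m1, mp1)
        d_a1 = d_r1 * (a1 > 0.0)
        _, grads["conv1.W"], grads["conv1.b"] = _conv1d_backward(
            d_a1, cols1, p["conv1.W"], x_shape)
        return grads

    def predict_proba(self, mirna: np.ndarray, cts: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(mirna, cts)
        return softmax(logits)


def cnn1d_forward(
    mirna_enc: np.ndarray, cts_enc: np.ndarray, model: CNN1d
) -> ClassProbabilities:
    """Single-pair probability from the CNN1d baseline."""
    probs = model.predict_proba(
        np.asarray(mirna_enc)[None], np.asarray(cts_enc)[None]
    )
    return ClassProbabilities(p=probs[0])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model, path) -> None:
    """Write all parameter tensors plus the config to one archive.

    The format is a JSON header line (config + ordered tensor names)
    followed by each tensor in .npy format.  The round trip through
    :func:`load_checkpoint` is bit-exact, and identical models produce
    byte-identical files (no timestamps).
    """
    kind = "cnn" if isinstance(model, CNN1d) else "rnn"
    keys = sorted(model.params)
    header = json.dumps(
        {"kind": kind, "config": model.config.__dict__, "tensors": keys},
        sort_keys=True,
    )
    with open(path, "wb") as fh:
        fh.write(header.encode() + b"\n")
        for k in keys:
            np.lib.format.write_array(fh, np.ascontiguousarray(model.params[k]))


def load_checkpoint(path):
    """Reconstruct a classifier saved by :func:`save_checkpoint`."""
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        params = {k: np.lib.format.read_array(fh) for k in header["tensors"]}
    cfg = header["config"]
    if header["kind"] == "cnn":
        return CNN1d(CNNConfig(**cfg), params=params)
    return SequenceClassifier(ModelConfig(**cfg), params=params)
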