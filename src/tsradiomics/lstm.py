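"""Parallel multistream LSTM classifier for variable-length feature series.

One LSTM per feature stream is run over a patient's standardized visit
sequence (masked post-padding; padded steps carry state through unchanged).
The last hidden state of every stream is concatenated into a single vector
h_i, passed through dropout (training only, inverted convention) and a
1-unit dense sigmoid head to give the progression probability

    o_i = sigmoid(W_l . h~_i + b_l).

Per stream k and gate g in {input, forget, output, candidate}:

    i_t = sigmoid(h_{t-1} U_i + x_t W_i + b_i)
    f_t = sigmoid(h_{t-1} U_f + x_t W_f + b_f)
    o_t = sigmoid(h_{t-1} U_o + x_t W_o + b_o)
    g_t = tanh   (h_{t-1} U_c + x_t W_c + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

with W_g of shape d_k x H_k (Glorot-uniform init), U_g of shape H_k x H_k
(random orthogonal init), and zero biases. Training is full-batch gradient
descent on binary cross-entropy with Adam; forward, backward (BPTT through
the mask) and the optimiser are implemented here in numpy, and the gradients
are validated against central finite differences in the test suite.

All trainable values live in one flat float64 vector; the per-stream/per-gate
matrices are reshaped views into it, so the Adam update is a handful of
whole-vector operations and the gate equations still read naturally. The
time loop stores its activations in (T, N, .) order so the gradient
accumulations reduce to two GEMMs per stream.

The ``tied_input_forget_recurrence`` switch makes the input gate reuse the
forget gate's recurrent kernel U_f — an audit mode for a variant sometimes
(mis)printed in the literature; the default uses four independent recurrent
kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort, PatientSeries, StreamSchema
from .errors import SchemaError, TrainingError, ValidationError
from .preprocessing import PaddedBatch, StandardizationParams, apply_standardizer, \
    fit_standardizer, pad_and_mask

GATES = ("i", "f", "o", "c")  # column-block order inside the packed kernels


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Hyperparameters and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TSRHyperparams:
    """Training configuration; the defaults are the tuned operating point
    (130 epochs, learning rate 0.002, dropout 0.2, 16 hidden units per
    stream) selected by random-search LOOCV in the motivating study."""

    hidden_units: int | tuple[int, ...] = 16
    dropout_rate: float = 0.2
    learning_rate: float = 0.002
    epochs: int = 130
    tied_input_forget_recurrence: bool = False
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.learning_rate < 0:
            raise ValidationError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")

    def units_for(self, schema: StreamSchema) -> tuple[int, ...]:
        if isinstance(self.hidden_units, int):
            if self.hidden_units < 1:
                raise ValidationError("hidden_units must be positive")
            return tuple(self.hidden_units for _ in schema.widths)
        units = tuple(int(h) for h in self.hidden_units)
        if len(units) != schema.n_streams:
            raise ValidationError(
                f"hidden_units has {len(units)} entries for {schema.n_streams} streams"
            )
        if any(h < 1 for h in units):
            raise ValidationError(f"hidden units must be positive, got {units}")
        return units


class TSRModelParams:
    """All trainable weights, stored in one flat vector with named views.

    Per stream the four gate kernels are packed column-wise in GATES order:
    ``kernels[k]`` is d_k x 4H_k (input kernels W_g), ``recurrents[k]`` is
    H_k x 4H_k (recurrent kernels U_g), ``biases[k]`` has length 4H_k. The
    head is a weight vector of length sum(H_k) plus a scalar bias. The
    per-gate accessors :meth:`kernel`, :meth:`recurrent` and :meth:`bias`
    return H_k-wide column views.
    """

    __slots__ = ("schema", "hidden", "flat", "kernels", "recurrents", "biases",
                 "head_w", "_head_b")

    def __init__(self, schema: StreamSchema, hidden: tuple[int, ...],
                 flat: np.ndarray | None = None):
        self.schema = schema
        self.hidden = tuple(hidden)
        if len(self.hidden) != schema.n_streams:
            raise SchemaError("one hidden size per stream required")
        size = self.n_parameters(schema, self.hidden)
        if flat is None:
            flat = np.zeros(size)
        elif flat.shape != (size,):
            raise SchemaError(f"flat parameter vector must have length {size}")
        self.flat = flat
        self.kernels, self.recurrents, self.biases = [], [], []
        off = 0
        for d_k, h_k in zip(schema.widths, self.hidden):
            self.kernels.append(flat[off : off + d_k * 4 * h_k].reshape(d_k, 4 * h_k))
            off += d_k * 4 * h_k
            self.recurrents.append(flat[off : off + 4 * h_k * h_k].reshape(h_k, 4 * h_k))
            off += 4 * h_k * h_k
            self.biases.append(flat[off : off + 4 * h_k])
            off += 4 * h_k
        total_h = sum(self.hidden)
        self.head_w = flat[off : off + total_h]
        off += total_h
        self._head_b = flat[off : off + 1]

    @staticmethod
    def n_parameters(schema: StreamSchema, hidden: tuple[int, ...]) -> int:
        return sum(
            4 * h * (d + h + 1) for d, h in zip(schema.widths, hidden)
        ) + sum(hidden) + 1

    @property
    def head_b(self) -> float:
        return float(self._head_b[0])

    @head_b.setter
    def head_b(self, value: float) -> None:
        self._head_b[0] = value

    def _gate_slice(self, k: int, gate: str) -> slice:
        h = self.hidden[k]
        g = GATES.index(gate)
        return slice(g * h, (g + 1) * h)

    def kernel(self, k: int, gate: str) -> np.ndarray:
        """Input kernel W_g for stream k (d_k x H_k view)."""
        return self.kernels[k][:, self._gate_slice(k, gate)]

    def recurrent(self, k: int, gate: str) -> np.ndarray:
        """Recurrent kernel U_g for stream k (H_k x H_k view)."""
        return self.recurrents[k][:, self._gate_slice(k, gate)]

    def bias(self, k: int, gate: str) -> np.ndarray:
        """Bias b_g for stream k (length H_k view)."""
        return self.biases[k][self._gate_slice(k, gate)]

    def copy(self) -> "TSRModelParams":
        return TSRModelParams(self.schema, self.hidden, self.flat.copy())


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))  # fix the QR sign ambiguity -> Haar-uniform


def init_params(schema: StreamSchema, hyper: TSRHyperparams, seed: int) -> TSRModelParams:
    """Fresh weights: Glorot-uniform input kernels (fan_in=d_k, fan_out=H_k),
    random orthogonal recurrent kernels per gate, zero biases; Glorot head
    weights and zero head bias. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    hidden = hyper.units_for(schema)
    params = TSRModelParams(schema, hidden)
    for k, (d_k, h_k) in enumerate(zip(schema.widths, hidden)):
        for gate in GATES:
            params.kernel(k, gate)[:] = _glorot_uniform(rng, d_k, h_k, (d_k, h_k))
            params.recurrent(k, gate)[:] = _orthogonal(rng, h_k)
        # biases already zero
    total_h = sum(hidden)
    params.head_w[:] = _glorot_uniform(rng, total_h, 1, (total_h,))
    return params


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

class _StreamCache:
    """Time-major activations kept for BPTT. ``z`` holds the gate
    activations written in place over the pre-activations: columns
    [i | f | o | candidate], each T x N x H_k."""

    __slots__ = ("z", "tanh_c", "h_prev", "c_prev", "x_flat", "u_eff")

    def __init__(self, z, tanh_c, h_prev, c_prev, x_flat, u_eff):
        self.z = z
        self.tanh_c = tanh_c
        self.h_prev = h_prev
        self.c_prev = c_prev
        self.x_flat = x_flat
        self.u_eff = u_eff


def _effective_recurrent(params: TSRModelParams, k: int, tied: bool) -> np.ndarray:
    u = params.recurrents[k]
    if not tied:
        return u
    u_eff = u.copy()
    h = params.hidden[k]
    u_eff[:, 0:h] = params.recurrent(k, "f")  # input gate reuses U_f
    return u_eff


def _run_stream(x: np.ndarray, mask: np.ndarray, params: TSRModelParams, k: int,
                tied: bool, keep_cache: bool):
    """Masked LSTM over one stream. x: N x T x d_k, mask: N x T (prefix-ones).

    The input projection x W + b for every step is a single GEMM; the time
    loop carries only the recurrence h U. Padded steps are computed and then
    overwritten with the carried state (their cached values are inert in the
    backward pass, which masks every contribution).
    """
    n, t_max, d_k = x.shape
    h_k = params.hidden[k]
    u_eff = _effective_recurrent(params, k, tied)
    x_flat = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(t_max * n, d_k)
    z_all = (x_flat @ params.kernels[k] + params.biases[k]).reshape(t_max, n, 4 * h_k)
    tc_all = np.empty((t_max, n, h_k))
    hp_all = np.empty((t_max, n, h_k)) if keep_cache else None
    cp_all = np.empty((t_max, n, h_k)) if keep_cache else None
    pad_rows = [np.flatnonzero(mask[:, t] == 0) for t in range(t_max)]

    h = np.zeros((n, h_k))
    c = np.zeros((n, h_k))
    for t in range(t_max):
        z = z_all[t]
        z += h @ u_eff
        zs = z[:, : 3 * h_k]          # sigmoid gates, in place
        np.negative(zs, out=zs)
        np.exp(zs, out=zs)
        zs += 1.0
        np.reciprocal(zs, out=zs)
        cand = z[:, 3 * h_k :]
        np.tanh(cand, out=cand)
        if keep_cache:
            hp_all[t] = h
            cp_all[t] = c
        c_new = z[:, h_k : 2 * h_k] * c          # f * c_prev
        c_new += z[:, 0 * h_k : 1 * h_k] * cand  # + i * candidate
        tc = tc_all[t]
        np.tanh(c_new, out=tc)
        h_new = z[:, 2 * h_k : 3 * h_k] * tc     # o * tanh(c)
        pad = pad_rows[t]
        if pad.size:  # padded steps: carry state through unchanged
            h_new[pad] = h[pad]
            c_new[pad] = c[pad]
        h, c = h_new, c_new
    cache = _StreamCache(z_all, tc_all, hp_all, cp_all, x_flat, u_eff) \
        if keep_cache else None
    return h, c, cache, u_eff


@dataclass
class ForwardTrace:
    """Per-stream, per-step gate and state activations, kept for diagnostics
    and invariant checks. ``gates[k][name]`` has shape N x T_max x H_k;
    entries at padded steps are inert placeholders."""

    gates: list[dict[str, np.ndarray]]
    hidden: list[np.ndarray]          # h after each step, N x T_max x H_k
    cell: list[np.ndarray]            # c after each step
    h_concat: np.ndarray              # N x sum(H_k), pre-dropout
    probs: np.ndarray


def forward(batch: PaddedBatch, params: TSRModelParams,
            hyper: TSRHyperparams | None = None, training: bool = False,
            rng: np.random.Generator | None = None,
            return_trace: bool = False):
    """Per-patient progression probabilities for a padded batch.

    In training mode, inverted dropout at ``hyper.dropout_rate`` is applied
    to the concatenated last hidden states (``rng`` required when the rate is
    positive); inference applies no dropout and is deterministic.
    """
    hyper = hyper or TSRHyperparams()
    if len(batch.streams) != params.schema.n_streams:
        raise SchemaError(
            f"batch has {len(batch.streams)} streams, params expect "
            f"{params.schema.n_streams}"
        )
    tied = hyper.tied_input_forget_recurrence
    finals, caches = [], []
    for k, x in enumerate(batch.streams):
        if x.shape[2] != params.schema.widths[k]:
            raise SchemaError(
                f"stream {k}: width {x.shape[2]} != schema {params.schema.widths[k]}"
            )
        h_fin, _, cache, _ = _run_stream(x, batch.mask, params, k, tied,
                                         keep_cache=return_trace)
        finals.append(h_fin)
        caches.append(cache)
    h_cat = np.concatenate(finals, axis=1)
    h_drop = h_cat
    if training and hyper.dropout_rate > 0:
        if rng is None:
            raise ValidationError("training-mode dropout needs an rng")
        keep = 1.0 - hyper.dropout_rate
        d_mask = (rng.random(h_cat.shape) < keep).astype(float)
        h_drop = h_cat * d_mask / keep
    probs = _sigmoid(h_drop @ params.head_w + params.head_b)
    if not return_trace:
        return probs
    gates, hidden, cell = [], [], []
    m3 = batch.mask[:, :, None]
    for k, cache in enumerate(caches):
        h_k = params.hidden[k]
        z = cache.z.transpose(1, 0, 2)  # back to N x T x 4H
        ig, fg = z[:, :, :h_k], z[:, :, h_k : 2 * h_k]
        og, cand = z[:, :, 2 * h_k : 3 * h_k], z[:, :, 3 * h_k :]
        tc = cache.tanh_c.transpose(1, 0, 2)
        hp = cache.h_prev.transpose(1, 0, 2)
        cp = cache.c_prev.transpose(1, 0, 2)
        gates.append({"i": ig, "f": fg, "o": og, "candidate": cand})
        hidden.append(m3 * (og * tc) + (1 - m3) * hp)
        cell.append(m3 * (fg * cp + ig * cand) + (1 - m3) * cp)
    trace = ForwardTrace(gates=gates, hidden=hidden, cell=cell,
                         h_concat=h_cat, probs=probs)
    return probs, trace


def lstm_cell_step(x_j: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   params: TSRModelParams, stream: int = 0,
                   tied: bool = False):
    """Single LSTM cell update for one stream: returns (h_j, c_j, gates)
    where gates maps {"i","f","o","candidate"} to their activations."""
    x_j = np.asarray(x_j, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    d_k = params.schema.widths[stream]
    h_k = params.hidden[stream]
    if x_j.shape != (d_k,) or h_prev.shape != (h_k,) or c_prev.shape != (h_k,):
        raise SchemaError(
            f"expected shapes x=({d_k},), h=c=({h_k},); got "
            f"{x_j.shape}, {h_prev.shape}, {c_prev.shape}"
        )
    u_eff = _effective_recurrent(params, stream, tied)
    z = h_prev @ u_eff + x_j @ params.kernels[stream] + params.biases[stream]
    ig = _sigmoid(z[0 * h_k : 1 * h_k])
    fg = _sigmoid(z[1 * h_k : 2 * h_k])
    og = _sigmoid(z[2 * h_k : 3 * h_k])
    cand = np.tanh(z[3 * h_k : 4 * h_k])
    c_j = fg * c_prev + ig * cand
    h_j = og * np.tanh(c_j)
    return h_j, c_j, {"i": ig, "f": fg, "o": og, "candidate": cand}


# ---------------------------------------------------------------------------
# Loss and gradients
# ---------------------------------------------------------------------------

_EPS_CLIP = 1e-12


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy, probabilities clipped away from {0,1}."""
    p = np.clip(probs, _EPS_CLIP, 1.0 - _EPS_CLIP)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def compute_loss(params: TSRModelParams, batch: PaddedBatch,
                 hyper: TSRHyperparams | None = None) -> float:
    """Inference-mode BCE of the batch under the given parameters."""
    return bce_loss(forward(batch, params, hyper, training=False), batch.labels)


def bce_gradients(params: TSRModelParams, batch: PaddedBatch,
                  hyper: TSRHyperparams | None = None,
                  dropout_mask: np.ndarray | None = None):
    """Analytic gradients of mean BCE w.r.t. every parameter (BPTT through
    the masked streams). ``dropout_mask`` (N x sum H_k of 0/1), if given, is
    applied to h_i with inverted scaling, matching a training-mode forward.

    Returns ``(loss, grads, h_cat)`` where grads is a :class:`TSRModelParams`
    holding the gradient in each slot and h_cat is the pre-dropout
    concatenated last-hidden-state matrix (useful for a cheap dropout-free
    loss evaluation).
    """
    hyper = hyper or TSRHyperparams()
    tied = hyper.tied_input_forget_recurrence
    n, t_max = batch.mask.shape
    y = batch.labels.astype(float)

    finals, caches = [], []
    for k, x in enumerate(batch.streams):
        h_fin, _, cache, _ = _run_stream(x, batch.mask, params, k, tied,
                                         keep_cache=True)
        finals.append(h_fin)
        caches.append(cache)
    h_cat = np.concatenate(finals, axis=1)

    keep = 1.0 - hyper.dropout_rate
    if dropout_mask is not None:
        h_drop = h_cat * dropout_mask / keep
    else:
        h_drop = h_cat
    logits = h_drop @ params.head_w + params.head_b
    probs = _sigmoid(logits)
    loss = bce_loss(probs, y)

    grads = TSRModelParams(params.schema, params.hidden)
    d_logit = (probs - y) / n
    grads.head_w[:] = h_drop.T @ d_logit
    grads.head_b = d_logit.sum()
    dh_cat = np.outer(d_logit, params.head_w)
    if dropout_mask is not None:
        dh_cat *= dropout_mask
        dh_cat /= keep

    # float mask, time-major, and its complement for the state carry
    mf = np.ascontiguousarray(batch.mask.T)[:, :, None]
    inv_mf = 1.0 - mf

    col = 0
    for k in range(len(batch.streams)):
        h_k = params.hidden[k]
        cache = caches[k]
        z_all, tc_all = cache.z, cache.tanh_c
        dh = dh_cat[:, col : col + h_k].copy()
        col += h_k
        dc = np.zeros_like(dh)
        dz_all = np.empty((t_max, n, 4 * h_k))
        u_eff_t = np.ascontiguousarray(cache.u_eff.T)
        for t in range(t_max - 1, -1, -1):
            z = z_all[t]
            ig = z[:, 0 * h_k : 1 * h_k]
            fg = z[:, 1 * h_k : 2 * h_k]
            og = z[:, 2 * h_k : 3 * h_k]
            cand = z[:, 3 * h_k :]
            tc = tc_all[t]
            m, im = mf[t], inv_mf[t]
            dh_eff = dh * m
            d_og = dh_eff * tc
            dct = dc * m
            dct += dh_eff * og * (1.0 - tc * tc)
            dz = dz_all[t]
            dz[:, 0 * h_k : 1 * h_k] = (dct * cand) * (ig * (1.0 - ig))
            dz[:, 1 * h_k : 2 * h_k] = (dct * cache.c_prev[t]) * (fg * (1.0 - fg))
            dz[:, 2 * h_k : 3 * h_k] = d_og * (og * (1.0 - og))
            dz[:, 3 * h_k :] = (dct * ig) * (1.0 - cand * cand)
            dh *= im
            dh += dz @ u_eff_t
            dc *= im
            dc += dct * fg
        flat_dz = dz_all.reshape(t_max * n, 4 * h_k)
        np.dot(cache.x_flat.T, flat_dz, out=grads.kernels[k])
        np.dot(cache.h_prev.reshape(t_max * n, h_k).T, flat_dz,
               out=grads.recurrents[k])
        np.sum(flat_dz, axis=0, out=grads.biases[k])
        if tied:
            # input-gate recurrence reads U_f, so its gradient block moves there
            grads.recurrents[k][:, 1 * h_k : 2 * h_k] += grads.recurrents[k][:, 0:h_k]
            grads.recurrents[k][:, 0:h_k] = 0.0
    return loss, grads, h_cat


# ---------------------------------------------------------------------------
# Training (full-batch Adam)
# ---------------------------------------------------------------------------

class _Adam:
    """Adam on the flat parameter vector (published defaults beta1=0.9,
    beta2=0.999, eps=1e-7)."""

    def __init__(self, params: TSRModelParams, hyper: TSRHyperparams):
        self.lr = hyper.learning_rate
        self.b1, self.b2, self.eps = hyper.adam_beta1, hyper.adam_beta2, hyper.adam_eps
        self.t = 0
        self.m = np.zeros_like(params.flat)
        self.v = np.zeros_like(params.flat)

    def step(self, params: TSRModelParams, grads: TSRModelParams) -> None:
        self.t += 1
        g = grads.flat
        self.m *= self.b1
        self.m += (1.0 - self.b1) * g
        self.v *= self.b2
        self.v += (1.0 - self.b2) * g * g
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        params.flat -= self.lr * (self.m / bc1) / (np.sqrt(self.v / bc2) + self.eps)


def train(patients: Sequence[PatientSeries] | PaddedBatch, schema: StreamSchema,
          hyper: TSRHyperparams, seed: int):
    """Train on already-standardized series: full-batch Adam on BCE for
    ``hyper.epochs`` updates, dropout active. Deterministic given seed.

    Returns ``(params, loss_history)`` where loss_history is the per-epoch
    inference-mode (dropout-free) BCE before each update.
    """
    batch = patients if isinstance(patients, PaddedBatch) \
        else pad_and_mask(list(patients), schema)
    labels = set(batch.labels.tolist())
    if labels != {0, 1}:
        raise TrainingError(
            f"training set must contain both classes, got labels {sorted(labels)}"
        )
    rng = np.random.default_rng(seed)
    params = init_params(schema, hyper, seed=int(rng.integers(2 ** 31)))
    opt = _Adam(params, hyper)
    keep = 1.0 - hyper.dropout_rate
    total_h = sum(params.hidden)
    n = batch.mask.shape[0]
    losses = np.empty(hyper.epochs)
    for epoch in range(hyper.epochs):
        if hyper.dropout_rate > 0:
            d_mask = (rng.random((n, total_h)) < keep).astype(float)
        else:
            d_mask = None
        _, grads, h_cat = bce_gradients(params, batch, hyper, dropout_mask=d_mask)
        eval_probs = _sigmoid(h_cat @ params.head_w + params.head_b)
        losses[epoch] = bce_loss(eval_probs, batch.labels)
        opt.step(params, grads)
    return params, losses


def train_ensemble(patients: Sequence[PatientSeries] | PaddedBatch,
                   schema: StreamSchema, hyper: TSRHyperparams,
                   seeds: Sequence[int]) -> list[TSRModelParams]:
    """Train M independent models on the same batch, one per seed.

    Numerically this mirrors calling :func:`train` once per seed (identical
    initialisation and dropout draws; the only difference is that the M
    models' linear algebra runs through batched GEMMs), and a regression test
    holds the two paths together. Exists because repeat-averaged LOOCV
    retrains the same fold M times.
    """
    batch = patients if isinstance(patients, PaddedBatch) \
        else pad_and_mask(list(patients), schema)
    if set(batch.labels.tolist()) != {0, 1}:
        raise TrainingError("training set must contain both classes")
    m_models = len(seeds)
    if m_models == 0:
        return []
    tied = hyper.tied_input_forget_recurrence
    rngs = [np.random.default_rng(s) for s in seeds]
    protos = [init_params(schema, hyper, seed=int(r.integers(2 ** 31))) for r in rngs]
    hidden = protos[0].hidden
    flat = np.stack([p.flat for p in protos])            # M x P
    n, t_max = batch.mask.shape
    total_h = sum(hidden)
    keep = 1.0 - hyper.dropout_rate
    y = batch.labels.astype(float)

    # stacked views into flat, mirroring TSRModelParams layout
    kernels, recurrents, biases = [], [], []
    off = 0
    for d_k, h_k in zip(schema.widths, hidden):
        kernels.append(flat[:, off : off + d_k * 4 * h_k].reshape(m_models, d_k, 4 * h_k))
        off += d_k * 4 * h_k
        recurrents.append(
            flat[:, off : off + 4 * h_k * h_k].reshape(m_models, h_k, 4 * h_k))
        off += 4 * h_k * h_k
        biases.append(flat[:, off : off + 4 * h_k])
        off += 4 * h_k
    head_w = flat[:, off : off + total_h]
    off += total_h
    head_b = flat[:, off]

    x_flats = [
        np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(t_max * n, -1)
        for x in batch.streams
    ]
    mf = np.ascontiguousarray(batch.mask.T)[None, :, :, None]   # 1 x T x N x 1
    inv_mf = 1.0 - mf
    pad_rows = [np.flatnonzero(batch.mask[:, t] == 0) for t in range(t_max)]

    g_flat = np.empty_like(flat)
    g_kernels, g_recurrents, g_biases = [], [], []
    off = 0
    for d_k, h_k in zip(schema.widths, hidden):
        g_kernels.append(g_flat[:, off : off + d_k * 4 * h_k].reshape(m_models, d_k, 4 * h_k))
        off += d_k * 4 * h_k
        g_recurrents.append(
            g_flat[:, off : off + 4 * h_k * h_k].reshape(m_models, h_k, 4 * h_k))
        off += 4 * h_k * h_k
        g_biases.append(g_flat[:, off : off + 4 * h_k])
        off += 4 * h_k
    g_head_w = g_flat[:, off : off + total_h]
    g_head_b = g_flat[:, off + total_h]

    adam_m = np.zeros_like(flat)
    adam_v = np.zeros_like(flat)
    b1, b2, eps = hyper.adam_beta1, hyper.adam_beta2, hyper.adam_eps

    for epoch in range(hyper.epochs):
        finals, caches = [], []
        for k in range(schema.n_streams):
            h_k = hidden[k]
            z_all = (x_flats[k][None] @ kernels[k] + biases[k][:, None, :]) \
                .reshape(m_models, t_max, n, 4 * h_k)
            tc_all = np.empty((m_models, t_max, n, h_k))
            hp_all = np.empty((m_models, t_max, n, h_k))
            cp_all = np.empty((m_models, t_max, n, h_k))
            u_eff = recurrents[k]
            if tied:
                u_eff = u_eff.copy()
                u_eff[:, :, 0:h_k] = u_eff[:, :, h_k : 2 * h_k]
            h = np.zeros((m_models, n, h_k))
            c = np.zeros((m_models, n, h_k))
            for t in range(t_max):
                z = z_all[:, t]
                z += h @ u_eff
                zs = z[:, :, : 3 * h_k]
                np.negative(zs, out=zs)
                np.exp(zs, out=zs)
                zs += 1.0
                np.reciprocal(zs, out=zs)
                cand = z[:, :, 3 * h_k :]
                np.tanh(cand, out=cand)
                hp_all[:, t] = h
                cp_all[:, t] = c
                c_new = z[:, :, h_k : 2 * h_k] * c
                c_new += z[:, :, 0 * h_k : 1 * h_k] * cand
                tc = tc_all[:, t]
                np.tanh(c_new, out=tc)
                h_new = z[:, :, 2 * h_k : 3 * h_k] * tc
                pad = pad_rows[t]
                if pad.size:
                    h_new[:, pad] = h[:, pad]
                    c_new[:, pad] = c[:, pad]
                h, c = h_new, c_new
            finals.append(h)
            caches.append((z_all, tc_all, hp_all, cp_all, u_eff))
        h_cat = np.concatenate(finals, axis=2)              # M x N x sumH

        if hyper.dropout_rate > 0:
            d_mask = np.stack(
                [(r.random((n, total_h)) < keep).astype(float) for r in rngs])
            h_drop = h_cat * d_mask / keep
        else:
            d_mask = None
            h_drop = h_cat
        logits = np.einsum("mnh,mh->mn", h_drop, head_w) + head_b[:, None]
        probs = 1.0 / (1.0 + np.exp(-logits))

        d_logit = (probs - y[None]) / n
        g_head_w[:] = np.einsum("mn,mnh->mh", d_logit, h_drop)
        g_head_b[:] = d_logit.sum(axis=1)
        dh_cat = d_logit[:, :, None] * head_w[:, None, :]
        if d_mask is not None:
            dh_cat *= d_mask
            dh_cat /= keep

        col = 0
        for k in range(schema.n_streams):
            h_k = hidden[k]
            z_all, tc_all, hp_all, cp_all, u_eff = caches[k]
            dh = dh_cat[:, :, col : col + h_k].copy()
            col += h_k
            dc = np.zeros_like(dh)
            dz_all = np.empty((m_models, t_max, n, 4 * h_k))
            u_eff_t = np.ascontiguousarray(u_eff.transpose(0, 2, 1))
            for t in range(t_max - 1, -1, -1):
                z = z_all[:, t]
                ig = z[:, :, 0 * h_k : 1 * h_k]
                fg = z[:, :, 1 * h_k : 2 * h_k]
                og = z[:, :, 2 * h_k : 3 * h_k]
                cand = z[:, :, 3 * h_k :]
                tc = tc_all[:, t]
                m, im = mf[0, t], inv_mf[0, t]
                dh_eff = dh * m
                d_og = dh_eff * tc
                dct = dc * m
                dct += dh_eff * og * (1.0 - tc * tc)
                dz = dz_all[:, t]
                dz[:, :, 0 * h_k : 1 * h_k] = (dct * cand) * (ig * (1.0 - ig))
                dz[:, :, 1 * h_k : 2 * h_k] = (dct * cp_all[:, t]) * (fg * (1.0 - fg))
                dz[:, :, 2 * h_k : 3 * h_k] = d_og * (og * (1.0 - og))
                dz[:, :, 3 * h_k :] = (dct * ig) * (1.0 - cand * cand)
                dh *= im
                dh += dz @ u_eff_t
                dc *= im
                dc += dct * fg
            flat_dz = dz_all.reshape(m_models, t_max * n, 4 * h_k)
            g_kernels[k][:] = x_flats[k].T[None] @ flat_dz
            g_recurrents[k][:] = hp_all.reshape(m_models, t_max * n, h_k) \
                .transpose(0, 2, 1) @ flat_dz
            g_biases[k][:] = flat_dz.sum(axis=1)
            if tied:
                g_recurrents[k][:, :, 1 * h_k : 2 * h_k] += \
                    g_recurrents[k][:, :, 0:h_k]
                g_recurrents[k][:, :, 0:h_k] = 0.0

        tt = epoch + 1
        adam_m *= b1
        adam_m += (1.0 - b1) * g_flat
        adam_v *= b2
        adam_v += (1.0 - b2) * g_flat * g_flat
        bc1 = 1.0 - b1 ** tt
        bc2 = 1.0 - b2 ** tt
        flat -= hyper.learning_rate * (adam_m / bc1) / (np.sqrt(adam_v / bc2) + eps)

    return [TSRModelParams(schema, hidden, flat[i].copy()) for i in range(m_models)]


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class TimeSeriesRadiomicsModel:
    """Multistream LSTM progression classifier bound to a cohort.

    Parameters
    ----------
    cohort : the (raw) cohort to model.
    hyper : training hyperparameters; defaults to the tuned operating point.
    standardize : fit a feature standardizer on the cohort before training
        (default). Pass False when the data is already standardized.

    Examples
    --------
    >>> model = TimeSeriesRadiomicsModel(cohort)
    >>> res = model.fit(seed=0)
    >>> res.predict(cohort)           # in-sample probabilities
    """

    def __init__(self, cohort: Cohort, hyper: TSRHyperparams | None = None,
                 standardize: bool = True):
        self.cohort = cohort
        self.hyper = hyper or TSRHyperparams()
        self.standardize = standardize

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "TimeSeriesRadiomicsModel":
        return cls(cohort, **kwargs)

    def fit(self, seed: int = 0) -> "TSRResults":
        scaler = None
        data = self.cohort
        if self.standardize:
            scaler = fit_standardizer(self.cohort, self.cohort.patient_ids)
            data = apply_standardizer(scaler, self.cohort)
        params, losses = train(data.patients, data.schema, self.hyper, seed)
        return TSRResults(model=self, params=params, loss_history=losses,
                          scaler=scaler, seed=seed)


@dataclass
class TSRResults:
    """Fitted multistream LSTM: final weights, per-epoch training loss, and
    the standardizer (if fitted) needed to score new patients."""

    model: TimeSeriesRadiomicsModel
    params: TSRModelParams
    loss_history: np.ndarray
    scaler: StandardizationParams | None
    seed: int

    def predict(self, data: Cohort | Sequence[PatientSeries]) -> np.ndarray:
        """Progression probabilities for a cohort or list of patients
        (standardized with the training-time scaler when one was fitted)."""
        patients = data.patients if isinstance(data, Cohort) else list(data)
        if self.scaler is not None:
            patients = [apply_standardizer(self.scaler, p) for p in patients]
        batch = pad_and_mask(patients, self.params.schema)
        return forward(batch, self.params, self.model.hyper, training=False)

    def summary(self) -> str:
        from .evaluation import roc_auc  # deferred: evaluation imports this module

        probs = self.predict(self.model.cohort)
        labels = self.model.cohort.labels
        auc = roc_auc(probs, labels)
        h = self.model.hyper
        lines = [
            "Time Series Radiomics LSTM — fit summary",
            "=" * 44,
            f"patients: {len(self.model.cohort)} "
            f"({int(labels.sum())} progressors / {int((1 - labels).sum())} non-progressors)",
            f"streams:  {self.params.schema.stream_names} widths {self.params.schema.widths}",
            f"hidden units/stream: {self.params.hidden}",
            f"epochs {h.epochs}, lr {h.learning_rate}, dropout {h.dropout_rate}",
            f"final training BCE: {self.loss_history[-1]:.4f}",
            f"in-sample AUC: {auc.auc:.3f} [95% CI {auc.ci_low:.3f}-{auc.ci_high:.3f}]",
        ]
        return "\n".join(lines)
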