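"""The neural parenting-style assessment network.

Architecture (forward order): a user's post-embedding sequence
``{emb_1..emb_n}`` feeds a two-layer LSTM producing hidden states
``H ∈ R^{n×d_h}``; a per-post scalar attention score ``e_i =
tanh(h_i·W1 + b1)`` pools the sequence into ``H' = Att^T H``; the
correlation-injection layer concatenates ``H'`` with six constant
lexicon representations (mean word embeddings of the style-correlated
word sets T_p, E_p, T_m, E_m, T_n, E_n, in that fixed order) into
``C ∈ R^{1×(d_h+6 d_w)}``; finally two fully-connected tanh layers map
``C`` to the three normalized parenting scores in (-1, 1)^3.

With the published widths (d_h = d_w = 300) the concatenation is
2100-wide and the head is 2100→128→3.

Everything is implemented in NumPy with hand-derived analytic gradients
(finite-difference-checked in the test suite); batched sequences of
unequal length are right-padded and masked, and masked steps are
excluded from attention and mean pooling.

Two ablations mirror the architecture study: ``no_attention`` replaces
attention pooling with a masked mean over the hidden states, and
``no_injection`` feeds the head ``H'`` alone.

Design notes: the attention scores are raw tanh outputs exactly as the
model computes them (they may be negative and do not sum to one); the
sum-to-one weights shown in case studies are a display-layer softmax
applied by :func:`attention_report`, not part of the model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .embu_scoring import Post
from .embedding import EmbeddedSequence

__all__ = [
    "ModelConfig",
    "ForwardTrace",
    "init_params",
    "forward",
    "forward_batch",
    "loss_and_grads",
    "mse_loss",
    "attention_report",
    "make_ablation",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATIONS = ("full", "no_attention", "no_injection")
N_SETS = 6  # correlation word sets, concatenated in the fixed canonical order


@dataclass(frozen=True)
class ModelConfig:
    """Widths and variant of the assessment network.

    d_e: post-embedding input width; d_h: LSTM hidden width (300 in the
    published configuration); d_w: width of each injected set
    representation (300); d_u: head hidden width (128); ablation: one of
    ``full``, ``no_attention``, ``no_injection``; seed fixes the
    parameter initialization.
    """

    d_e: int = 384
    d_h: int = 300
    d_w: int = 300
    d_u: int = 128
    ablation: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_e", "d_h", "d_w", "d_u"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")

    @property
    def inject(self) -> bool:
        return self.ablation != "no_injection"

    @property
    def concat_width(self) -> int:
        return self.d_h + N_SETS * self.d_w if self.inject else self.d_h


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    """Seeded parameter initialization.

    All weights uniform in ±1/sqrt(fan_in); biases zero except the LSTM
    forget gates, initialized to 1 (standard long-memory-at-start
    choice).  Identical seeds give bitwise-identical parameters.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    H = config.d_h

    def uni(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    params: dict[str, np.ndarray] = {}
    for layer, d_in in (("lstm1", config.d_e), ("lstm2", H)):
        params[f"{layer}_W"] = uni(d_in, (d_in, 4 * H))
        params[f"{layer}_U"] = uni(H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget gate
        params[f"{layer}_b"] = b
    params["W1"] = uni(H, (H, 1))
    params["b1"] = np.zeros(1)
    params["W2"] = uni(config.concat_width, (config.concat_width, config.d_u))
    params["b2"] = np.zeros(config.d_u)
    params["W3"] = uni(config.d_u, (config.d_u, 3))
    params["b3"] = np.zeros(3)
    return params


# -- LSTM layer (batched, masked) -------------------------------------------


def _lstm_forward(X, mask, W, U, b):
    """One LSTM layer over right-padded input X (B,n,d_in), mask (B,n).

    Masked steps carry h and c through unchanged.  Returns the hidden
    sequence (B,n,H) and a cache for backward.
    """
    B, n, _ = X.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, n, H))
    steps = []
    for t in range(n):
        h_prev, c_prev = h, c
        z = X[:, t] @ W + h_prev @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c_prev + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t : t + 1]
        h = m * h_new + (1.0 - m) * h_prev
        c = m * c_new + (1.0 - m) * c_prev
        Hs[:, t] = h
        steps.append((i, f, g, o, tc, h_prev, c_prev))
    return Hs, (X, mask, W, U, steps)


def _lstm_backward(dHs, cache):
    """Backward through one masked LSTM layer; returns (dX, dW, dU, db)."""
    X, mask, W, U, steps = cache
    B, n, d_in = X.shape
    H = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dX = np.zeros_like(X)
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    for t in range(n - 1, -1, -1):
        i, f, g, o, tc, h_prev, c_prev = steps[t]
        m = mask[:, t : t + 1]
        dh = dHs[:, t] + dh_carry
        dc = dc_carry
        dh_new = m * dh
        dc_new = m * dc
        dh_prev = (1.0 - m) * dh  # carry path for padded steps
        dc_prev = (1.0 - m) * dc
        # h_new = o * tanh(c_new)
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dc_prev = dc_prev + dc_new * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += X[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ W.T
        dh_carry = dh_prev + dz @ U.T
        dc_carry = dc_prev
    return dX, dW, dU, db


# -- full network -----------------------------------------------------------


def _check_widths(X: np.ndarray, reps: np.ndarray | None, config: ModelConfig):
    if X.shape[-1] != config.d_e:
        raise ValueError(
            f"embedding stage: input width {X.shape[-1]} != config.d_e {config.d_e}"
        )
    if config.inject:
        if reps is None:
            raise ValueError("correlation injection stage: set representations missing")
        reps = np.asarray(reps, dtype=float).ravel()
        if reps.shape[0] != N_SETS * config.d_w:
            raise ValueError(
                "correlation injection stage: stacked representations width "
                f"{reps.shape[0]} != 6*d_w = {N_SETS * config.d_w}"
            )
        return reps
    return None


def forward_batch(
    params: Mapping[str, np.ndarray],
    X: np.ndarray,
    mask: np.ndarray,
    reps: np.ndarray | None,
    config: ModelConfig,
):
    """Batched forward pass.

    X: (B, n, d_e) right-padded post embeddings; mask: (B, n) with 1 for
    real posts; reps: stacked (6*d_w,) set representations (ignored under
    ``no_injection``).  Returns (Y, cache) with Y (B, 3) in (-1, 1).
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=float)
    reps = _check_widths(X, reps, config)
    B, n, _ = X.shape

    H1, cache1 = _lstm_forward(X, mask, params["lstm1_W"], params["lstm1_U"], params["lstm1_b"])
    H2, cache2 = _lstm_forward(H1, mask, params["lstm2_W"], params["lstm2_U"], params["lstm2_b"])

    if config.ablation == "no_attention":
        counts = mask.sum(axis=1, keepdims=True)
        pooled = (H2 * mask[:, :, None]).sum(axis=1) / counts
        att = None
    else:
        scores = np.einsum("bth,ho->bt", H2, params["W1"]) + params["b1"][0]
        att = np.tanh(scores)
        att_m = att * mask
        pooled = np.einsum("bt,bth->bh", att_m, H2)

    if config.inject:
        C = np.concatenate([pooled, np.tile(reps, (B, 1))], axis=1)
    else:
        C = pooled
    Uh = np.tanh(C @ params["W2"] + params["b2"])
    Y = np.tanh(Uh @ params["W3"] + params["b3"])
    cache = (X, mask, reps, cache1, cache2, H2, att, pooled, C, Uh, Y)
    return Y, cache


def backward_batch(
    params: Mapping[str, np.ndarray],
    dY: np.ndarray,
    cache,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Analytic gradients of a scalar loss given dL/dY."""
    X, mask, reps, cache1, cache2, H2, att, pooled, C, Uh, Y = cache
    grads: dict[str, np.ndarray] = {}

    dZ3 = dY * (1.0 - Y * Y)
    grads["W3"] = Uh.T @ dZ3
    grads["b3"] = dZ3.sum(axis=0)
    dUh = dZ3 @ params["W3"].T
    dZ2 = dUh * (1.0 - Uh * Uh)
    grads["W2"] = C.T @ dZ2
    grads["b2"] = dZ2.sum(axis=0)
    dC = dZ2 @ params["W2"].T
    dPooled = dC[:, : config.d_h]

    if config.ablation == "no_attention":
        counts = mask.sum(axis=1, keepdims=True)
        dH2 = dPooled[:, None, :] * (mask / counts)[:, :, None]
        grads["W1"] = np.zeros_like(params["W1"])
        grads["b1"] = np.zeros_like(params["b1"])
    else:
        att_m = att * mask
        dAtt_m = np.einsum("bh,bth->bt", dPooled, H2)
        dH2 = att_m[:, :, None] * dPooled[:, None, :]
        dScores = dAtt_m * (1.0 - att * att) * mask
        grads["W1"] = np.einsum("bth,bt->h", H2, dScores)[:, None]
        grads["b1"] = np.array([dScores.sum()])
        dH2 = dH2 + dScores[:, :, None] * params["W1"][:, 0][None, None, :]

    dH1, dW2l, dU2l, db2l = _lstm_backward(dH2, cache2)
    grads["lstm2_W"], grads["lstm2_U"], grads["lstm2_b"] = dW2l, dU2l, db2l
    _, dW1l, dU1l, db1l = _lstm_backward(dH1, cache1)
    grads["lstm1_W"], grads["lstm1_U"], grads["lstm1_b"] = dW1l, dU1l, db1l
    return grads


def mse_loss(Y: np.ndarray, T: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient w.r.t. Y."""
    diff = Y - T
    loss = float(np.mean(diff * diff))
    dY = 2.0 * diff / diff.size
    return loss, dY


def loss_and_grads(
    params: Mapping[str, np.ndarray],
    X: np.ndarray,
    mask: np.ndarray,
    reps: np.ndarray | None,
    T: np.ndarray,
    config: ModelConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE training loss on normalized labels T (B, 3) plus gradients."""
    Y, cache = forward_batch(params, X, mask, reps, config)
    loss, dY = mse_loss(Y, T)
    return loss, backward_batch(params, dY, cache, config)


# -- single-user API --------------------------------------------------------


@dataclass
class ForwardTrace:
    """Intermediate states of one user's forward pass."""

    hidden: np.ndarray       # (n, d_h) LSTM-2 output sequence H
    attention: np.ndarray    # (n,) raw tanh attention scores e_i (empty if ablated)
    pooled: np.ndarray       # (d_h,) H'
    concat: np.ndarray       # (concat_width,) C
    head_hidden: np.ndarray  # (d_u,) U
    scores: np.ndarray       # (3,) normalized predictions in (-1, 1)


def forward(
    emb_seq: EmbeddedSequence,
    reps: np.ndarray | None,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> ForwardTrace:
    """Run the network on one user's embedded post sequence."""
    X = emb_seq.matrix[None, :, :]
    mask = np.ones((1, X.shape[1]))
    Y, cache = forward_batch(params, X, mask, reps, config)
    _, _, _, _, _, H2, att, pooled, C, Uh, _ = cache
    return ForwardTrace(
        hidden=H2[0],
        attention=att[0] if att is not None else np.empty(0),
        pooled=pooled[0],
        concat=C[0],
        head_hidden=Uh[0],
        scores=Y[0],
    )


def attention_report(
    posts: Sequence[Post], trace: ForwardTrace
) -> list[dict[str, object]]:
    """Rank posts by display attention weight.

    Raw scores e_i are the model's tanh outputs; the displayed weights
    are their softmax (non-negative, summing to one).  Returns a list of
    dicts (rank, post text, raw score, weight) sorted by weight
    descending.
    """
    e = np.asarray(trace.attention, dtype=float)
    if e.size != len(posts):
        raise ValueError(
            f"attention length {e.size} does not match {len(posts)} posts"
        )
    ex = np.exp(e - e.max())
    w = ex / ex.sum()
    order = np.argsort(-w, kind="stable")
    return [
        {
            "rank": r + 1,
            "post": posts[i].text,
            "raw_score": float(e[i]),
            "weight": float(w[i]),
        }
        for r, i in enumerate(order)
    ]


def make_ablation(config: ModelConfig, which: str) -> ModelConfig:
    """Derive an ablated configuration (``no_attention`` or ``no_injection``)."""
    if which not in ("no_attention", "no_injection"):
        raise ValueError(
            f"unknown ablation {which!r}: expected 'no_attention' or 'no_injection'"
        )
    return dataclasses.replace(config, ablation=which)


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path: str, params: Mapping[str, np.ndarray], config: ModelConfig) -> None:
    """Single-file archive: config header + named parameter blocks."""
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(dataclasses.asdict(config)).encode("utf-8"), dtype=np.uint8
        ),
        **{k: np.asarray(v) for k, v in params.items()},
    )


def load_checkpoint(path: str) -> tuple[dict[str, np.ndarray], ModelConfig]:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode("utf-8")))
        params = {k: data[k] for k in data.files if k != "__config__"}
    return params, cfg
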