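"""Two-layer LSTM with time-dimension attention for sequence classification.

The model consumes variable-length frame-feature sequences and predicts a
binary label (healthy control vs. depression).  A two-layer forget-gate
LSTM encodes the sequence; its last valid hidden state acts as the query
of a time-dimension attention mechanism over the full hidden-state
sequence, and the resulting context vector feeds a small fully connected
classifier.

Three attention variants are supported:

* ``none`` — plain LSTM; the classifier sees the last hidden state.
* ``single`` — single-head time attention:
  ``s = softmax(o_last (o_all W_t)^H)``, ``context = s o_all``.
* ``multi`` — n-head attention: per head, ``o_all`` is projected to keys
  K_i and values V_i of width Z/n and ``o_last`` to the query Q_i;
  ``s_i = softmax(Q_i K_i^H)``, ``context_i = s_i V_i``, and the context
  vectors are concatenated back to width Z.  The attention logits are
  unscaled by default; ``scale_scores`` enables the 1/sqrt(Z/n)
  convention.

Softmax is always masked to the valid time steps, so padding carries
exactly zero attention.  Everything runs in NumPy with analytic gradients
(see :mod:`attnspeech.nn`); determinism is controlled by a single seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .nn import (
    Adam,
    clip_global_norm,
    glorot_uniform,
    linear_init,
    lstm_layer_backward,
    lstm_layer_forward,
    lstm_layer_init,
    masked_softmax,
)

__all__ = [
    "SequenceBatch",
    "pad_sequences",
    "ModelConfig",
    "LSTMOutputs",
    "AttentionResult",
    "lstm_forward",
    "single_head_time_attention",
    "project_heads",
    "multi_head_time_attention",
    "classify",
    "model_forward",
    "AttentionLSTMClassifier",
    "attention_mass_in_window",
]


# ---------------------------------------------------------------------------
# batch container


@dataclass(frozen=True)
class SequenceBatch:
    """Padded batch of sequences: features (B, T_max, Z), true lengths, labels."""

    features: np.ndarray
    lengths: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.float64)
        lengths = np.asarray(self.lengths, dtype=np.int64)
        if feats.ndim != 3:
            raise ValueError(f"features must be (B, T, Z), got shape {feats.shape}")
        if lengths.shape != (feats.shape[0],):
            raise ValueError("lengths must have one entry per sequence")
        if lengths.min() < 1 or lengths.max() > feats.shape[1]:
            raise ValueError("lengths must lie in [1, T_max]")
        for b, ln in enumerate(lengths):
            if not np.all(feats[b, ln:] == 0):
                raise ValueError(f"sequence {b}: padded positions must be zero")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (feats.shape[0],):
                raise ValueError("labels must have one entry per sequence")
            object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "lengths", lengths)

    @property
    def batch_size(self) -> int:
        return self.features.shape[0]

    @property
    def t_max(self) -> int:
        return self.features.shape[1]

    @property
    def z(self) -> int:
        return self.features.shape[2]

    def time_mask(self) -> np.ndarray:
        """(B, T) float mask: 1 at valid steps, 0 at padding."""
        return (np.arange(self.t_max)[None, :] < self.lengths[:, None]).astype(float)


def pad_sequences(
    sequences: Sequence[np.ndarray], labels: Sequence[int] | None = None
) -> SequenceBatch:
    """Zero-pad variable-length (T_i, Z) arrays into one SequenceBatch."""
    if not sequences:
        raise ValueError("cannot build a batch from zero sequences")
    z = sequences[0].shape[1]
    lengths = np.array([s.shape[0] for s in sequences], dtype=np.int64)
    t_max = int(lengths.max())
    feats = np.zeros((len(sequences), t_max, z))
    for i, s in enumerate(sequences):
        if s.shape[1] != z:
            raise ValueError(f"sequence {i} has {s.shape[1]} features, expected {z}")
        feats[i, : s.shape[0]] = s
    return SequenceBatch(feats, lengths, None if labels is None else np.asarray(labels))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings.

    Defaults follow the reference configuration for corpus-scale studies:
    LSTM hidden sizes [512, 256], fully connected sizes [128, 12], 2-way
    softmax output, Adam at learning rate 1e-4, batch size 64.  Smaller
    hidden sizes are appropriate for the synthetic studies shipped with
    the package.
    """

    input_size: int
    lstm_hidden: tuple[int, int] = (512, 256)
    heads: int = 4
    fc_sizes: tuple[int, ...] = (128, 12)
    n_classes: int = 2
    lr: float = 1e-4
    batch: int = 64
    scale_scores: bool = False
    attention: Literal["none", "single", "multi"] = "multi"
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("this classifier is binary: n_classes must be 2")
        if self.attention == "multi" and self.lstm_hidden[-1] % self.heads:
            raise ValueError(
                f"last LSTM hidden size {self.lstm_hidden[-1]} is not divisible "
                f"by {self.heads} attention heads"
            )
        if len(self.lstm_hidden) != 2:
            raise ValueError("the backbone is a two-layer LSTM: give two hidden sizes")

    @property
    def z_out(self) -> int:
        return self.lstm_hidden[-1]

    @property
    def head_width(self) -> int:
        return self.z_out // self.heads


# ---------------------------------------------------------------------------
# forward operations


@dataclass(frozen=True)
class LSTMOutputs:
    """o_all: (B, T, Z_out) full hidden sequence; o_last: (B, 1, Z_out)
    hidden state at each sequence's last *valid* step."""

    o_all: np.ndarray
    o_last: np.ndarray


@dataclass(frozen=True)
class AttentionResult:
    """Per-head attention scores (n, B, 1, T) and context vector (B, 1, Z)."""

    scores: np.ndarray
    context: np.ndarray


def _last_valid(o_all: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    return o_all[np.arange(o_all.shape[0]), lengths - 1][:, None, :]


def lstm_forward(batch: SequenceBatch, params: dict[str, np.ndarray]) -> LSTMOutputs:
    """Two stacked forget-gate LSTM layers over a padded batch."""
    mask = batch.time_mask()
    h1, _ = lstm_layer_forward(batch.features, mask, _layer(params, "lstm0"))
    h2, _ = lstm_layer_forward(h1, mask, _layer(params, "lstm1"))
    return LSTMOutputs(o_all=h2, o_last=_last_valid(h2, batch.lengths))


def _layer(params: dict[str, np.ndarray], prefix: str) -> dict[str, np.ndarray]:
    return {k.split("/", 1)[1]: v for k, v in params.items() if k.startswith(prefix + "/")}


def single_head_time_attention(
    o: LSTMOutputs, w_t: np.ndarray, lengths: np.ndarray
) -> AttentionResult:
    """Single-head time attention: s = softmax(o_last (o_all W_t)^H)."""
    z = o.o_all.shape[2]
    if w_t.shape != (z, z):
        raise ValueError(f"W_t must be ({z}, {z}), got {w_t.shape}")
    mask = (np.arange(o.o_all.shape[1])[None, :] < lengths[:, None]).astype(float)
    proj = o.o_all @ w_t
    logits = np.einsum("bz,btz->bt", o.o_last[:, 0, :], proj)
    s = masked_softmax(logits, mask)
    context = np.einsum("bt,btz->bz", s, o.o_all)[:, None, :]
    return AttentionResult(scores=s[None, :, None, :], context=context)


def project_heads(
    o: LSTMOutputs, projections: Sequence[dict[str, np.ndarray]]
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-head (K_i, V_i, Q_i): affine maps of o_all (keys, values) and
    o_last (query) into the head subspace of width Z/n."""
    z = o.o_all.shape[2]
    if z % len(projections):
        raise ValueError(f"hidden width {z} not divisible by {len(projections)} heads")
    out = []
    for proj in projections:
        k = o.o_all @ proj["wk"] + proj["bk"]
        v = o.o_all @ proj["wv"] + proj["bv"]
        q = o.o_last[:, 0, :] @ proj["wq"] + proj["bq"]
        out.append((k, v, q))
    return out


def multi_head_time_attention(
    kvq: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    lengths: np.ndarray,
    scale_scores: bool = False,
) -> AttentionResult:
    """n-head time attention: s_i = softmax(Q_i K_i^H), context_i = s_i V_i,
    CV = concat(context_1..context_n).  Logits are unscaled unless
    ``scale_scores`` requests the 1/sqrt(Z/n) convention."""
    t_len = kvq[0][0].shape[1]
    mask = (np.arange(t_len)[None, :] < lengths[:, None]).astype(float)
    scores = []
    contexts = []
    for k, v, q in kvq:
        alpha = 1.0 / np.sqrt(k.shape[2]) if scale_scores else 1.0
        logits = np.einsum("bd,btd->bt", q, k) * alpha
        s = masked_softmax(logits, mask)
        scores.append(s[:, None, :])
        contexts.append(np.einsum("bt,btd->bd", s, v))
    return AttentionResult(
        scores=np.stack(scores, axis=0),
        context=np.concatenate(contexts, axis=1)[:, None, :],
    )


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def classify(cv: np.ndarray, params: dict[str, np.ndarray], n_fc: int = 2) -> np.ndarray:
    """Fully connected head + 2-way softmax; rows sum to 1."""
    h = cv[:, 0, :] if cv.ndim == 3 else cv
    for i in range(n_fc):
        h = _relu(h @ params[f"fc{i}/w"] + params[f"fc{i}/b"])
    logits = h @ params["out/w"] + params["out/b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def model_forward(
    batch: SequenceBatch, params: dict[str, np.ndarray], cfg: ModelConfig
) -> tuple[np.ndarray, AttentionResult | None]:
    """Full composition: LSTM -> (attention) -> classifier."""
    o = lstm_forward(batch, params)
    if cfg.attention == "none":
        return classify(o.o_last, params, len(cfg.fc_sizes)), None
    if cfg.attention == "single":
        att = single_head_time_attention(o, params["att/wt"], batch.lengths)
    else:
        projections = [_layer(params, f"head{i}") for i in range(cfg.heads)]
        att = multi_head_time_attention(
            project_heads(o, projections), batch.lengths, cfg.scale_scores
        )
    return classify(att.context, params, len(cfg.fc_sizes)), att


# ---------------------------------------------------------------------------
# trainable classifier


class AttentionLSTMClassifier:
    """Seed-reproducible NumPy implementation of the attention LSTM.

    Holds the parameter dict, exposes forward prediction, cross-entropy
    loss with analytic gradients, and an Adam training step.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params = self._init_params(rng)
        self.optimizer = Adam(lr=cfg.lr)

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.cfg
        params: dict[str, np.ndarray] = {}
        sizes = [cfg.input_size, *cfg.lstm_hidden]
        for layer in range(2):
            for key, val in lstm_layer_init(rng, sizes[layer], sizes[layer + 1]).items():
                params[f"lstm{layer}/{key}"] = val
        z = cfg.z_out
        if cfg.attention == "single":
            params["att/wt"] = glorot_uniform(rng, z, z)
        elif cfg.attention == "multi":
            d = cfg.head_width
            for i in range(cfg.heads):
                for name in ("wk", "wv", "wq"):
                    params[f"head{i}/{name}"] = glorot_uniform(rng, z, d)
                for name in ("bk", "bv", "bq"):
                    params[f"head{i}/{name}"] = np.zeros(d)
        fan_in = z
        for i, width in enumerate(cfg.fc_sizes):
            lin = linear_init(rng, fan_in, width)
            params[f"fc{i}/w"], params[f"fc{i}/b"] = lin["w"], lin["b"]
            fan_in = width
        lin = linear_init(rng, fan_in, cfg.n_classes)
        params["out/w"], params["out/b"] = lin["w"], lin["b"]
        return params

    # -- forward -----------------------------------------------------------

    def forward(self, batch: SequenceBatch) -> tuple[np.ndarray, AttentionResult | None]:
        return model_forward(batch, self.params, self.cfg)

    def predict(self, batch: SequenceBatch) -> np.ndarray:
        probs, _ = self.forward(batch)
        return probs.argmax(axis=1)

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, batch: SequenceBatch) -> tuple[float, dict[str, np.ndarray]]:
        if batch.labels is None:
            raise ValueError("training requires labeled batches")
        cfg, params = self.cfg, self.params
        mask = batch.time_mask()
        b_sz = batch.batch_size

        h1, cache1 = lstm_layer_forward(batch.features, mask, _layer(params, "lstm0"))
        o_all, cache2 = lstm_layer_forward(h1, mask, _layer(params, "lstm1"))
        o_last = o_all[np.arange(b_sz), batch.lengths - 1]  # (B, Z)

        head_cache: list[dict] = []
        if cfg.attention == "none":
            cv = o_last
        elif cfg.attention == "single":
            proj = o_all @ params["att/wt"]
            logits = np.einsum("bz,btz->bt", o_last, proj)
            s = masked_softmax(logits, mask)
            cv = np.einsum("bt,btz->bz", s, o_all)
            head_cache.append({"proj": proj, "s": s})
        else:
            contexts = []
            for i in range(cfg.heads):
                hp = _layer(params, f"head{i}")
                k = o_all @ hp["wk"] + hp["bk"]
                v = o_all @ hp["wv"] + hp["bv"]
                q = o_last @ hp["wq"] + hp["bq"]
                alpha = 1.0 / np.sqrt(k.shape[2]) if cfg.scale_scores else 1.0
                s = masked_softmax(np.einsum("bd,btd->bt", q, k) * alpha, mask)
                contexts.append(np.einsum("bt,btd->bd", s, v))
                head_cache.append({"k": k, "v": v, "q": q, "s": s, "alpha": alpha})
            cv = np.concatenate(contexts, axis=1)

        acts = [cv]
        h = cv
        for i in range(len(cfg.fc_sizes)):
            h = _relu(h @ params[f"fc{i}/w"] + params[f"fc{i}/b"])
            acts.append(h)
        logits = h @ params["out/w"] + params["out/b"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(b_sz), batch.labels] + eps)))

        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(b_sz), batch.labels] -= 1.0
        dlogits /= b_sz
        grads["out/w"] = acts[-1].T @ dlogits
        grads["out/b"] = dlogits.sum(axis=0)
        dh = dlogits @ params["out/w"].T
        for i in range(len(cfg.fc_sizes) - 1, -1, -1):
            dh = dh * (acts[i + 1] > 0)
            grads[f"fc{i}/w"] = acts[i].T @ dh
            grads[f"fc{i}/b"] = dh.sum(axis=0)
            dh = dh @ params[f"fc{i}/w"].T
        dcv = dh  # (B, Z)

        d_oall = np.zeros_like(o_all)
        d_olast = np.zeros_like(o_last)
        if cfg.attention == "none":
            d_olast += dcv
        elif cfg.attention == "single":
            s, proj = head_cache[0]["s"], head_cache[0]["proj"]
            ds = np.einsum("bz,btz->bt", dcv, o_all)
            d_oall += s[:, :, None] * dcv[:, None, :]
            dlog = s * (ds - np.sum(ds * s, axis=1, keepdims=True))
            d_olast += np.einsum("bt,btz->bz", dlog, proj)
            dproj = dlog[:, :, None] * o_last[:, None, :]
            grads["att/wt"] = np.einsum("btz,btw->zw", o_all, dproj)
            d_oall += dproj @ params["att/wt"].T
        else:
            d = cfg.head_width
            for i, hc in enumerate(head_cache):
                dctx = dcv[:, i * d: (i + 1) * d]
                k, v, q, s, alpha = hc["k"], hc["v"], hc["q"], hc["s"], hc["alpha"]
                dv = s[:, :, None] * dctx[:, None, :]
                ds = np.einsum("bd,btd->bt", dctx, v)
                dlog = s * (ds - np.sum(ds * s, axis=1, keepdims=True))
                dq = np.einsum("bt,btd->bd", dlog, k) * alpha
                dk = dlog[:, :, None] * q[:, None, :] * alpha
                hp = _layer(params, f"head{i}")
                grads[f"head{i}/wk"] = np.einsum("btz,btd->zd", o_all, dk)
                grads[f"head{i}/bk"] = dk.sum(axis=(0, 1))
                grads[f"head{i}/wv"] = np.einsum("btz,btd->zd", o_all, dv)
                grads[f"head{i}/bv"] = dv.sum(axis=(0, 1))
                grads[f"head{i}/wq"] = o_last.T @ dq
                grads[f"head{i}/bq"] = dq.sum(axis=0)
                d_oall += dk @ hp["wk"].T + dv @ hp["wv"].T
                d_olast += dq @ hp["wq"].T

        d_oall[np.arange(b_sz), batch.lengths - 1] += d_olast
        dh1, g2 = lstm_layer_backward(d_oall, cache2)
        _, g1 = lstm_layer_backward(dh1, cache1)
        for key, val in g2.items():
            grads[f"lstm1/{key}"] = val
        for key, val in g1.items():
            grads[f"lstm0/{key}"] = val
        return loss, grads

    def train_step(self, batch: SequenceBatch) -> float:
        loss, grads = self.loss_and_grads(batch)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged: non-finite loss; lower the learning rate "
                "or check input normalization"
            )
        clip_global_norm(grads, self.cfg.grad_clip)
        self.optimizer.step(self.params, grads)
        return loss

    def state_copy(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.params = copy.deepcopy(state)


def attention_mass_in_window(
    att: AttentionResult,
    spans: Sequence[tuple[int, int]],
    lengths: np.ndarray,
) -> np.ndarray:
    """Fraction of attention mass inside each sequence's salient span.

    Averaged over heads; under uniform attention the expectation equals the
    span's fraction of the valid length, so values above that fraction mean
    the model attends preferentially to the span.
    """
    scores = att.scores  # (n, B, 1, T)
    out = np.zeros(scores.shape[1])
    for b, (start, end) in enumerate(spans):
        out[b] = scores[:, b, 0, start:end].sum(axis=-1).mean()
    return out
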