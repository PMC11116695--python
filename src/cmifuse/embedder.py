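"""Masked-language-model transformer embedding for short RNA sequences.

miRNAs are ~20-22 nt, too short and too uniform in length for profile
similarities to be informative, so they are embedded by a small
bidirectional transformer encoder pretrained with masked language
modeling (MLM) on the input corpus itself: nucleotide tokens are randomly
hidden and the encoder is trained to predict them from both-sided context.
The input representation is the sum of token, segment and position
embeddings over the closed vocabulary {A, C, G, U, CLS, SEP, MASK, PAD};
a sequence's feature vector is the final-layer hidden state at the CLS
position (mean pooling over nucleotide positions is available).

The network is implemented directly in NumPy (multi-head self-attention,
residual + layer normalization, ReLU feed-forward blocks) with
hand-written reverse-mode gradients and Adam, which keeps training fully
deterministic under a seed; gradient correctness is checked against
central differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .attribute import AttributeMatrix
from .data_io import SequenceRecord

PAD, CLS, SEP, MASK = 0, 1, 2, 3
NUC_IDS = {"A": 4, "C": 5, "G": 6, "U": 7}
VOCAB = ["[PAD]", "[CLS]", "[SEP]", "[MASK]", "A", "C", "G", "U"]
VOCAB_SIZE = len(VOCAB)
_IGNORE = -100


class VocabularyError(ValueError):
    """Sequence contains a character outside the fixed vocabulary."""


class TrainingDivergenceError(RuntimeError):
    """Non-finite loss encountered during MLM training."""


@dataclass
class EmbedderConfig:
    """Desk-scale transformer hyperparameters.

    ``hidden`` must divide evenly across ``n_heads``; ``mlm_mask_rate`` is
    the per-token masking probability in (0,1).
    """

    n_layers: int = 2
    hidden: int = 64
    n_heads: int = 4
    mlm_mask_rate: float = 0.15
    max_len: int = 64
    epochs: int = 30
    learning_rate: float = 1e-3
    ffn_mult: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        if not (0.0 < self.mlm_mask_rate < 1.0):
            raise ValueError("mlm_mask_rate must be in (0, 1)")


def tokenize(seq: str, max_len: int | None = None) -> list[int]:
    """[CLS] + one token per nucleotide + [SEP], truncated to max_len.

    Truncation drops trailing nucleotides but always keeps [SEP] as the
    final token.  Single-segment inputs only (segment id 0 throughout).
    """
    try:
        body = [NUC_IDS[ch] for ch in seq]
    except KeyError as exc:
        raise VocabularyError(
            f"character {exc.args[0]!r} outside vocabulary {{A,C,G,U}}"
        ) from None
    if max_len is not None and len(body) > max_len - 2:
        body = body[: max_len - 2]
    return [CLS] + body + [SEP]


# ---------------------------------------------------------------------------
# parameter initialization


def _init_params(cfg: EmbedderConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    h, f = cfg.hidden, cfg.hidden * cfg.ffn_mult

    def w(*shape: int) -> np.ndarray:
        scale = 1.0 / np.sqrt(shape[0])
        return rng.uniform(-scale, scale, size=shape)

    params: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0.0, 0.02, size=(VOCAB_SIZE, h)),
        "pos_emb": rng.normal(0.0, 0.02, size=(cfg.max_len, h)),
        "seg_emb": rng.normal(0.0, 0.02, size=(1, h)),
        "out_W": w(h, VOCAB_SIZE),
        "out_b": np.zeros(VOCAB_SIZE),
    }
    for l in range(cfg.n_layers):
        p = f"l{l}."
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[p + name] = w(h, h)
        for name in ("bq", "bk", "bv", "bo"):
            params[p + name] = np.zeros(h)
        params[p + "W1"] = w(h, f)
        params[p + "b1"] = np.zeros(f)
        params[p + "W2"] = w(f, h)
        params[p + "b2"] = np.zeros(h)
        params[p + "ln1_g"] = np.ones(h)
        params[p + "ln1_b"] = np.zeros(h)
        params[p + "ln2_g"] = np.ones(h)
        params[p + "ln2_b"] = np.zeros(h)
    return params


# ---------------------------------------------------------------------------
# forward / backward primitives

_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    std = np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + _LN_EPS)
    xhat = xc / std
    return g * xhat + b, (xhat, std, g)


def _layernorm_bwd(dy, cache):
    xhat, std, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = (dxhat - m1 - xhat * m2) / std
    return dx, dg, db


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _encoder_forward(params, cfg: EmbedderConfig, ids: np.ndarray):
    """Run the encoder stack; returns final hidden states and caches."""
    B, T = ids.shape
    nh, h = cfg.n_heads, cfg.hidden
    dh = h // nh
    pad_mask = ids == PAD
    attn_bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)  # (B,1,1,T)

    x = params["tok_emb"][ids] + params["pos_emb"][:T][None, :, :] + params["seg_emb"][0]
    caches = []
    for l in range(cfg.n_layers):
        p = f"l{l}."
        q = x @ params[p + "Wq"] + params[p + "bq"]
        k = x @ params[p + "Wk"] + params[p + "bk"]
        v = x @ params[p + "Wv"] + params[p + "bv"]
        # (B,T,H) -> (B,nh,T,dh)
        qh = q.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + attn_bias
        attn = _softmax(scores)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, h)
        proj = ctx @ params[p + "Wo"] + params[p + "bo"]
        y1, ln1_cache = _layernorm_fwd(x + proj, params[p + "ln1_g"], params[p + "ln1_b"])
        h1 = y1 @ params[p + "W1"] + params[p + "b1"]
        a1 = np.maximum(h1, 0.0)
        ffn = a1 @ params[p + "W2"] + params[p + "b2"]
        y2, ln2_cache = _layernorm_fwd(y1 + ffn, params[p + "ln2_g"], params[p + "ln2_b"])
        caches.append((x, qh, kh, vh, attn, ctx, y1, ln1_cache, h1, a1, ln2_cache))
        x = y2
    return x, caches, attn_bias


def _encoder_backward(params, cfg: EmbedderConfig, ids, dx, caches):
    """Backprop dx through the encoder stack; returns parameter grads."""
    B, T = ids.shape
    nh, h = cfg.n_heads, cfg.hidden
    dh = h // nh
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    for l in reversed(range(cfg.n_layers)):
        p = f"l{l}."
        x, qh, kh, vh, attn, ctx, y1, ln1_cache, h1, a1, ln2_cache = caches[l]
        dy2, dg, db = _layernorm_bwd(dx, ln2_cache)
        grads[p + "ln2_g"] += dg
        grads[p + "ln2_b"] += db
        # y2 input = y1 + ffn
        dffn = dy2
        grads[p + "W2"] += a1.reshape(-1, a1.shape[-1]).T @ dffn.reshape(-1, h)
        grads[p + "b2"] += dffn.sum(axis=(0, 1))
        da1 = dffn @ params[p + "W2"].T
        dh1 = da1 * (h1 > 0.0)
        grads[p + "W1"] += y1.reshape(-1, h).T @ dh1.reshape(-1, dh1.shape[-1])
        grads[p + "b1"] += dh1.sum(axis=(0, 1))
        dy1 = dy2 + dh1 @ params[p + "W1"].T
        dy1_in, dg, db = _layernorm_bwd(dy1, ln1_cache)
        grads[p + "ln1_g"] += dg
        grads[p + "ln1_b"] += db
        # y1 input = x + proj
        dproj = dy1_in
        grads[p + "Wo"] += ctx.reshape(-1, h).T @ dproj.reshape(-1, h)
        grads[p + "bo"] += dproj.sum(axis=(0, 1))
        dctx = (dproj @ params[p + "Wo"].T).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dqh = dscores @ kh
        dkh = dscores.transpose(0, 1, 3, 2) @ qh
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, h)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, h)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, h)
        xf = x.reshape(-1, h)
        grads[p + "Wq"] += xf.T @ dq.reshape(-1, h)
        grads[p + "Wk"] += xf.T @ dk.reshape(-1, h)
        grads[p + "Wv"] += xf.T @ dv.reshape(-1, h)
        grads[p + "bq"] += dq.sum(axis=(0, 1))
        grads[p + "bk"] += dk.sum(axis=(0, 1))
        grads[p + "bv"] += dv.sum(axis=(0, 1))
        dx = (
            dy1_in
            + dq @ params[p + "Wq"].T
            + dk @ params[p + "Wk"].T
            + dv @ params[p + "Wv"].T
        )

    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][:T] += dx.sum(axis=0)
    grads["seg_emb"][0] += dx.sum(axis=(0, 1))
    return grads


def _mlm_loss_and_grads(params, cfg: EmbedderConfig, ids, labels):
    """Masked-token cross-entropy and gradients for one batch.

    ``labels`` holds original token ids at masked positions and -100
    elsewhere (ignored by the loss).
    """
    hidden, caches, _ = _encoder_forward(params, cfg, ids)
    logits = hidden @ params["out_W"] + params["out_b"]
    probs = _softmax(logits)
    sel = labels != _IGNORE
    n_masked = int(sel.sum())
    if n_masked == 0:
        raise ValueError("no masked positions in batch")
    picked = probs[sel, labels[sel]]
    loss = -np.log(np.clip(picked, 1e-30, None)).mean()

    dlogits = np.zeros_like(logits)
    dlogits[sel] = probs[sel]
    dlogits[sel, labels[sel]] -= 1.0
    dlogits /= n_masked

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    flat_h = hidden.reshape(-1, cfg.hidden)
    grads["out_W"] = flat_h.T @ dlogits.reshape(-1, VOCAB_SIZE)
    grads["out_b"] = dlogits.sum(axis=(0, 1))
    dhidden = dlogits @ params["out_W"].T
    enc_grads = _encoder_backward(params, cfg, ids, dhidden, caches)
    for k in enc_grads:
        grads[k] += enc_grads[k]
    return loss, grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class SeqEmbedderModel:
    """A trained MLM sequence embedder (config + weights + loss history)."""

    config: EmbedderConfig
    params: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            __history__=np.array(self.loss_history),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SeqEmbedderModel":
        data = np.load(path)
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        config = EmbedderConfig(**cfg_raw)
        params = {k: data[k] for k in data.files if not k.startswith("__")}
        return cls(config=config, params=params,
                   loss_history=list(data["__history__"]))


def _mask_batch(ids, rng, rate):
    """Apply BERT-style corruption; returns (corrupted ids, labels)."""
    corrupted = ids.copy()
    labels = np.full_like(ids, _IGNORE)
    for row in range(ids.shape[0]):
        cand = np.flatnonzero(ids[row] >= 4)  # nucleotide positions only
        pick = cand[rng.random(len(cand)) < rate]
        if len(pick) == 0:
            pick = cand[[int(rng.integers(len(cand)))]]
        labels[row, pick] = ids[row, pick]
        r = rng.random(len(pick))
        for pos, u in zip(pick, r):
            if u < 0.8:
                corrupted[row, pos] = MASK
            elif u < 0.9:
                corrupted[row, pos] = int(rng.integers(4, 8))
            # else: keep the original token
    return corrupted, labels


def _pad_tokens(token_lists: list[list[int]]) -> np.ndarray:
    T = max(len(t) for t in token_lists)
    out = np.full((len(token_lists), T), PAD, dtype=int)
    for i, t in enumerate(token_lists):
        out[i, : len(t)] = t
    return out


def train_mlm_embedder(
    corpus: Sequence[SequenceRecord], config: EmbedderConfig
) -> SeqEmbedderModel:
    """Pretrain the embedder by masked language modeling on a corpus.

    Each epoch re-draws the masked positions per sequence (mask rate
    ``mlm_mask_rate``; 80% MASK / 10% random nucleotide / 10% unchanged)
    and takes one full-batch Adam step on the masked-token cross-entropy.
    Deterministic for a fixed seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(config.seed)
    ids = _pad_tokens([tokenize(r.seq, config.max_len) for r in corpus])
    params = _init_params(config, rng)
    opt = _Adam(params, config.learning_rate)
    history: list[float] = []
    for epoch in range(config.epochs):
        corrupted, labels = _mask_batch(ids, rng, config.mlm_mask_rate)
        loss, grads = _mlm_loss_and_grads(params, config, corrupted, labels)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite MLM loss at epoch {epoch}")
        history.append(float(loss))
        opt.step(params, grads)
    return SeqEmbedderModel(config=config, params=params, loss_history=history)


def embed_mirna(
    model: SeqEmbedderModel, seq: str, pooling: str = "cls"
) -> np.ndarray:
    """Embed one sequence: final-layer hidden state at the CLS position.

    ``pooling="mean"`` averages the final hidden states over nucleotide
    positions instead.
    """
    ids = np.array([tokenize(seq, model.config.max_len)], dtype=int)
    hidden, _, _ = _encoder_forward(model.params, model.config, ids)
    if pooling == "cls":
        vec = hidden[0, 0]
    elif pooling == "mean":
        body = ids[0] >= 4
        vec = hidden[0, body].mean(axis=0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return np.asarray(vec, dtype=float)


def mirna_attribute_matrix(
    model: SeqEmbedderModel,
    records: Sequence[SequenceRecord],
    pooling: str = "cls",
) -> AttributeMatrix:
    """Embed a whole miRNA corpus into an AttributeMatrix (batched)."""
    ids = _pad_tokens([tokenize(r.seq, model.config.max_len) for r in records])
    hidden, _, _ = _encoder_forward(model.params, model.config, ids)
    if pooling == "cls":
        vecs = hidden[:, 0, :]
    elif pooling == "mean":
        body = ids >= 4
        vecs = (hidden * body[:, :, None]).sum(axis=1) / body.sum(axis=1)[:, None]
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return AttributeMatrix(ids=[r.id for r in records], vectors=np.asarray(vecs))
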