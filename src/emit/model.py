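"""Transformer encoder over ranked end-motif sequences (NumPy).

The model is a BERT-style encoder: token + position embeddings summed
element-wise, L encoder layers (multi-head scaled dot-product self-attention
with residual, layer normalization, position-wise FFN
``max(0, xW1 + b1)W2 + b2`` with residual, layer normalization), and a
two-layer projection head with a layer normalization in between that maps
each hidden state onto the motif vocabulary. Pretraining corrupts 15% of
motif tokens (80% MASK / 10% random motif / 10% unchanged) and maximizes the
log-likelihood of the corrupted positions only; model fit is tracked as the
exponentiated cross-entropy (ECE), which is 1 for a perfect predictor and
equals the vocabulary size for an uninformed one.

Forward and backward passes are implemented directly with NumPy; gradients
are exact (verified against finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .motifs import EmitError, InvalidParameterError, MotifDictionary

CHECKPOINT_SCHEMA = "emit-checkpoint-v1"
_NEG_INF = -1e9
_LN_EPS = 1e-5


class ShapeError(EmitError, ValueError):
    pass


class DegenerateSequenceError(EmitError, ValueError):
    pass


@dataclass(frozen=True)
class EMITConfig:
    """Architecture hyperparameters.

    hidden_size d must be divisible by num_heads h; ffn_dim defaults to 4d;
    max_positions defaults to 258 so every probing length up to t = 256
    (plus CLS and SEP) fits one positional table.
    """

    hidden_size: int = 64
    num_heads: int = 2
    num_layers: int = 1
    vocab_size: int = 260
    ffn_dim: int | None = None
    max_positions: int = 258
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.hidden_size % self.num_heads != 0:
            raise InvalidParameterError(
                f"hidden_size {self.hidden_size} not divisible by num_heads {self.num_heads}"
            )
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.hidden_size)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidParameterError("dropout_rate must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.num_heads


@dataclass
class ModelState:
    """All learnable parameters, keyed by name, as float64 arrays."""

    config: EMITConfig
    params: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def init_model_state(config: EMITConfig, seed: int = 0) -> ModelState:
    """Gaussian(0, 0.02) weights, zero biases, unit layer-norm gains."""
    rng = np.random.default_rng(seed)
    d, f, V, P = config.hidden_size, config.ffn_dim, config.vocab_size, config.max_positions
    p: dict[str, np.ndarray] = {}

    def w(shape):
        return rng.normal(0.0, 0.02, size=shape)

    p["tok_emb"] = w((V, d))
    p["pos_emb"] = w((P, d))
    for layer in range(config.num_layers):
        pre = f"l{layer}."
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = w((d, d))
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(d)
        p[pre + "ln1_g"] = np.ones(d)
        p[pre + "ln1_b"] = np.zeros(d)
        p[pre + "W1"] = w((d, f))
        p[pre + "b1"] = np.zeros(f)
        p[pre + "W2"] = w((f, d))
        p[pre + "b2"] = np.zeros(d)
        p[pre + "ln2_g"] = np.ones(d)
        p[pre + "ln2_b"] = np.zeros(d)
    p["head.W1"] = w((d, d))
    p["head.b1"] = np.zeros(d)
    p["head.ln_g"] = np.ones(d)
    p["head.ln_b"] = np.zeros(d)
    p["head.W2"] = w((d, V))
    p["head.b2"] = np.zeros(V)
    return ModelState(config=config, params=p)


# ---------------------------------------------------------------- primitives


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_product_attention(Q, K, V, mask=None):
    """``A = softmax(QK^T / sqrt(d_k))``; returns (A @ V, A).

    Q, K, V: (..., T, d_k). ``mask``, if given, is a boolean (..., T) key
    mask; masked-out keys receive no attention. Rows of A sum to 1.
    """
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ShapeError(f"inconsistent attention shapes {Q.shape} {K.shape} {V.shape}")
    dk = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(dk)
    if mask is not None:
        scores = np.where(np.asarray(mask, bool)[..., None, :], scores, _NEG_INF)
    A = softmax(scores, axis=-1)
    return A @ V, A


def feed_forward(x, state: ModelState, layer: int = 0):
    """Position-wise FFN ``max(0, xW1 + b1)W2 + b2`` of one encoder layer."""
    x = np.asarray(x, float)
    p = state.params
    W1, b1 = p[f"l{layer}.W1"], p[f"l{layer}.b1"]
    W2, b2 = p[f"l{layer}.W2"], p[f"l{layer}.b2"]
    if x.shape[-1] != W1.shape[0]:
        raise ShapeError(f"input width {x.shape[-1]} != hidden size {W1.shape[0]}")
    return np.maximum(0.0, x @ W1 + b1) @ W2 + b2


def _layer_norm(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _split_heads(x, h):
    B, T, d = x.shape
    return x.reshape(B, T, h, d // h).transpose(0, 2, 1, 3)  # (B,h,T,dk)


def _merge_heads(x):
    B, h, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)


# ------------------------------------------------------------------- forward


def forward(
    ids: np.ndarray,
    state: ModelState,
    attention_mask: np.ndarray | None = None,
    train: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Run the encoder + projection head.

    ids: (T,) or (B, T) integer token ids; attention_mask flags non-PAD
    positions (all-true if omitted). Returns ``(Z, logits, attentions)``
    where Z is the final hidden-state matrix (same shape as the embedded
    input), logits are per-position distributions over the vocabulary, and
    attentions is a list of per-layer (B, h, T, T) attention tensors.
    Evaluation mode (train=False) is deterministic: dropout is disabled.
    """
    cfg = state.config
    p = state.params
    ids = np.asarray(ids)
    squeeze = ids.ndim == 1
    if squeeze:
        ids = ids[None, :]
        if attention_mask is not None:
            attention_mask = np.asarray(attention_mask, bool)[None, :]
    B, T = ids.shape
    if T > cfg.max_positions:
        raise InvalidParameterError(f"sequence length {T} exceeds max_positions {cfg.max_positions}")
    if ids.min() < 0 or ids.max() >= cfg.vocab_size:
        raise InvalidParameterError("token id out of vocabulary")
    if attention_mask is None:
        attention_mask = np.ones((B, T), dtype=bool)
    drop = cfg.dropout_rate if train else 0.0
    if drop > 0 and rng is None:
        rng = np.random.default_rng()

    def dropout(x):
        if drop == 0:
            return x, None
        m = (rng.random(x.shape) >= drop) / (1.0 - drop)
        return x * m, m

    x = p["tok_emb"][ids] + p["pos_emb"][:T]
    x, m_emb = dropout(x)
    cache: dict = {"ids": ids, "T": T, "mask": attention_mask, "m_emb": m_emb, "layers": []}
    attentions = []
    h = cfg.num_heads
    for layer in range(cfg.num_layers):
        pre = f"l{layer}."
        x_in = x
        Q = x @ p[pre + "Wq"] + p[pre + "bq"]
        K = x @ p[pre + "Wk"] + p[pre + "bk"]
        V = x @ p[pre + "Wv"] + p[pre + "bv"]
        Qh, Kh, Vh = _split_heads(Q, h), _split_heads(K, h), _split_heads(V, h)
        ctx_h, A = scaled_dot_product_attention(Qh, Kh, Vh, mask=attention_mask[:, None, :])
        attentions.append(A)
        ctx = _merge_heads(ctx_h)
        proj = ctx @ p[pre + "Wo"] + p[pre + "bo"]
        proj, m_attn = dropout(proj)
        res1 = x_in + proj
        x1, ln1_cache = _layer_norm(res1, p[pre + "ln1_g"], p[pre + "ln1_b"])
        pre_act = x1 @ p[pre + "W1"] + p[pre + "b1"]
        act = np.maximum(0.0, pre_act)
        ffn = act @ p[pre + "W2"] + p[pre + "b2"]
        ffn, m_ffn = dropout(ffn)
        res2 = x1 + ffn
        x2, ln2_cache = _layer_norm(res2, p[pre + "ln2_g"], p[pre + "ln2_b"])
        cache["layers"].append(
            dict(x_in=x_in, Qh=Qh, Kh=Kh, Vh=Vh, A=A, ctx=ctx, m_attn=m_attn,
                 ln1_cache=ln1_cache, x1=x1, pre_act=pre_act, act=act,
                 m_ffn=m_ffn, ln2_cache=ln2_cache)
        )
        x = x2
    Z = x
    h1 = Z @ p["head.W1"] + p["head.b1"]
    a1 = np.maximum(0.0, h1)
    n1, lnh_cache = _layer_norm(a1, p["head.ln_g"], p["head.ln_b"])
    logits = n1 @ p["head.W2"] + p["head.b2"]
    cache.update(Z=Z, h1=h1, a1=a1, n1=n1, lnh_cache=lnh_cache)
    if squeeze:
        Z_out, logits_out = Z[0], logits[0]
        att_out = [A[0] for A in attentions]
    else:
        Z_out, logits_out, att_out = Z, logits, attentions
    if return_cache:
        return Z_out, logits_out, att_out, cache
    return Z_out, logits_out, att_out


# ------------------------------------------------------------------ backward


def backward(dlogits: np.ndarray, state: ModelState, cache: dict) -> dict[str, np.ndarray]:
    """Exact gradients of a scalar loss with upstream gradient ``dlogits``
    (B, T, V) w.r.t. every parameter. Mirrors :func:`forward`."""
    cfg = state.config
    p = state.params
    grads = {name: np.zeros_like(arr) for name, arr in p.items()}
    B, T = cache["ids"].shape
    h = cfg.num_heads
    dk = cfg.head_dim

    # projection head
    grads["head.W2"] = np.einsum("btd,btv->dv", cache["n1"], dlogits)
    grads["head.b2"] = dlogits.sum(axis=(0, 1))
    dn1 = dlogits @ p["head.W2"].T
    da1, dg, db = _layer_norm_backward(dn1, p["head.ln_g"], cache["lnh_cache"])
    grads["head.ln_g"], grads["head.ln_b"] = dg, db
    dh1 = da1 * (cache["h1"] > 0)
    grads["head.W1"] = np.einsum("btd,bte->de", cache["Z"], dh1)
    grads["head.b1"] = dh1.sum(axis=(0, 1))
    dx = dh1 @ p["head.W1"].T

    for layer in reversed(range(cfg.num_layers)):
        pre = f"l{layer}."
        c = cache["layers"][layer]
        dres2, dg, db = _layer_norm_backward(dx, p[pre + "ln2_g"], c["ln2_cache"])
        grads[pre + "ln2_g"], grads[pre + "ln2_b"] = dg, db
        dffn = dres2 if c["m_ffn"] is None else dres2 * c["m_ffn"]
        grads[pre + "W2"] = np.einsum("btf,btd->fd", c["act"], dffn)
        grads[pre + "b2"] = dffn.sum(axis=(0, 1))
        dact = dffn @ p[pre + "W2"].T
        dpre_act = dact * (c["pre_act"] > 0)
        grads[pre + "W1"] = np.einsum("btd,btf->df", c["x1"], dpre_act)
        grads[pre + "b1"] = dpre_act.sum(axis=(0, 1))
        dx1 = dres2 + dpre_act @ p[pre + "W1"].T
        dres1, dg, db = _layer_norm_backward(dx1, p[pre + "ln1_g"], c["ln1_cache"])
        grads[pre + "ln1_g"], grads[pre + "ln1_b"] = dg, db
        dproj = dres1 if c["m_attn"] is None else dres1 * c["m_attn"]
        grads[pre + "Wo"] = np.einsum("btd,bte->de", c["ctx"], dproj)
        grads[pre + "bo"] = dproj.sum(axis=(0, 1))
        dctx = dproj @ p[pre + "Wo"].T
        dctx_h = dctx.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
        A = c["A"]
        dA = dctx_h @ np.swapaxes(c["Vh"], -1, -2)
        dVh = np.swapaxes(A, -1, -2) @ dctx_h
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dS @ c["Kh"] / np.sqrt(dk)
        dKh = np.swapaxes(dS, -1, -2) @ c["Qh"] / np.sqrt(dk)
        dQ, dK, dV = _merge_heads(dQh), _merge_heads(dKh), _merge_heads(dVh)
        x_in = c["x_in"]
        grads[pre + "Wq"] = np.einsum("btd,bte->de", x_in, dQ)
        grads[pre + "Wk"] = np.einsum("btd,bte->de", x_in, dK)
        grads[pre + "Wv"] = np.einsum("btd,bte->de", x_in, dV)
        grads[pre + "bq"] = dQ.sum(axis=(0, 1))
        grads[pre + "bk"] = dK.sum(axis=(0, 1))
        grads[pre + "bv"] = dV.sum(axis=(0, 1))
        dx = dres1 + dQ @ p[pre + "Wq"].T + dK @ p[pre + "Wk"].T + dV @ p[pre + "Wv"].T

    if cache["m_emb"] is not None:
        dx = dx * cache["m_emb"]
    np.add.at(grads["tok_emb"], cache["ids"].ravel(), dx.reshape(-1, cfg.hidden_size))
    grads["pos_emb"][:T] = dx.sum(axis=0)
    return grads


# ---------------------------------------------------------- masking and loss


def mask_sequence(
    token_ids: np.ndarray,
    dictionary: MotifDictionary,
    seed: int | np.random.Generator,
    corruption_rate: float = 0.15,
    mask_share: float = 0.8,
    random_share: float = 0.1,
):
    """BERT-style corruption of a ranked motif sequence.

    Each motif position (CLS/SEP/MASK/PAD are never candidates) is selected
    independently with probability ``corruption_rate``; if none is selected,
    one motif position chosen uniformly is forced so that every sequence has
    a defined loss. A selected position is replaced by the MASK token with
    probability ``mask_share``, by a uniformly random motif with probability
    ``random_share``, and kept unchanged otherwise. Returns
    ``(corrupted_ids, target_ids, selected)`` where target_ids is -1 at
    unselected positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.asarray(token_ids)
    squeeze = ids.ndim == 1
    ids2 = np.atleast_2d(ids)
    n_motifs = dictionary.n_motifs
    candidates = ids2 < n_motifs  # motif tokens have the lowest ids
    if not candidates.any(axis=1).all():
        raise DegenerateSequenceError("sequence contains no motif tokens to corrupt")
    selected = (rng.random(ids2.shape) < corruption_rate) & candidates
    for b in np.flatnonzero(~selected.any(axis=1)):
        pos = rng.choice(np.flatnonzero(candidates[b]))
        selected[b, pos] = True
    corrupted = ids2.copy()
    u = rng.random(ids2.shape)
    randoms = rng.integers(0, n_motifs, size=ids2.shape)
    to_mask = selected & (u < mask_share)
    to_random = selected & (u >= mask_share) & (u < mask_share + random_share)
    corrupted[to_mask] = dictionary.mask_id
    corrupted[to_random] = randoms[to_random]
    targets = np.where(selected, ids2, -1)
    if squeeze:
        return corrupted[0], targets[0], selected[0]
    return corrupted, targets, selected


def masked_lm_loss_and_grads(
    state: ModelState,
    corrupted_ids: np.ndarray,
    targets: np.ndarray,
    attention_mask: np.ndarray | None = None,
    train: bool = True,
    rng: np.random.Generator | None = None,
):
    """Mean cross-entropy over the selected (target >= 0) positions and its
    parameter gradients."""
    corrupted_ids = np.atleast_2d(corrupted_ids)
    targets = np.atleast_2d(targets)
    _, logits, _, cache = forward(
        corrupted_ids, state, attention_mask=attention_mask, train=train, rng=rng,
        return_cache=True,
    )
    sel = targets >= 0
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise DegenerateSequenceError("no masked targets")
    probs = softmax(logits, axis=-1)
    b_idx, t_idx = np.nonzero(sel)
    tgt = targets[sel]
    logp = np.log(probs[b_idx, t_idx, tgt] + 1e-300)
    loss = -logp.mean()
    dlogits = np.zeros_like(logits)
    dlogits[b_idx, t_idx, :] = probs[b_idx, t_idx, :] / n_sel
    dlogits[b_idx, t_idx, tgt] -= 1.0 / n_sel
    grads = backward(dlogits, state, cache)
    return loss, grads


def compute_ece(logits: np.ndarray, target_ids: np.ndarray) -> float:
    """Exponentiated cross-entropy over masked positions.

    ``exp(mean cross-entropy)``: 1 for a perfect predictor, equal to the
    vocabulary size for a uniform one; never below 1 at the optimum.
    """
    logits = np.atleast_2d(np.asarray(logits, float))
    target_ids = np.asarray(target_ids).ravel()
    if target_ids.size == 0:
        raise DegenerateSequenceError("ECE undefined with zero masked targets")
    if logits.shape[0] != target_ids.size:
        raise ShapeError("one logit row per masked target required")
    logZ = np.log(np.exp(logits - logits.max(axis=1, keepdims=True)).sum(axis=1))
    logp = logits[np.arange(len(target_ids)), target_ids] - logits.max(axis=1) - logZ
    return float(np.exp(-logp.mean()))


# --------------------------------------------------------------- checkpoints


def save_checkpoint(state: ModelState, path) -> None:
    """Single-archive checkpoint (config JSON + all weights); reloading
    reproduces forward outputs bit for bit."""
    meta = json.dumps({"schema": CHECKPOINT_SCHEMA, "config": asdict(state.config)})
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state.params)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise EmitError(f"unknown checkpoint schema {meta.get('schema')!r}")
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelState(config=EMITConfig(**meta["config"]), params=params)
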