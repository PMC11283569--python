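"""Masked-LM pretraining loop.

Adam with decoupled weight decay (applied to weight matrices only, not to
biases or layer-norm parameters), a learning-rate schedule that warms up
linearly for the first epoch and then decays to zero along a cosine, and
per-epoch monitoring of the exponentiated cross-entropy (ECE) on a held-out
set of sequences that is never trained on. Published-scale defaults are
batch size 256, weight decay 0.01, peak learning rate 1e-4, 40 epochs and a
5,000-sequence holdout; every knob is overridable for desk-scale runs.

All randomness (holdout split, batch shuffling, masking, dropout) flows from
a single run seed, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    EMITConfig,
    ModelState,
    compute_ece,
    forward,
    init_model_state,
    mask_sequence,
    masked_lm_loss_and_grads,
)
from .motifs import InvalidParameterError, MotifDictionary
from .sequences import EndMotifSequence


def lr_schedule(step: int, total_steps: int, warmup_steps: int, peak_lr: float) -> float:
    """Linear warmup from 0 to ``peak_lr`` over ``warmup_steps``, then
    cosine decay to 0 at ``total_steps``; clamped to 0 beyond."""
    if warmup_steps >= total_steps:
        raise InvalidParameterError("warmup_steps must be < total_steps")
    if step < 0:
        raise InvalidParameterError("step must be non-negative")
    if step > total_steps:
        return 0.0
    if step < warmup_steps:
        return peak_lr * step / warmup_steps
    frac = (step - warmup_steps) / (total_steps - warmup_steps)
    return peak_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


@dataclass
class TrainingMetrics:
    """Per-epoch holdout ECE and per-step learning rates of one run."""

    seed: int
    holdout_ece: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)

    @property
    def final_ece(self) -> float:
        return self.holdout_ece[-1]


class AdamW:
    """Adam with decoupled weight decay (betas 0.9/0.999, eps 1e-8).

    Decay is applied only to 2-D weight matrices; biases and layer-norm
    gains/offsets are exempt, following common transformer practice.
    """

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.weight_decay and p.ndim == 2:
                update = update + self.weight_decay * p
            p -= lr * update


def holdout_ece(state: ModelState, sequences: list[np.ndarray], masks: list, seed: int) -> float:
    """ECE on a fixed, seeded corruption of the holdout sequences."""
    rng = np.random.default_rng(seed)
    ids = np.stack(sequences)
    attn = np.stack(masks)
    dictionary = _dict_for_vocab(state.config)
    corrupted, targets, _ = mask_sequence(ids, dictionary, rng)
    _, logits, _ = forward(corrupted, state, attention_mask=attn, train=False)
    sel = targets >= 0
    return compute_ece(logits[sel], targets[sel])


def _dict_for_vocab(config: EMITConfig) -> MotifDictionary:
    from .motifs import build_dictionary

    k = round(np.log(config.vocab_size - 4) / np.log(4))
    if 4**k + 4 != config.vocab_size:
        raise InvalidParameterError(f"vocab_size {config.vocab_size} is not 4^k + 4")
    return build_dictionary(k)


def pretrain(
    corpus: list[EndMotifSequence],
    config: EMITConfig,
    dictionary: MotifDictionary,
    *,
    batch_size: int = 256,
    weight_decay: float = 0.01,
    peak_lr: float = 1e-4,
    epochs: int = 40,
    holdout_n: int = 200,
    seed: int = 0,
    log=None,
) -> tuple[ModelState, TrainingMetrics]:
    """Train a masked-LM on a corpus of ranked end-motif sequences.

    ``holdout_n`` sequences are withheld uniformly at random (seeded) and
    never trained on; holdout ECE is recorded after every epoch. Each epoch
    reshuffles the training set and applies a fresh seeded corruption.
    """
    if not 1 <= holdout_n < len(corpus):
        raise InvalidParameterError("need corpus size > holdout_n >= 1")
    rng = np.random.default_rng(seed)
    ids_all = np.stack([s.token_ids(dictionary) for s in corpus])
    attn_all = np.stack([s.attention_mask for s in corpus])
    perm = rng.permutation(len(corpus))
    hold_idx, train_idx = perm[:holdout_n], perm[holdout_n:]
    if len(train_idx) < 1:
        raise InvalidParameterError("corpus too small after holdout")
    hold_ids = [ids_all[i] for i in hold_idx]
    hold_masks = [attn_all[i] for i in hold_idx]
    hold_seed = int(rng.integers(2**31))

    state = init_model_state(config, seed=int(rng.integers(2**31)))
    optimizer = AdamW(state.params, weight_decay=weight_decay)
    steps_per_epoch = max(1, len(train_idx) // batch_size)
    total_steps = steps_per_epoch * epochs
    # one-epoch warmup, shortened when a single epoch is the whole run
    warmup_steps = min(steps_per_epoch, max(0, total_steps - 1))
    metrics = TrainingMetrics(seed=seed)
    metrics.holdout_ece.append(holdout_ece(state, hold_ids, hold_masks, hold_seed))
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        for b in range(steps_per_epoch):
            batch = order[b * batch_size : (b + 1) * batch_size]
            if len(batch) == 0:
                continue
            ids = ids_all[batch]
            attn = attn_all[batch]
            corrupted, targets, _ = mask_sequence(ids, dictionary, rng)
            loss, grads = masked_lm_loss_and_grads(
                state, corrupted, targets, attention_mask=attn, train=True, rng=rng
            )
            lr = lr_schedule(step + 1, total_steps, warmup_steps, peak_lr)
            optimizer.step(state.params, grads, lr)
            metrics.learning_rates.append(lr)
            metrics.train_loss.append(float(loss))
            step += 1
        ece = holdout_ece(state, hold_ids, hold_masks, hold_seed)
        metrics.holdout_ece.append(ece)
        if log is not None:
            log({"epoch": epoch, "step": step, "lr": metrics.learning_rates[-1],
                 "loss": metrics.train_loss[-1], "holdout_ece": ece})
    return state, metrics
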