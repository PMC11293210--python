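"""Fitting the encoder and scoring head, and end-to-end prediction.

Training minimizes a per-cell categorical cross-entropy over the four link
tags: gold triples are encoded once per sentence into the L x K x L tag
tensor, the model produces logits for every (subject position, relation,
object position) cell, and the loss is the weighted mean negative
log-probability of the gold tag. Because tag 0 (background) dominates the
tensor, background cells can be down-weighted through
``class_weight_background``. Optimization uses Adam.

The forward/backward pass is written directly in numpy: the model is small
(a character-embedding table, a couple of centered convolution layers and
two fully connected scoring layers), so explicit gradients are simpler and
more transparent than pulling in a deep-learning framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import log_softmax

from .evaluation import strict_match
from .scoring_model import GlobalPointerModel, build_model, tags_from_scores
from .tag_codec import decode_tensor, encode_triples, resolve_collision, triple_cells
from .types import RelationSchema, Sentence, Triple, validate_triples

logger = logging.getLogger(__name__)

Corpus = "list[tuple[Sentence, frozenset[Triple] | set[Triple]]]"


@dataclass
class TrainConfig:
    """Training settings; defaults follow the published full-scale recipe
    (Adam, lr 1e-5, 50 epochs, batch 64, dropout 0.5, max length 256)."""

    learning_rate: float = 1e-5
    epochs: int = 50
    batch_size: int = 64
    dropout_rate: float = 0.5
    max_len: int = 256
    seed: int = 0
    class_weight_background: float = 1.0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.class_weight_background < 0:
            raise ValueError("class_weight_background must be nonnegative")


def compute_loss(scores: np.ndarray, gold: np.ndarray, config: TrainConfig) -> float:
    """Weighted mean cross-entropy of the gold tag over all L*K*L cells.

    ``scores`` are raw logits (L, K, L, 4); ``gold`` the tag tensor
    (L, K, L). Background (tag 0) cells carry weight
    ``class_weight_background``, others weight 1; the loss is the weighted
    mean, 0 when every weight is 0.
    """
    scores, gold = np.asarray(scores), np.asarray(gold)
    if scores.shape[:3] != gold.shape or scores.shape[-1] != 4:
        raise ValueError(f"shape mismatch: scores {scores.shape}, gold {gold.shape}")
    logp = log_softmax(scores, axis=-1)
    nll = -np.take_along_axis(logp, gold[..., None].astype(int), axis=-1)[..., 0]
    w = np.where(gold == 0, config.class_weight_background, 1.0)
    total = w.sum()
    return float((w * nll).sum() / total) if total > 0 else 0.0


# --------------------------------------------------------------------------
# internal batched forward/backward
# --------------------------------------------------------------------------

def _prepare(corpus, model: GlobalPointerModel, config: TrainConfig):
    """Token ids and sparse gold cells per sentence; truncates over-long
    sentences, dropping triples that touch truncated positions."""
    items = []
    n_dropped = 0
    K = len(model.schema)
    for sentence, triples in corpus:
        tokens = sentence.tokens
        triples = set(triples)
        if len(tokens) > config.max_len:
            tokens = tokens[: config.max_len]
            kept = {
                t for t in triples
                if t.subject.tail < config.max_len and t.object.tail < config.max_len
            }
            n_dropped += len(triples) - len(kept)
            triples = kept
            sentence = Sentence(sentence.id, tokens)
        validate_triples(triples, len(tokens), K)
        cells = {}
        for t in triples:
            for cell, tag in triple_cells(t).items():
                cells[cell] = resolve_collision(cells.get(cell, 0), tag)
        items.append((model.encoder.token_ids(tokens), len(tokens), cells))
    if n_dropped:
        logger.warning(
            "truncated corpus to max_len=%d, dropping %d triples", config.max_len, n_dropped
        )
    return items


def _batch_forward_backward(
    model: GlobalPointerModel, batch, config: TrainConfig, rng: np.random.Generator,
    training: bool = True,
):
    """One batch: returns (loss, grads). Pads to the batch max length."""
    K = len(model.schema)
    B = len(batch)
    Lmax = max(L for _, L, _ in batch)
    ids = np.zeros((B, Lmax), dtype=np.int64)
    mask = np.zeros((B, Lmax))
    gold = np.zeros((B, Lmax, K, Lmax), dtype=np.int8)
    for bi, (tid, L, cells) in enumerate(batch):
        ids[bi, :L] = tid
        mask[bi, :L] = 1.0
        for (i, k, j), tag in cells.items():
            gold[bi, i, k, j] = tag
    cache: dict = {}
    H = model.encoder.forward_batch(ids, mask, cache)  # (B, L, d)
    sc = model.scorer
    d, d_e = sc.d, sc.d_e
    Wl, Wr = sc.W[:, :d], sc.W[:, d:]
    Hl, Hr = H @ Wl.T, H @ Wr.T
    Zp = Hl[:, :, None, :] + Hr[:, None, :, :] + sc.b  # (B, L, L, d_e)
    if training and config.dropout_rate > 0:
        keep = 1.0 - config.dropout_rate
        D = (rng.random(Zp.shape) < keep) / keep
        Zd = Zp * D
    else:
        D = None
        Zd = Zp
    P = np.maximum(Zd, 0.0)
    S = P @ sc.R_w  # (B, L, L, 4K)
    logits = S.reshape(B, Lmax, Lmax, K, 4)

    goldT = gold.transpose(0, 1, 3, 2)  # (B, Li, Lj, K)
    valid = mask[:, :, None] * mask[:, None, :]  # (B, Li, Lj)
    w = valid[..., None] * np.where(goldT == 0, config.class_weight_background, 1.0)
    logp = log_softmax(logits, axis=-1)
    nll = -np.take_along_axis(logp, goldT[..., None].astype(int), axis=-1)[..., 0]
    W_sum = w.sum()
    loss = float((w * nll).sum() / W_sum) if W_sum > 0 else 0.0
    if not training:
        return loss, None

    probs = np.exp(logp)
    dlogits = probs.copy()
    np.put_along_axis(
        dlogits,
        goldT[..., None].astype(int),
        np.take_along_axis(dlogits, goldT[..., None].astype(int), axis=-1) - 1.0,
        axis=-1,
    )
    dlogits *= (w / max(W_sum, 1e-12))[..., None]
    dS = dlogits.reshape(B, Lmax, Lmax, 4 * K)
    grads: dict[str, np.ndarray] = {}
    grads["R_w"] = P.reshape(-1, d_e).T @ dS.reshape(-1, 4 * K)
    dP = dS @ sc.R_w.T
    dZd = dP * (Zd > 0)
    dZp = dZd * D if D is not None else dZd
    grads["b"] = dZp.sum(axis=(0, 1, 2))
    dHl = dZp.sum(axis=2)
    dHr = dZp.sum(axis=1)
    dWl = dHl.reshape(-1, d_e).T @ H.reshape(-1, d)
    dWr = dHr.reshape(-1, d_e).T @ H.reshape(-1, d)
    grads["W"] = np.concatenate([dWl, dWr], axis=1)
    dH = dHl @ Wl + dHr @ Wr
    model.encoder.backward_batch(dH, cache, grads)
    return loss, grads


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def train(
    corpus,
    schema: RelationSchema,
    config: TrainConfig,
    model: GlobalPointerModel | None = None,
    val_corpus=None,
    vocab: "list[str] | None" = None,
    model_kwargs: dict | None = None,
):
    """Fit a model on (sentence, gold triples) pairs; returns
    (model, history).

    Gold triples are encoded to tag tensors once per sentence via the tag
    codec (stored sparsely, densified per batch). ``history`` holds one
    record per epoch with the mean training loss and, when ``val_corpus``
    is given, held-out strict micro-F1. Fully reproducible under
    ``config.seed``.
    """
    config.validate()
    corpus = list(corpus)
    if not corpus:
        raise ValueError("training corpus is empty")
    if model is None:
        if vocab is None:
            vocab = sorted({t for s, _ in corpus for t in s.tokens})
        model = build_model(
            schema, vocab, dropout_rate=config.dropout_rate,
            seed=config.seed, **(model_kwargs or {}),
        )
    rng = np.random.default_rng(config.seed)
    items = _prepare(corpus, model, config)
    params = model.parameters()
    opt = _Adam(params, config.learning_rate)
    history = []
    order = np.arange(len(items))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [items[i] for i in order[start : start + config.batch_size]]
            loss, grads = _batch_forward_backward(model, batch, config, rng)
            opt.step(params, grads)
            losses.append(loss)
        record = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if val_corpus is not None:
            gold = {s.id: set(ts) for s, ts in val_corpus}
            pred = {
                s.id: predict(model, s, max_len=config.max_len)
                for s, _ in val_corpus
            }
            record["val_f1"] = strict_match(gold, pred).f1
        history.append(record)
        logger.info("epoch %d: %s", epoch + 1, record)
    return model, history


def predict(
    model: GlobalPointerModel, sentence: Sentence, max_len: int = 256
) -> set[Triple]:
    """End-to-end prediction: encode -> score (dropout off) -> argmax tags
    -> decode. Deterministic given the model."""
    if sentence.length > max_len:
        sentence = Sentence(sentence.id, sentence.tokens[:max_len])
    logits = model.score_sentence(sentence, training=False)
    return decode_tensor(tags_from_scores(logits))


def predict_corpus(
    model: GlobalPointerModel, sentences, max_len: int = 256
) -> dict[str, set[Triple]]:
    return {s.id: predict(model, s, max_len=max_len) for s in sentences}


def encode_gold(sentence: Sentence, triples, K: int) -> np.ndarray:
    """Convenience: gold tag tensor for one sentence."""
    return encode_triples(sentence.length, triples, K)
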