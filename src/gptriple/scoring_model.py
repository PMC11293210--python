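"""Sentence scoring: pluggable encoder + pair-scoring head.

The head scores every ordered token pair (w_i, w_j) against all K relations
and 4 link tags at once:

    v(w_i, r_k, w_j) = R^T ReLU(drop(W [e_i ; e_j] + b))

where ``W`` (d_e x 2d) and ``b`` project the concatenated pair of token
embeddings to a shared pair representation and ``R`` (d_e x 4K) maps it to
the 4K tag logits, grouped as (K, 4). The concatenation is asymmetric, which
is what lets the head distinguish subject from object. Because ``R`` scores
all relations from one pair representation, the expensive projection is done
L x 1 x L times (once per ordered pair), not L x K x L times.

The encoder is a contract: anything mapping a character sequence to one
d-dimensional vector per token. The default desk-scale encoder is a
trainable character-embedding table followed by a small stack of
bidirectional (centered) convolution layers, giving each token a local
context window; an external pretrained encoder can be plugged in through the
same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .types import Sentence

UNK_ID = 0  #: reserved row of the embedding table for out-of-vocabulary chars


# --------------------------------------------------------------------------
# pair-scoring head
# --------------------------------------------------------------------------

@dataclass
class ScorerParams:
    """Trainable weights of the two-layer scoring head.

    W: (d_e, 2d) concatenation projection; b: (d_e,); R_w: (d_e, 4K).
    """

    W: np.ndarray
    b: np.ndarray
    R_w: np.ndarray
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        d_e = self.W.shape[0]
        if self.b.shape != (d_e,) or self.R_w.shape[0] != d_e:
            raise ValueError("inconsistent scorer parameter shapes")
        if self.R_w.shape[1] % 4 != 0:
            raise ValueError("R_w output width must be 4*K")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")

    @property
    def d(self) -> int:
        return self.W.shape[1] // 2

    @property
    def d_e(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.R_w.shape[1] // 4

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size + self.R_w.size

    @classmethod
    def init(
        cls, d: int, K: int, d_e: int | None = None, dropout_rate: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> "ScorerParams":
        """He-scaled random initialization; d_e defaults to d."""
        rng = rng or np.random.default_rng(0)
        d_e = d_e or d
        return cls(
            W=rng.normal(0.0, np.sqrt(2.0 / (2 * d)), (d_e, 2 * d)),
            b=np.zeros(d_e),
            R_w=rng.normal(0.0, np.sqrt(2.0 / d_e), (d_e, 4 * K)),
            dropout_rate=dropout_rate,
        )


def pair_representation(
    e_i: np.ndarray,
    e_j: np.ndarray,
    params: ScorerParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ReLU(drop(W [e_i; e_j] + b)) for one ordered token pair.

    Dropout (inverted scaling) is applied to the affine output, inside the
    ReLU, only when ``training`` is set. Asymmetric in (e_i, e_j).
    """
    e_i, e_j = np.asarray(e_i), np.asarray(e_j)
    if e_i.shape != (params.d,) or e_j.shape != (params.d,):
        raise ValueError(
            f"pair inputs must have dimension {params.d}, got {e_i.shape}, {e_j.shape}"
        )
    z = params.W @ np.concatenate([e_i, e_j]) + params.b
    if training and params.dropout_rate > 0.0:
        rng = rng or np.random.default_rng()
        keep = 1.0 - params.dropout_rate
        z = z * (rng.random(z.shape) < keep) / keep
    return np.maximum(z, 0.0)


def score_all_pairs(
    emb: np.ndarray,
    params: ScorerParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    max_cells: int = 100_000_000,
    counter: "PairRepCounter | None" = None,
) -> np.ndarray:
    """Score every ordered pair; returns raw logits of shape (L, K, L, 4).

    The pair representation is computed exactly once per ordered (i, j) —
    L*L affine+ReLU evaluations — and projected once through R_w to produce
    the scores of all K relations and 4 tags simultaneously. ``counter``,
    when given, records that count for instrumentation.
    """
    emb = np.asarray(emb)
    L, d = emb.shape
    if d != params.d:
        raise ValueError(f"embedding width {d} != scorer input width {params.d}")
    K = params.K
    if L * K * L * 4 > max_cells:
        raise MemoryError(
            f"score tensor {L}x{K}x{L}x4 exceeds the {max_cells}-cell budget"
        )
    Wl, Wr = params.W[:, :d], params.W[:, d:]
    z = emb @ Wl.T
    z = z[:, None, :] + (emb @ Wr.T)[None, :, :] + params.b  # (L, L, d_e)
    if training and params.dropout_rate > 0.0:
        rng = rng or np.random.default_rng()
        keep = 1.0 - params.dropout_rate
        z = z * (rng.random(z.shape) < keep) / keep
    p = np.maximum(z, 0.0)
    if counter is not None:
        counter.add(L * L)
    s = p @ params.R_w  # (L, L, 4K), grouped (K, 4)
    return s.reshape(L, L, K, 4).transpose(0, 2, 1, 3)


def score_all_pairs_loop(
    emb: np.ndarray, params: ScorerParams, counter: "PairRepCounter | None" = None
) -> np.ndarray:
    """Reference path: explicit loop calling :func:`pair_representation`
    once per ordered pair. Equals :func:`score_all_pairs` in eval mode;
    used for instrumented probes of the L x 1 x L contract."""
    emb = np.asarray(emb)
    L = emb.shape[0]
    K = params.K
    out = np.empty((L, K, L, 4))
    for i in range(L):
        for j in range(L):
            p = pair_representation(emb[i], emb[j], params, training=False)
            if counter is not None:
                counter.add(1)
            out[i, :, j, :] = (p @ params.R_w).reshape(K, 4)
    return out


class PairRepCounter:
    """Counts pair-representation evaluations (instrumentation hook)."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += n


def softmax_scores(logits: np.ndarray) -> np.ndarray:
    """Per-cell softmax over the 4 tag scores."""
    return softmax(logits, axis=-1)


def tags_from_scores(scores: np.ndarray) -> np.ndarray:
    """Predicted tag tensor (L, K, L): per-cell argmax over the 4 tag
    scores. Softmax is monotone, so raw logits and probabilities give the
    same argmax; ties break toward the lower tag value (background first)."""
    scores = np.asarray(scores)
    if scores.ndim != 4 or scores.shape[-1] != 4:
        raise ValueError(f"score tensor must be (L, K, L, 4), got {scores.shape}")
    return np.argmax(scores, axis=-1).astype(np.int8)


# --------------------------------------------------------------------------
# default desk-scale encoder
# --------------------------------------------------------------------------

def _shift(x: np.ndarray, o: int) -> np.ndarray:
    """Shift along the length axis (axis 1) by offset o, zero-padded."""
    out = np.zeros_like(x)
    if o == 0:
        return x.copy()
    if o > 0:
        out[:, :-o] = x[:, o:]
    else:
        out[:, -o:] = x[:, :o]
    return out


class CharConvEncoder:
    """Character-embedding table + centered-convolution context mixer.

    Each token vector sees a symmetric window of neighbours (receptive field
    ``n_layers * radius`` on each side), enough to recognise entity
    boundaries in character-class corpora. Deterministic in eval mode; no
    dropout. Vocabulary row 0 is reserved for unknown characters.
    """

    def __init__(
        self,
        vocab: "dict[str, int] | list[str]",
        d: int = 32,
        n_layers: int = 2,
        radius: int = 2,
        rng: np.random.Generator | None = None,
    ):
        if isinstance(vocab, dict):
            self.vocab = dict(vocab)
        else:
            # id 0 reserved for UNK
            self.vocab = {ch: i + 1 for i, ch in enumerate(vocab)}
        if UNK_ID in self.vocab.values():
            raise ValueError("vocabulary id 0 is reserved for the unknown token")
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.n_layers = n_layers
        self.radius = radius
        V = max(self.vocab.values()) + 1
        width = 2 * radius + 1
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 1.0, (V, d))
        }
        for l in range(n_layers):
            self.params[f"convW{l}"] = rng.normal(
                0.0, np.sqrt(2.0 / (width * d)), (width, d, d)
            )
            self.params[f"convb{l}"] = np.zeros(d)

    # -- vocabulary ---------------------------------------------------------
    def token_ids(self, tokens: "tuple[str, ...] | list[str]") -> np.ndarray:
        return np.array([self.vocab.get(t, UNK_ID) for t in tokens], dtype=np.int64)

    # -- forward ------------------------------------------------------------
    def forward_batch(
        self, ids: np.ndarray, mask: np.ndarray, cache: dict | None = None
    ) -> np.ndarray:
        """Batched forward: ids (B, L) -> contextual vectors (B, L, d).

        Padded positions (mask 0) are zeroed before and after each layer so
        padding never leaks into neighbouring windows.
        """
        m = mask[..., None]
        h = self.params["E"][ids] * m
        if cache is not None:
            cache["ids"], cache["mask"], cache["x"] = ids, mask, [h]
        offsets = range(-self.radius, self.radius + 1)
        for l in range(self.n_layers):
            W, b = self.params[f"convW{l}"], self.params[f"convb{l}"]
            z = b + sum(
                _shift(h, o) @ W[oi] for oi, o in enumerate(offsets)
            )
            h = np.maximum(z, 0.0) * m
            if cache is not None:
                cache.setdefault("z", []).append(z)
                cache["x"].append(h)
        return h

    def backward_batch(self, dh: np.ndarray, cache: dict, grads: dict) -> None:
        """Accumulate parameter gradients into ``grads`` given upstream
        gradient ``dh`` on the output of :meth:`forward_batch`."""
        ids, mask = cache["ids"], cache["mask"]
        m = mask[..., None]
        offsets = list(range(-self.radius, self.radius + 1))
        for l in reversed(range(self.n_layers)):
            W = self.params[f"convW{l}"]
            z, x_in = cache["z"][l], cache["x"][l]
            dz = dh * (z > 0) * m
            grads[f"convb{l}"] = grads.get(f"convb{l}", 0) + dz.sum(axis=(0, 1))
            gW = grads.get(f"convW{l}")
            if gW is None:
                gW = np.zeros_like(W)
                grads[f"convW{l}"] = gW
            dh = np.zeros_like(dz)
            for oi, o in enumerate(offsets):
                xs = _shift(x_in, o)
                gW[oi] += np.einsum("bld,ble->de", xs, dz)
                dh += _shift(dz, -o) @ W[oi].T
        dx0 = dh * m
        gE = grads.get("E")
        if gE is None:
            gE = np.zeros_like(self.params["E"])
            grads["E"] = gE
        np.add.at(gE, ids.ravel(), dx0.reshape(-1, self.d))

    def encode(self, tokens: "tuple[str, ...] | list[str]") -> np.ndarray:
        """Encoder-contract entry point: tokens -> (L, d) aligned vectors."""
        ids = self.token_ids(tokens)[None, :]
        mask = np.ones_like(ids, dtype=float)
        return self.forward_batch(ids, mask)[0]


# --------------------------------------------------------------------------
# model bundle + checkpointing
# --------------------------------------------------------------------------

class GlobalPointerModel:
    """Encoder + scoring head + relation schema, checkpointable as one file.

    The checkpoint embeds the relation schema and encoder vocabulary, so
    predictions are reproducible from the file alone.
    """

    def __init__(self, encoder: "CharConvEncoder", scorer: ScorerParams, schema):
        if scorer.K != len(schema):
            raise ValueError("scorer output width does not match schema size")
        if scorer.d != encoder.d:
            raise ValueError("scorer input width does not match encoder width")
        self.encoder = encoder
        self.scorer = scorer
        self.schema = schema

    # unified parameter dict (views, not copies) for generic optimizers
    def parameters(self) -> dict[str, np.ndarray]:
        p = dict(self.encoder.params)
        p["W"], p["b"], p["R_w"] = self.scorer.W, self.scorer.b, self.scorer.R_w
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for name in self.encoder.params:
            self.encoder.params[name] = params[name]
        self.scorer.W, self.scorer.b = params["W"], params["b"]
        self.scorer.R_w = params["R_w"]

    def score_sentence(
        self, sentence: Sentence, training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        emb = encode_sentence(sentence, self.encoder)
        return score_all_pairs(emb, self.scorer, training=training, rng=rng)

    def save(self, path) -> None:
        import json

        meta = {
            "schema": self.schema.to_dict(),
            "vocab": self.encoder.vocab,
            "d": self.encoder.d,
            "n_layers": self.encoder.n_layers,
            "radius": self.encoder.radius,
            "dropout_rate": self.scorer.dropout_rate,
        }
        np.savez(path, _meta=json.dumps(meta), **self.parameters())

    @classmethod
    def load(cls, path) -> "GlobalPointerModel":
        import json

        from .types import RelationSchema

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            arrays = {k: data[k] for k in data.files if k != "_meta"}
        encoder = CharConvEncoder(
            meta["vocab"], d=meta["d"], n_layers=meta["n_layers"], radius=meta["radius"]
        )
        scorer = ScorerParams(
            W=arrays["W"], b=arrays["b"], R_w=arrays["R_w"],
            dropout_rate=meta["dropout_rate"],
        )
        model = cls(encoder, scorer, RelationSchema.from_dict(meta["schema"]))
        model.set_parameters(arrays)
        return model


def build_model(
    schema, vocab: "list[str] | dict[str, int]", d: int = 32, d_e: int = 64,
    n_layers: int = 2, radius: int = 3, dropout_rate: float = 0.5, seed: int = 0,
) -> GlobalPointerModel:
    """Fresh desk-scale model with seeded initialization."""
    rng = np.random.default_rng(seed)
    encoder = CharConvEncoder(vocab, d=d, n_layers=n_layers, radius=radius, rng=rng)
    scorer = ScorerParams.init(
        d=d, K=len(schema), d_e=d_e, dropout_rate=dropout_rate, rng=rng
    )
    return GlobalPointerModel(encoder, scorer, schema)


def encode_sentence(sentence: Sentence, encoder) -> np.ndarray:
    """Run any encoder honouring the contract (``encode(tokens) -> (L, d)``)
    and check the one-vector-per-token alignment."""
    out = np.asarray(encoder.encode(sentence.tokens))
    if out.ndim != 2 or out.shape[0] != sentence.length:
        raise ValueError(
            f"encoder returned shape {out.shape} for sentence of length {sentence.length}"
        )
    return out
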