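"""Synthetic character-level corpora with planted (subject, relation, object)
triples.

The generator emulates the structure of Chinese medical IE corpora in the
CMeIE JSON-lines dialect — character-token sentences, K relation types,
1..5+ triples per sentence, Normal / SingleEntityOverlap / EntityPairOverlap
configurations, nested entities and single-character entities — without any
attempt at fluent text: the extraction scheme operates on spans, not
semantics.

So that a character-level model can actually recover the planted triples
(the parameter-recovery experiment), the vocabulary is partitioned into
disjoint *character classes* carrying (role, relation) assignments:

* a filler class with no role,
* a subject class and an object class per relation k,
* for each relation pair (2m, 2m+1): an EPO subject/object class pair whose
  entities carry *both* relations (entity-pair overlap), and a SEO subject
  class acting as subject of both relations (single-entity overlap, realized
  as one shared subject with two relation-specific objects).

Every planted triple is therefore a deterministic local function of the
characters: relation and role are read off the class, entity boundaries off
the filler separation. Nested entities follow the prefix pattern (the object
is a class-marked prefix of its subject). In the default regime each
relation has at most one subject-role and one object-role run per sentence,
which keeps the tag tensor unambiguous; ``unique_relation_roles=False``
lifts that cap (same-relation multi-pair sentences) for codec stress tests,
where decode ambiguities are handled by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .evaluation import OverlapLabel, classify_overlap
from .tag_codec import decode_tensor, encode_triples
from .types import EntitySpan, RelationSchema, Sentence, Triple

#: rendered characters start here (CJK Unified Ideographs block)
_GLYPH_BASE = 0x4E00

SPECIAL_PATTERNS = (
    "nested",
    "single_char_subject",
    "single_char_object",
    "single_char_both",
)


def _glyph(i: int) -> str:
    return chr(_GLYPH_BASE + i)


@dataclass
class GenConfig:
    """Study conditions for corpus generation.

    Defaults describe a desk-scale corpus: short sentences (max_len 30),
    K=4 relations over a 60-character vocabulary, 1-4 triples per sentence,
    and an overlap mix dominated by SEO (roughly the proportions seen in
    real medical IE corpora, where SEO sentences outnumber Normal ones and
    EPO is rare).
    """

    n_sentences: int = 2000
    K: int = 4
    vocab_size: int = 60
    max_len: int = 30
    entity_len_distribution: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.45, 3: 0.40}
    )
    p_single_char: "float | None" = None  # overrides P(len=1) when set
    triples_per_sentence_distribution: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.20, 4: 0.10}
    )
    pattern_mix: dict = field(
        default_factory=lambda: {"Normal": 0.39, "SEO": 0.60, "EPO": 0.01}
    )
    p_nested: float = 0.10
    reject_cross_triple_collisions: bool = True
    unique_relation_roles: bool = True
    unique_surface_forms: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_sentences < 0 or self.K < 1 or self.max_len < 1:
            raise ValueError("counts must be positive")
        for dist, name in (
            (self.entity_len_distribution, "entity_len_distribution"),
            (self.triples_per_sentence_distribution, "triples_per_sentence_distribution"),
            (self.pattern_mix, "pattern_mix"),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} must be a probability distribution")
        if self.K < 2 and (
            self.pattern_mix.get("SEO", 0) > 0 or self.pattern_mix.get("EPO", 0) > 0
        ):
            raise ValueError("SEO/EPO patterns require at least 2 relations")
        if self.unique_relation_roles:
            too_many = [n for n, p in self.triples_per_sentence_distribution.items()
                        if p > 0 and int(n) > self.K]
            if too_many:
                raise ValueError(
                    f"triple counts {too_many} exceed the K={self.K} capacity of the "
                    "unique-relation-roles regime"
                )
        n_classes = 1 + 2 * self.K + 3 * (self.K // 2)
        if self.vocab_size < 2 * n_classes:
            raise ValueError(
                f"vocab_size {self.vocab_size} too small for {n_classes} character "
                f"classes (need >= {2 * n_classes})"
            )


class CharClasses:
    """Partition of the rendered vocabulary into role-carrying classes."""

    def __init__(self, vocab_size: int, K: int):
        self.K = K
        names = ["filler"]
        names += [f"sub{k}" for k in range(K)]
        names += [f"obj{k}" for k in range(K)]
        for m in range(K // 2):
            names += [f"epo_sub{m}", f"epo_obj{m}", f"seo_sub{m}"]
        per = vocab_size // len(names)
        extra = vocab_size - per * len(names)
        self.chars: dict[str, list[str]] = {}
        idx = 0
        for n in names:
            width = per + (extra if n == "filler" else 0)
            self.chars[n] = [_glyph(i) for i in range(idx, idx + width)]
            idx += width
        self.all_chars = [_glyph(i) for i in range(vocab_size)]

    def sample_string(self, cls: str, length: int, rng: np.random.Generator) -> str:
        pool = self.chars[cls]
        return "".join(rng.choice(pool) for _ in range(length))


def _sample_discrete(dist: dict, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


@dataclass(frozen=True)
class GeneratedExample:
    sentence: Sentence
    triples: frozenset
    patterns: tuple


@dataclass
class _Run:
    """One contiguous non-filler stretch: surface string plus local entity
    spans (local id -> (lo, hi) inclusive offsets within the run)."""

    surface: str
    spans: dict


def _entity_length(config: GenConfig, rng: np.random.Generator) -> int:
    dist = dict(config.entity_len_distribution)
    if config.p_single_char is not None:
        rest = {k: v for k, v in dist.items() if int(k) != 1}
        scale = (1.0 - config.p_single_char) / max(sum(rest.values()), 1e-12)
        dist = {1: config.p_single_char, **{k: v * scale for k, v in rest.items()}}
    return int(_sample_discrete(dist, rng))


def _plant_instance(
    pattern: str,
    rels,
    classes: CharClasses,
    config: GenConfig,
    rng: np.random.Generator,
    special: "str | None" = None,
):
    """Build runs and triple templates for one pattern instance.

    Returns (runs, triples) where triples reference (run_index, local_id).
    ``rels`` is the relation (Normal) or relation pair m (SEO/EPO).
    """
    ent_len = lambda: _entity_length(config, rng)
    if pattern == "Normal":
        k = rels
        nested = special == "nested" or (
            special is None and rng.random() < config.p_nested
        )
        if special == "single_char_subject":
            ls, lo = 1, max(ent_len(), 1)
        elif special == "single_char_object":
            ls, lo = max(ent_len(), 1), 1
        elif special == "single_char_both":
            ls, lo = 1, 1
        else:
            ls, lo = ent_len(), ent_len()
        if nested:
            # object is a class-marked prefix of the subject run
            lo = max(1, min(lo, 3))
            extra = max(1, ls - lo) if ls > lo else max(1, ent_len())
            obj = classes.sample_string(f"obj{k}", lo, rng)
            tail = classes.sample_string(f"sub{k}", extra, rng)
            run = _Run(obj + tail, {"s": (0, lo + extra - 1), "o": (0, lo - 1)})
            return [run], [((0, "s"), k, (0, "o"))]
        sub = _Run(classes.sample_string(f"sub{k}", ls, rng), {"s": (0, ls - 1)})
        obj = _Run(classes.sample_string(f"obj{k}", lo, rng), {"o": (0, lo - 1)})
        return [sub, obj], [((0, "s"), k, (1, "o"))]
    if pattern == "SEO":
        m = rels
        k1, k2 = 2 * m, 2 * m + 1
        ls = 1 if special == "single_char_subject" else ent_len()
        runs = [
            _Run(classes.sample_string(f"seo_sub{m}", ls, rng), {"s": (0, ls - 1)}),
        ]
        for idx, k in enumerate((k1, k2)):
            lo = 1 if special == "single_char_object" else ent_len()
            runs.append(
                _Run(classes.sample_string(f"obj{k}", lo, rng), {"o": (0, lo - 1)})
            )
        return runs, [((0, "s"), k1, (1, "o")), ((0, "s"), k2, (2, "o"))]
    if pattern == "EPO":
        m = rels
        k1, k2 = 2 * m, 2 * m + 1
        ls = 1 if special in ("single_char_subject", "single_char_both") else ent_len()
        lo = 1 if special in ("single_char_object", "single_char_both") else ent_len()
        runs = [
            _Run(classes.sample_string(f"epo_sub{m}", ls, rng), {"s": (0, ls - 1)}),
            _Run(classes.sample_string(f"epo_obj{m}", lo, rng), {"o": (0, lo - 1)}),
        ]
        return runs, [((0, "s"), k1, (1, "o")), ((0, "s"), k2, (1, "o"))]
    raise ValueError(f"unknown pattern {pattern!r}")


def _choose_patterns(n_triples: int, config: GenConfig, rng: np.random.Generator):
    """Pattern instances (name, relation-or-pair) summing to n_triples.

    Tracks relation usage so each relation hosts at most one subject/object
    role pair per sentence (unless unique_relation_roles is off).
    """
    K = config.K
    free_rels = set(range(K))
    instances = []
    remaining = n_triples
    while remaining > 0:
        pat = "Normal" if remaining == 1 else _sample_discrete(config.pattern_mix, rng)
        if pat in ("SEO", "EPO"):
            pairs = [m for m in range(K // 2)
                     if {2 * m, 2 * m + 1} <= free_rels or not config.unique_relation_roles]
            if pairs:
                m = int(rng.choice(pairs))
                free_rels -= {2 * m, 2 * m + 1}
                instances.append((pat, m))
                remaining -= 2
                continue
            pat = "Normal"
        choices = sorted(free_rels) if config.unique_relation_roles else list(range(K))
        if not choices:
            raise RuntimeError("relation capacity exhausted")  # pragma: no cover
        k = int(rng.choice(choices))
        free_rels.discard(k)
        instances.append(("Normal", k))
        remaining -= 1
    return instances


def _assemble(
    runs, triples_tpl, classes: CharClasses, config: GenConfig,
    rng: np.random.Generator, sid: str,
):
    """Order runs, insert filler, and materialize Sentence + gold triples."""
    order = rng.permutation(len(runs))
    base = sum(len(r.surface) for r in runs) + (len(runs) - 1)
    if base > config.max_len:
        return None
    budget = config.max_len - base
    text_parts = []
    offsets = {}
    pos = 0
    lead = int(rng.integers(0, min(2, budget) + 1))
    budget -= lead
    text_parts.append(classes.sample_string("filler", lead, rng))
    pos += lead
    for n, ri in enumerate(order):
        run = runs[ri]
        offsets[ri] = pos
        text_parts.append(run.surface)
        pos += len(run.surface)
        if n < len(runs) - 1:
            gap = 1 + int(rng.integers(0, min(2, budget) + 1))
            budget -= gap - 1
            text_parts.append(classes.sample_string("filler", gap, rng))
            pos += gap
    text = "".join(text_parts)
    gold = set()
    for (rs, ls), k, (ro, lo) in triples_tpl:
        s_lo, s_hi = runs[rs].spans[ls]
        o_lo, o_hi = runs[ro].spans[lo]
        gold.add(
            Triple(
                EntitySpan(offsets[rs] + s_lo, offsets[rs] + s_hi),
                k,
                EntitySpan(offsets[ro] + o_lo, offsets[ro] + o_hi),
            )
        )
    return Sentence.from_text(sid, text), frozenset(gold)


def _surface_forms_unique(text: str, gold, nested_ok: bool = True) -> bool:
    for t in gold:
        for span in (t.subject, t.object):
            s = text[span.head : span.tail + 1]
            if text.count(s) != 1:
                return False
    return True


def _make_sentence(
    sid: str, n_triples: int, classes: CharClasses, config: GenConfig,
    rng: np.random.Generator, special: "str | None" = None,
    forced_pattern: "str | None" = None,
):
    for _ in range(200):
        if forced_pattern is not None:
            if forced_pattern in ("SEO", "EPO"):
                instances = [(forced_pattern, 0)]
            else:
                instances = [("Normal", int(rng.integers(config.K)))]
        else:
            instances = _choose_patterns(n_triples, config, rng)
        runs, tpl = [], []
        for pat, rels in instances:
            r, t = _plant_instance(pat, rels, classes, config, rng, special=special)
            base = len(runs)
            runs.extend(r)
            tpl.extend(((base + rs, ls), k, (base + ro, lo)) for (rs, ls), k, (ro, lo) in t)
        built = _assemble(runs, tpl, classes, config, rng, sid)
        if built is None:
            continue
        sentence, gold = built
        if config.unique_surface_forms and not _surface_forms_unique(sentence.text, gold):
            continue
        if config.reject_cross_triple_collisions:
            M = encode_triples(sentence.length, gold, config.K)
            if decode_tensor(M) != set(gold):
                continue
        return sentence, gold, tuple(sorted({p for p, _ in instances}))
    raise RuntimeError(
        f"could not realize a valid sentence for {sid} (n_triples={n_triples}); "
        "the configuration is likely infeasible"
    )


def plant_pattern(
    pattern: str, config: GenConfig, rng: np.random.Generator, sid: str = "planted",
):
    """One sentence realizing a single overlap pattern or special case.

    ``pattern`` is "Normal", "SEO", "EPO" or one of the special tags
    "nested", "single_char_subject", "single_char_object",
    "single_char_both" (planted on a Normal-pattern triple).
    """
    config.validate()
    classes = CharClasses(config.vocab_size, config.K)
    if pattern in SPECIAL_PATTERNS:
        special = pattern
        forced, n = "Normal", 1
    elif pattern in ("Normal", "SEO", "EPO"):
        special = None
        forced, n = pattern, 1 if pattern == "Normal" else 2
        if pattern in ("SEO", "EPO") and config.K < 2:
            raise ValueError(f"{pattern} requires at least 2 relations")
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    sentence, gold, _ = _make_sentence(
        sid, n, classes, config, rng, special=special, forced_pattern=forced
    )
    return sentence, gold


def relation_schema(config: GenConfig) -> RelationSchema:
    """Relation labels for a generated corpus (stable, index = k)."""
    return RelationSchema([f"rel{k}" for k in range(config.K)])


def vocabulary(config: GenConfig) -> list[str]:
    """The rendered character vocabulary of a config (for encoder tables)."""
    return [_glyph(i) for i in range(config.vocab_size)]


def generate_corpus(config: GenConfig):
    """Generate a corpus of (sentence, gold triples) plus a manifest.

    Deterministic under config.seed. Every sentence is validated at
    generation time: spans in bounds, requested overlap patterns present
    (checked with :func:`gptriple.evaluation.classify_overlap`) and, with
    ``reject_cross_triple_collisions``, exactly round-trippable through the
    tag codec.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = CharClasses(config.vocab_size, config.K)
    examples = []
    pattern_counts: dict[str, int] = {}
    triple_hist: dict[str, int] = {}
    for i in range(config.n_sentences):
        n_triples = int(_sample_discrete(config.triples_per_sentence_distribution, rng))
        sentence, gold, patterns = _make_sentence(
            f"s{i:06d}", n_triples, classes, config, rng
        )
        labels = classify_overlap(gold)
        if "EPO" in patterns:
            assert OverlapLabel.EPO in labels
        if "SEO" in patterns:
            assert OverlapLabel.SEO in labels or OverlapLabel.EPO in labels
        for span in [s for t in gold for s in (t.subject, t.object)]:
            assert span.tail < sentence.length
        examples.append(GeneratedExample(sentence, gold, patterns))
        for p in patterns:
            pattern_counts[p] = pattern_counts.get(p, 0) + 1
        key = str(len(gold)) if len(gold) <= 4 else ">=5"
        triple_hist[key] = triple_hist.get(key, 0) + 1
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_sentences": config.n_sentences,
        "pattern_counts": pattern_counts,
        "triples_per_sentence": triple_hist,
        "relations": relation_schema(config).names,
    }
    return examples, manifest
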