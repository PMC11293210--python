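"""Strict triple-match evaluation and breakdown analyses.

A predicted triple counts as correct only under *strict match*: both entity
spans and the relation must exactly equal a gold triple from the same
sentence. Metrics are micro-averaged over the corpus. Breakdowns follow the
usual analyses for overlapping-triple extraction: by entity-pair overlap
pattern (Normal / SingleEntityOverlap / EntityPairOverlap), by the number of
gold triples in the sentence (1, 2, 3, 4, >=5), and by relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .types import RelationSchema, Triple

TripleSets = Mapping[str, "set[Triple] | frozenset[Triple]"]


class OverlapLabel(str, Enum):
    NORMAL = "Normal"
    SEO = "SEO"  # SingleEntityOverlap: two triples share exactly one span
    EPO = "EPO"  # EntityPairOverlap: two triples share both spans

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Metrics:
    """Micro precision / recall / F1 with the underlying counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def _check_ids(gold: TripleSets, pred: TripleSets) -> None:
    missing = sorted(set(gold) ^ set(pred))
    if missing:
        raise ValueError(f"gold/pred sentence id mismatch: {missing[:10]}")


def strict_match(gold: TripleSets, pred: TripleSets) -> Metrics:
    """Micro-averaged strict-match counts over sentences.

    Triples are sets, so each gold triple matches at most one prediction and
    duplicates cannot inflate the counts.
    """
    _check_ids(gold, pred)
    tp = fp = fn = 0
    for sid in gold:
        g, p = set(gold[sid]), set(pred[sid])
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    return Metrics(tp, fp, fn)


def classify_overlap(triples: Iterable[Triple]) -> set[OverlapLabel]:
    """Overlap pattern labels for one sentence's gold triples.

    EPO: some two distinct triples share both subject and object spans
    (necessarily differing in relation). SEO: some two distinct triples
    share exactly one entity span (in any role combination). Normal: neither
    holds. SEO and EPO can co-occur; Normal excludes both.
    """
    ts = list(set(triples))
    if not ts:
        raise ValueError("classify_overlap requires a nonempty triple set")
    labels: set[OverlapLabel] = set()
    for a in range(len(ts)):
        for b in range(a + 1, len(ts)):
            t1, t2 = ts[a], ts[b]
            if (t1.subject, t1.object) == (t2.subject, t2.object):
                labels.add(OverlapLabel.EPO)
            elif {t1.subject, t1.object} & {t2.subject, t2.object}:
                labels.add(OverlapLabel.SEO)
    if not labels:
        labels.add(OverlapLabel.NORMAL)
    return labels


def bucket_by_triple_count(gold: TripleSets) -> dict[str, list[str]]:
    """Partition sentence ids by gold triple count into {1, 2, 3, 4, >=5}."""
    buckets: dict[str, list[str]] = {"1": [], "2": [], "3": [], "4": [], ">=5": []}
    for sid, ts in gold.items():
        n = len(set(ts))
        key = str(n) if 1 <= n <= 4 else ">=5" if n >= 5 else None
        if key is not None:
            buckets[key].append(sid)
    return buckets


def per_relation_metrics(
    gold: TripleSets, pred: TripleSets, schema: RelationSchema
) -> dict[str, Metrics]:
    """Strict matching restricted to each relation; counts conserve the
    global strict-match counts (every triple has exactly one relation)."""
    _check_ids(gold, pred)
    out: dict[str, Metrics] = {}
    for k, name in enumerate(schema.names):
        g = {sid: {t for t in ts if t.relation == k} for sid, ts in gold.items()}
        p = {sid: {t for t in ts if t.relation == k} for sid, ts in pred.items()}
        out[name] = strict_match(g, p)
    return out


def per_category_metrics(gold: TripleSets, pred: TripleSets) -> dict[str, Metrics]:
    """Strict metrics per overlap category.

    A sentence is counted under every label :func:`classify_overlap` assigns
    to it (a sentence exhibiting both SEO and EPO contributes to both rows).
    Sentences with no gold triples are ignored.
    """
    _check_ids(gold, pred)
    out = {lab.value: Metrics(0, 0, 0) for lab in OverlapLabel}
    for sid in gold:
        if not gold[sid]:
            continue
        m = strict_match({sid: gold[sid]}, {sid: pred[sid]})
        for lab in classify_overlap(gold[sid]):
            out[lab.value] = out[lab.value] + m
    return out


def per_bucket_metrics(gold: TripleSets, pred: TripleSets) -> dict[str, Metrics]:
    """Strict metrics per triples-per-sentence bucket."""
    _check_ids(gold, pred)
    out: dict[str, Metrics] = {}
    for key, sids in bucket_by_triple_count(gold).items():
        out[key] = strict_match({s: gold[s] for s in sids}, {s: pred[s] for s in sids})
    return out


def evaluation_report(
    gold: TripleSets, pred: TripleSets, schema: RelationSchema
) -> dict:
    """Full evaluation report: global, per-category, per-bucket and
    per-relation strict metrics, as a JSON-serializable dict. Relations with
    no gold triples and no predictions are flagged ``absent``."""
    per_rel = {}
    for name, m in per_relation_metrics(gold, pred, schema).items():
        d = m.to_dict()
        d["absent"] = (m.tp + m.fp + m.fn) == 0
        per_rel[name] = d
    return {
        "global": strict_match(gold, pred).to_dict(),
        "by_category": {c: m.to_dict() for c, m in per_category_metrics(gold, pred).items()},
        "by_triple_count": {b: m.to_dict() for b, m in per_bucket_metrics(gold, pred).items()},
        "by_relation": per_rel,
    }
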