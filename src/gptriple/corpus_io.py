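"""CMeIE-style JSON-lines I/O and surface-form span anchoring.

The dialect is one JSON object per line::

    {"text": "...", "spo_list": [
        {"predicate": "...", "subject": "...", "object": {"@value": "..."}},
        ...]}

The public release carries no character offsets, so entity strings must be
*anchored*: located in the text by exact substring search (character/code
point indexing, not bytes). Synthetic corpora are written in the same
dialect plus a sidecar file carrying exact gold spans, so tests can bypass
anchoring entirely. Entity-type fields present in real records are
preserved on the raw record but never modeled — the task is relations over
spans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .types import EntitySpan, RelationSchema, Sentence, Triple

logger = logging.getLogger(__name__)


@dataclass
class SPO:
    predicate: str
    subject: str
    object_value: str


@dataclass
class RawRecord:
    text: str
    spo_list: list
    extras: dict = field(default_factory=dict)


def _parse_record(obj: dict) -> RawRecord:
    text = obj["text"]
    if not text:
        raise ValueError("empty text")
    spo_list = []
    for spo in obj.get("spo_list", []):
        obj_field = spo["object"]
        value = obj_field["@value"] if isinstance(obj_field, dict) else obj_field
        spo_list.append(SPO(spo["predicate"], spo["subject"], value))
    extras = {k: v for k, v in obj.items() if k not in ("text", "spo_list")}
    return RawRecord(text=text, spo_list=spo_list, extras=extras)


def read_jsonl(path, schema: RelationSchema) -> list:
    """Read records in file order.

    Malformed lines are skipped with logged line numbers; predicates absent
    from the schema are kept on the record but reported once, with counts.
    A file with zero parseable lines is an error.
    """
    path = Path(path)
    records: list[RawRecord] = []
    unknown: dict[str, int] = {}
    bad_lines: list[int] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = _parse_record(json.loads(line))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                bad_lines.append(lineno)
                continue
            for spo in rec.spo_list:
                if spo.predicate not in schema:
                    unknown[spo.predicate] = unknown.get(spo.predicate, 0) + 1
            records.append(rec)
    if bad_lines:
        logger.warning("%s: skipped %d malformed lines: %s",
                       path, len(bad_lines), bad_lines[:20])
    if unknown:
        logger.warning("%s: predicates not in schema (dropped at anchoring): %s",
                       path, unknown)
    if not records:
        raise ValueError(f"{path}: no parseable records")
    return records


def _occurrences(text: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = text.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def anchor_spans(
    record: RawRecord,
    schema: RelationSchema,
    sentence_id: str = "r0",
    policy: str = "first",
):
    """Locate entity strings in the text; returns (Sentence, gold triples,
    n_dropped).

    ``policy`` "first" anchors each entity at its first occurrence; "all"
    emits one triple per (subject occurrence, object occurrence) pair.
    Triples whose entity string or predicate cannot be resolved are dropped
    with a logged reason; a record losing every triple is retained with an
    empty gold set.
    """
    if policy not in ("first", "all"):
        raise ValueError(f"unknown anchoring policy {policy!r}")
    sentence = Sentence.from_text(sentence_id, record.text)
    gold: set[Triple] = set()
    dropped = 0
    for spo in record.spo_list:
        if spo.predicate not in schema:
            logger.debug("%s: unknown predicate %r dropped", sentence_id, spo.predicate)
            dropped += 1
            continue
        subs = _occurrences(record.text, spo.subject)
        objs = _occurrences(record.text, spo.object_value)
        if not subs or not objs or not spo.subject or not spo.object_value:
            logger.debug("%s: entity not found for %r", sentence_id, spo)
            dropped += 1
            continue
        if policy == "first":
            subs, objs = subs[:1], objs[:1]
        k = schema.index(spo.predicate)
        for si in subs:
            for oi in objs:
                gold.add(
                    Triple(
                        EntitySpan(si, si + len(spo.subject) - 1),
                        k,
                        EntitySpan(oi, oi + len(spo.object_value) - 1),
                    )
                )
    if dropped and not gold:
        logger.warning("%s: all %d triples dropped at anchoring", sentence_id, dropped)
    return sentence, gold, dropped


def _record_dict(sentence: Sentence, triples, schema: RelationSchema) -> dict:
    text = sentence.text
    return {
        "text": text,
        "spo_list": [
            {
                "predicate": schema.label(t.relation),
                "subject": text[t.subject.head : t.subject.tail + 1],
                "object": {"@value": text[t.object.head : t.object.tail + 1]},
            }
            for t in sorted(triples)
        ],
    }


def write_predictions(sentences, predictions: dict, schema: RelationSchema, path) -> None:
    """Write (sentence, predicted triples) in the JSON-lines dialect;
    surface forms are sliced from the text, so write -> read is lossless at
    the surface-form level."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps(_record_dict(s, predictions.get(s.id, set()), schema),
                                ensure_ascii=False) + "\n")


def write_corpus(examples, schema: RelationSchema, path, sidecar_path=None) -> None:
    """Write a generated corpus in the dialect, plus an optional sidecar of
    exact gold spans (JSON lines: id, text, triples with 0-based inclusive
    spans and relation labels)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(json.dumps(_record_dict(ex.sentence, ex.triples, schema),
                                ensure_ascii=False) + "\n")
    if sidecar_path is not None:
        with Path(sidecar_path).open("w", encoding="utf-8") as fh:
            for ex in examples:
                rec = {
                    "id": ex.sentence.id,
                    "text": ex.sentence.text,
                    "triples": [
                        {
                            "subject": [t.subject.head, t.subject.tail],
                            "relation": schema.label(t.relation),
                            "object": [t.object.head, t.object.tail],
                        }
                        for t in sorted(ex.triples)
                    ],
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_sidecar(path, schema: RelationSchema):
    """Read a sidecar file back into (Sentence, gold triples) pairs."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            triples = {
                Triple(
                    EntitySpan(*t["subject"]),
                    schema.index(t["relation"]),
                    EntitySpan(*t["object"]),
                )
                for t in rec["triples"]
            }
            out.append((Sentence.from_text(rec["id"], rec["text"]), triples))
    return out
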