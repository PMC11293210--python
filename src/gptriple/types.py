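"""Core domain types for span-based joint entity-relation extraction.

A *triple* is a (subject entity, relation, object entity) fact asserted by a
single sentence. Entities are contiguous character spans, stored 0-based and
inclusive at both ends, so a single-character entity has ``head == tail``.
Sentences are sequences of atomic character tokens (Chinese clinical text has
no whitespace word boundaries, so the character is the token).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Contiguous token span, 0-based, inclusive on both ends."""

    head: int
    tail: int

    def __post_init__(self) -> None:
        if self.head < 0 or self.tail < self.head:
            raise ValueError(f"invalid span ({self.head}, {self.tail})")

    @property
    def is_single_char(self) -> bool:
        return self.head == self.tail

    def __len__(self) -> int:
        return self.tail - self.head + 1

    def contains(self, other: "EntitySpan") -> bool:
        """True if *other* lies strictly inside this span (nested entity)."""
        return (
            self.head <= other.head
            and other.tail <= self.tail
            and (self.head, self.tail) != (other.head, other.tail)
        )


@dataclass(frozen=True, order=True)
class Triple:
    """(subject span, relation index, object span); equality is component-wise."""

    subject: EntitySpan
    relation: int
    object: EntitySpan


@dataclass(frozen=True)
class Sentence:
    """Character-token sequence with a stable identifier."""

    id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError(f"sentence {self.id!r} has no tokens")
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    @classmethod
    def from_text(cls, id: str, text: str) -> "Sentence":
        return cls(id=id, tokens=tuple(text))


class RelationSchema:
    """Ordered relation label set; indices are stable for a run and are
    serialized alongside model parameters."""

    def __init__(self, names: Sequence[str]):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("relation labels must be unique")
        if not names:
            raise ValueError("relation schema must be nonempty")
        self.names: list[str] = names
        self._index: dict[str, int] = {n: k for k, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    @property
    def K(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"relation label {label!r} not in schema") from None

    def label(self, k: int) -> str:
        return self.names[k]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RelationSchema) and self.names == other.names

    def to_dict(self) -> dict:
        return {"names": list(self.names)}

    @classmethod
    def from_dict(cls, d: dict) -> "RelationSchema":
        return cls(d["names"])


def validate_triples(triples: Iterable[Triple], L: int, K: int) -> None:
    """Raise ValueError if any span or relation index is out of range."""
    for t in triples:
        for span in (t.subject, t.object):
            if span.tail >= L:
                raise ValueError(f"span {span} out of range for sentence length {L}")
        if not (0 <= t.relation < K):
            raise ValueError(f"relation index {t.relation} out of range for K={K}")
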