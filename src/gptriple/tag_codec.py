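"""Single-module global-pointer tag codec.

All entity and relation link information for a sentence of length ``L`` under
``K`` relation types is stored in one ``L x K x L`` integer tensor ``M``:
rows index subject positions, columns index object positions, and each cell
holds one of four link tags:

* tag 1 — subject head -> object head,
* tag 2 — subject tail -> object tail,
* tag 3 — subject head -> object tail,
* tag 0 — background (no link).

A multi-character subject paired with a multi-character object writes three
distinct cells. Single-character entities collapse some of those cells onto
each other (e.g. a single-character object makes the tag-1 and tag-3 cells
coincide); collisions are resolved by a fixed total priority order
``1 > 2 > 3 > 0``, so the tag-3 cell of a single-character-object pair is
overwritten by tag 1. Decoding handles the four single/multi-character
combinations as separate cases with explicit absence guards so each tag
pattern is consumed by exactly one case.

The codec is lossy across triples in pathological configurations: one
triple's cell can overwrite another's (cross-triple collision), and two
same-relation triples sharing a subject span create a spurious decodable
cross-join. This is inherent to the single-tensor scheme; the synthetic
corpus generator can reject such sentences (see
:mod:`gptriple.synthetic_data`).
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np

from .types import EntitySpan, Triple, validate_triples

#: higher value = higher priority when two link types hit the same cell
_PRIORITY = {0: 0, 3: 1, 2: 2, 1: 3}

VALID_TAGS = frozenset((0, 1, 2, 3))


def resolve_collision(existing_tag: int, incoming_tag: int) -> int:
    """Winner of two tags competing for one cell, under ``1 > 2 > 3 > 0``.

    Commutative: the final cell value does not depend on write order.
    """
    for t in (existing_tag, incoming_tag):
        if t not in VALID_TAGS:
            raise ValueError(f"invalid tag {t!r}; tags are 0, 1, 2 or 3")
    return max(existing_tag, incoming_tag, key=_PRIORITY.__getitem__)


def triple_cells(t: Triple) -> dict[tuple[int, int, int], int]:
    """Cells one triple writes, with intra-triple collisions resolved.

    Base pattern: (s.head, k, o.head) <- 1, (s.tail, k, o.tail) <- 2,
    (s.head, k, o.tail) <- 3. Coincident cells (single-character entities)
    keep the higher-priority tag.
    """
    cells: dict[tuple[int, int, int], int] = {}
    writes = (
        ((t.subject.head, t.relation, t.object.head), 1),
        ((t.subject.tail, t.relation, t.object.tail), 2),
        ((t.subject.head, t.relation, t.object.tail), 3),
    )
    for cell, tag in writes:
        cells[cell] = resolve_collision(cells.get(cell, 0), tag)
    return cells


def encode_triples(L: int, triples: Iterable[Triple], K: int) -> np.ndarray:
    """Encode gold triples into the ``L x K x L`` tag tensor.

    Collisions are resolved by priority both within a triple and across
    triples. The empty triple set encodes to the all-zero tensor.
    """
    triples = list(triples)
    validate_triples(triples, L, K)
    M = np.zeros((L, K, L), dtype=np.int8)
    for t in triples:
        for (i, k, j), tag in triple_cells(t).items():
            M[i, k, j] = resolve_collision(int(M[i, k, j]), tag)
    return M


def _check_tensor(tags: np.ndarray) -> np.ndarray:
    tags = np.asarray(tags)
    if tags.ndim != 3:
        raise ValueError(f"tag tensor must be 3-dimensional, got shape {tags.shape}")
    if not np.isin(tags, (0, 1, 2, 3)).all():
        raise ValueError("tag tensor contains values outside {0,1,2,3}")
    return tags


def decode_tensor(tags: np.ndarray) -> set[Triple]:
    """Decode a tag tensor into the set of triples it encodes.

    Per relation matrix, four guard-ordered cases are applied; a cell
    participates in the most specific applicable case:

    A. general: tag 3 at (sh, ot) anchors the pair; tag 1 in the same row at
       (sh, oh), oh <= ot, gives the object head; tag 2 in the same column at
       (st, ot), st >= sh, gives the subject tail.
    B. single-character object: tag 1 and tag 2 in the same column j (the
       tag-3 cell was overwritten by tag 1) -> object (j, j).
    C. single-character subject: tag 1 and tag 2 in the same row sh (the
       tag-3 cell was overwritten by tag 2) -> subject (sh, sh).
    D. both single-character: a tag 1 at (sh, j) with no tag 2 in column j,
       no tag 2 in row sh and no tag 3 in row sh -> ((sh,sh), k, (j,j)).

    Malformed patterns simply yield fewer triples, never an exception.
    """
    tags = _check_tensor(tags)
    L, K, _ = tags.shape
    out: set[Triple] = set()
    for k in range(K):
        m = tags[:, k, :]
        ones = np.argwhere(m == 1)
        twos = np.argwhere(m == 2)
        threes = np.argwhere(m == 3)
        rows_with_3 = set(threes[:, 0].tolist())
        rows_with_2 = set(twos[:, 0].tolist())
        cols_with_2 = set(twos[:, 1].tolist())

        # A: full three-tag pattern
        for sh, ot in threes:
            heads = ones[(ones[:, 0] == sh) & (ones[:, 1] <= ot)]
            tails = twos[(twos[:, 1] == ot) & (twos[:, 0] >= sh)]
            for _, oh in heads:
                for st, _ in tails:
                    out.add(
                        Triple(EntitySpan(int(sh), int(st)), k, EntitySpan(int(oh), int(ot)))
                    )

        # B: single-character object — tag 1 above tag 2 in one column
        for sh, j in ones:
            tails = twos[(twos[:, 1] == j) & (twos[:, 0] >= sh)]
            for st, _ in tails:
                out.add(
                    Triple(EntitySpan(int(sh), int(st)), k, EntitySpan(int(j), int(j)))
                )

        # C: single-character subject — tag 1 left of tag 2 in one row
        for sh, oh in ones:
            tails = twos[(twos[:, 0] == sh) & (twos[:, 1] >= oh)]
            for _, ot in tails:
                out.add(
                    Triple(EntitySpan(int(sh), int(sh)), k, EntitySpan(int(oh), int(ot)))
                )

        # D: both single-character — a lone tag 1
        for sh, j in ones:
            if int(j) in cols_with_2 or int(sh) in rows_with_2 or int(sh) in rows_with_3:
                continue
            out.add(Triple(EntitySpan(int(sh), int(sh)), k, EntitySpan(int(j), int(j))))
    return out


def oracle_decode(tags: np.ndarray) -> set[Triple]:
    """Brute-force reference decoder.

    Enumerates every candidate ((sh,st), k, (oh,ot)) with sh <= st,
    oh <= ot and emits it iff each cell of its collision-resolved encoding
    pattern (:func:`triple_cells`) holds exactly the expected tag — plus, for
    the both-single-character candidate, whose pattern is a lone tag 1, the
    absence guards that prevent a tag 1 belonging to a multi-character pair
    from being read as a standalone triple.

    Set-equal to :func:`decode_tensor` on every input; kept deliberately
    naive (O(L^4 K)) for use as a test oracle.
    """
    tags = _check_tensor(tags)
    L, K, _ = tags.shape
    out: set[Triple] = set()
    for k in range(K):
        m = tags[:, k, :]
        for sh in range(L):
            for oh in range(L):
                # tag 1 wins every collision, so the (sh, oh) cell must hold
                # a 1 for any candidate — cheap necessary condition
                if m[sh, oh] != 1:
                    continue
                for st in range(sh, L):
                    for ot in range(oh, L):
                        cand = Triple(EntitySpan(sh, st), k, EntitySpan(oh, ot))
                        cells = triple_cells(cand)
                        if any(int(m[i, j]) != tag for (i, _, j), tag in cells.items()):
                            continue
                        if sh == st and oh == ot:
                            row, col = m[sh, :], m[:, ot]
                            if (row == 2).any() or (row == 3).any() or (col == 2).any():
                                continue
                        out.add(cand)
    return out


# --- sparse JSON serialization -------------------------------------------

def tensor_to_sparse(tags: np.ndarray) -> str:
    """Serialize a tag tensor to a JSON string of nonzero (row, relation,
    col, tag) records plus the dimensions; round-trips losslessly."""
    tags = _check_tensor(tags)
    L, K, _ = tags.shape
    cells = [
        [int(i), int(k), int(j), int(tags[i, k, j])]
        for i, k, j in np.argwhere(tags != 0)
    ]
    return json.dumps({"L": L, "K": K, "cells": cells})


def sparse_to_tensor(payload: str) -> np.ndarray:
    d = json.loads(payload)
    M = np.zeros((d["L"], d["K"], d["L"]), dtype=np.int8)
    for i, k, j, tag in d["cells"]:
        if tag not in VALID_TAGS:
            raise ValueError(f"invalid tag {tag!r} in sparse record")
        M[i, k, j] = tag
    return M
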