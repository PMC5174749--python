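"""Candidate-instance construction: tokenization, pair enumeration,
entity blinding, and the two lexical noise filters.

A sentence with *n* entity mentions yields C(n,2) candidate pairs.  For
each pair the two target mentions are blinded to ``Entity1`` / ``Entity2``
(in document order) and every other mention to ``EntityOther``, so the
classifier generalizes over entity names rather than memorizing them.

Two filters remove pairs that are almost never true interactions:

* Rule 1 — the two mentions are the same name, or one abbreviates the
  other (case-folded equality, a parenthesized short form immediately
  following the long form, or an initial-letter acronym);
* Rule 2 — the pair sits inside a coordinate list ("A, B and C"): every
  token strictly between the two blinded targets is a comma, "and",
  "or", or another (blinded) entity, with at least one such separator.

Filters default off for PPI-style binary corpora, where the corpora are
small and every pair is informative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .corpus_io import AnnotatedSentence, GoldPair, EntityMention

ENTITY1 = "Entity1"
ENTITY2 = "Entity2"
ENTITY_OTHER = "EntityOther"

_COORD_SEPARATORS = {",", "and", "or"}
_WORD_RE = re.compile(r"\w+|[^\w\s]")

__all__ = [
    "Instance",
    "Token",
    "tokenize",
    "enumerate_pairs",
    "blind",
    "rule1_same_name_or_abbrev",
    "rule2_coordinate_structure",
    "build_dataset",
    "filter_report",
]


@dataclass(frozen=True)
class Token:
    """A token with its character span (0-based inclusive) and, where the
    token covers an entity mention, that mention's id."""

    text: str
    char_start: int
    char_end: int
    entity_id: str | None = None


@dataclass(frozen=True)
class Instance:
    """One blinded candidate: the classifier's unit of input.

    Exactly one token is ``Entity1`` and one ``Entity2``, with Entity1
    first in document order.  ``filtered`` records why the instance was
    removed ("rule1"/"rule2") or "none" if kept.
    """

    sentence_id: str
    e1_id: str
    e2_id: str
    tokens: tuple[str, ...]
    label: str
    filtered: str = "none"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("instance token list is empty")
        if self.tokens.count(ENTITY1) != 1 or self.tokens.count(ENTITY2) != 1:
            raise ValueError(
                "instance must contain exactly one Entity1 and one Entity2"
            )
        if self.tokens.index(ENTITY1) > self.tokens.index(ENTITY2):
            raise ValueError("Entity1 must precede Entity2 in document order")


def tokenize(sentence: AnnotatedSentence) -> list[Token]:
    """Tokenize a sentence, collapsing each entity mention to one token.

    Multiword mentions become a single token covering their whole span.
    The remaining text splits on whitespace and punctuation boundaries.
    Token spans partition the sentence's non-whitespace characters in
    order.
    """
    ents = sorted(sentence.entities, key=lambda e: (e.char_start, e.char_end))
    for prev, nxt in zip(ents, ents[1:]):
        if nxt.char_start <= prev.char_end:
            raise ValueError(
                f"entity {nxt.id!r} overlaps collapsed entity {prev.id!r} "
                f"in sentence {sentence.id!r}"
            )
    tokens: list[Token] = []
    cursor = 0
    text = sentence.text

    def _plain(segment: str, offset: int) -> None:
        for m in _WORD_RE.finditer(segment):
            tokens.append(
                Token(m.group(), offset + m.start(), offset + m.end() - 1)
            )

    for ent in ents:
        _plain(text[cursor : ent.char_start], cursor)
        tokens.append(
            Token(
                text[ent.char_start : ent.char_end + 1],
                ent.char_start,
                ent.char_end,
                entity_id=ent.id,
            )
        )
        cursor = ent.char_end + 1
    _plain(text[cursor:], cursor)
    return tokens


def enumerate_pairs(sentence: AnnotatedSentence) -> list[tuple[EntityMention, EntityMention]]:
    """All C(n,2) unordered entity pairs, ordered by document position."""
    ents = sorted(sentence.entities, key=lambda e: (e.char_start, e.char_end))
    return [(a, b) for i, a in enumerate(ents) for b in ents[i + 1 :]]


def blind(
    tokens: Sequence[Token],
    pair: tuple[EntityMention, EntityMention],
    sentence_id: str = "",
    label: str = "negative",
) -> Instance:
    """Replace the target pair by Entity1/Entity2 and every other mention
    by EntityOther; non-entity tokens pass through unchanged."""
    e1, e2 = sorted(pair, key=lambda e: e.char_start)
    ids = {t.entity_id for t in tokens if t.entity_id is not None}
    for ent in (e1, e2):
        if ent.id not in ids:
            raise ValueError(f"pair entity {ent.id!r} not found in token spans")
    out = []
    for tok in tokens:
        if tok.entity_id == e1.id:
            out.append(ENTITY1)
        elif tok.entity_id == e2.id:
            out.append(ENTITY2)
        elif tok.entity_id is not None:
            out.append(ENTITY_OTHER)
        else:
            out.append(tok.text)
    return Instance(
        sentence_id=sentence_id,
        e1_id=e1.id,
        e2_id=e2.id,
        tokens=tuple(out),
        label=label,
    )


def _acronym(words: Sequence[str]) -> str:
    return "".join(w[0] for w in words if w)


def rule1_same_name_or_abbrev(
    e1: EntityMention, e2: EntityMention, sentence: AnnotatedSentence
) -> bool:
    """True if the pair should be removed as a same-name/abbreviation pair."""
    s1 = e1.surface.strip().casefold()
    s2 = e2.surface.strip().casefold()
    if s1 == s2:
        return True
    # "long form (SHORT)" — short form parenthesized right after the long one
    first, second = sorted((e1, e2), key=lambda e: e.char_start)
    between = sentence.text[first.char_end + 1 : second.char_start].strip()
    after = sentence.text[second.char_end + 1 : second.char_end + 2]
    if between == "(" and after == ")":
        return True
    if _acronym(s1.split()) == s2 or _acronym(s2.split()) == s1:
        return True
    return False


def rule2_coordinate_structure(instance: Instance) -> bool:
    """True if the pair should be removed as part of a coordinate list.

    Every token strictly between Entity1 and Entity2 must be a comma,
    "and", "or", or another entity, and at least one such separator must
    be present (adjacent entities with nothing between them are kept).
    """
    i1 = instance.tokens.index(ENTITY1)
    i2 = instance.tokens.index(ENTITY2)
    between = instance.tokens[i1 + 1 : i2]
    if not between:
        return False
    allowed = _COORD_SEPARATORS | {ENTITY_OTHER}
    return all(tok.casefold() in allowed or tok == ENTITY_OTHER for tok in between)


def build_dataset(
    sentences: Iterable[AnnotatedSentence],
    apply_filters: bool = True,
) -> tuple[list[Instance], list[Instance]]:
    """Enumerate, blind, and optionally filter every candidate pair.

    Returns ``(kept, removed)``; the two lists partition all enumerated
    pairs, and each removed instance records its removal reason.  Gold
    labels come from the sentence's pair annotations; an unannotated
    candidate pair is labeled negative.
    """
    kept: list[Instance] = []
    removed: list[Instance] = []
    for sent in sentences:
        tokens = tokenize(sent)
        gold = {frozenset((p.e1_id, p.e2_id)): p.label for p in sent.pairs}
        for e1, e2 in enumerate_pairs(sent):
            label = gold.get(frozenset((e1.id, e2.id)), "negative")
            inst = blind(tokens, (e1, e2), sentence_id=sent.id, label=label)
            if apply_filters and rule1_same_name_or_abbrev(e1, e2, sent):
                removed.append(replace(inst, filtered="rule1"))
            elif apply_filters and rule2_coordinate_structure(inst):
                removed.append(replace(inst, filtered="rule2"))
            else:
                kept.append(inst)
    return kept, removed


def filter_report(kept: Sequence[Instance], removed: Sequence[Instance]) -> str:
    """Per-label kept/removed counts as an aligned text table."""
    labels = sorted({i.label for i in kept} | {i.label for i in removed})
    lines = [f"{'label':<12}{'kept':>8}{'rule1':>8}{'rule2':>8}"]
    for lab in labels:
        k = sum(1 for i in kept if i.label == lab)
        r1 = sum(1 for i in removed if i.label == lab and i.filtered == "rule1")
        r2 = sum(1 for i in removed if i.label == lab and i.filtered == "rule2")
        lines.append(f"{lab:<12}{k:>8}{r1:>8}{r2:>8}")
    lines.append(
        f"{'total':<12}{len(kept):>8}"
        f"{sum(1 for i in removed if i.filtered == 'rule1'):>8}"
        f"{sum(1 for i in removed if i.filtered == 'rule2'):>8}"
    )
    return "\n".join(lines)
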