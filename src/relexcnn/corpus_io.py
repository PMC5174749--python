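"""Readers and writers for relation-extraction corpora.

Two XML dialects are supported:

* ``ddi2013`` — the DDIExtraction 2013 challenge layout
  (``document/sentence/entity/pair`` elements, ``charOffset`` attributes,
  five-way labels advice/effect/mechanism/int/negative);
* ``ppi_learning_format`` — the unified PPI "learning format"
  (sentences with entity and binary interaction-pair elements).

Plus an internal line-delimited JSON instance format used between the
preprocessing and training stages.

Character offsets are 0-based inclusive ``[start, end]``, as in the DDI
dialect's ``charOffset`` attribute.  Discontinuous offsets
(semicolon-separated spans) keep only the first span, with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

DDI_LABELS = ("advice", "effect", "mechanism", "int", "negative")
PPI_LABELS = ("positive", "negative")

__all__ = [
    "EntityMention",
    "GoldPair",
    "AnnotatedSentence",
    "CorpusFormatError",
    "DDI_LABELS",
    "PPI_LABELS",
    "read_relation_xml",
    "write_relation_xml",
    "read_instances",
    "write_instances",
]


class CorpusFormatError(ValueError):
    """Malformed corpus file: bad XML, bad offsets, or unknown labels."""


@dataclass(frozen=True)
class EntityMention:
    """A single entity annotation inside one sentence.

    ``char_start``/``char_end`` are 0-based inclusive offsets into the
    sentence text; ``surface`` must equal the substring they select.
    """

    id: str
    surface: str
    char_start: int
    char_end: int
    etype: str = "drug"

    def validate(self, text: str, sentence_id: str) -> None:
        if not (0 <= self.char_start <= self.char_end < len(text)):
            raise CorpusFormatError(
                f"entity {self.id!r} offsets [{self.char_start}, {self.char_end}] "
                f"outside sentence {sentence_id!r} (length {len(text)})"
            )
        span = text[self.char_start : self.char_end + 1]
        if span != self.surface:
            raise CorpusFormatError(
                f"entity {self.id!r} surface {self.surface!r} does not match "
                f"text span {span!r} in sentence {sentence_id!r}"
            )


@dataclass(frozen=True)
class GoldPair:
    """A labeled candidate pair of entity ids within one sentence."""

    e1_id: str
    e2_id: str
    label: str


@dataclass
class AnnotatedSentence:
    """A tokenizable sentence with entity mentions and gold pair labels."""

    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    pairs: list[GoldPair] = field(default_factory=list)

    def entity_by_id(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(f"entity {eid!r} not found in sentence {self.id!r}")

    def validate(self) -> None:
        seen: set[str] = set()
        for ent in self.entities:
            if ent.id in seen:
                raise CorpusFormatError(
                    f"duplicate entity id {ent.id!r} in sentence {self.id!r}"
                )
            seen.add(ent.id)
            ent.validate(self.text, self.id)
        for pair in self.pairs:
            if pair.e1_id == pair.e2_id:
                raise CorpusFormatError(
                    f"self-pair {pair.e1_id!r} in sentence {self.id!r}"
                )
            for eid in (pair.e1_id, pair.e2_id):
                if eid not in seen:
                    raise CorpusFormatError(
                        f"pair references unknown entity {eid!r} "
                        f"in sentence {self.id!r}"
                    )


def _parse_char_offset(raw: str, entity_id: str) -> tuple[int, int]:
    # "12-18" or discontinuous "12-18;25-30": keep the first span only.
    if ";" in raw:
        warnings.warn(
            f"entity {entity_id!r}: discontinuous offset {raw!r}; "
            "keeping first span",
            stacklevel=3,
        )
        raw = raw.split(";", 1)[0]
    try:
        start_s, end_s = raw.split("-", 1)
        return int(start_s), int(end_s)
    except ValueError as exc:
        raise CorpusFormatError(
            f"entity {entity_id!r}: cannot parse charOffset {raw!r}"
        ) from exc


def _parse_ddi_sentence(elem: etree._Element) -> AnnotatedSentence:
    sid = elem.get("id", "")
    text = elem.get("text", "")
    entities = []
    for ent in elem.findall("entity"):
        eid = ent.get("id", "")
        start, end = _parse_char_offset(ent.get("charOffset", ""), eid)
        entities.append(
            EntityMention(
                id=eid,
                surface=ent.get("text", ""),
                char_start=start,
                char_end=end,
                etype=ent.get("type", "drug"),
            )
        )
    pairs = []
    for pair in elem.findall("pair"):
        label = pair.get("type")
        if label is None:
            # non-interacting pairs carry ddi="false" and no type attribute
            label = "negative" if pair.get("ddi", "false") == "false" else "int"
        pairs.append(GoldPair(pair.get("e1", ""), pair.get("e2", ""), label))
    sentence = AnnotatedSentence(id=sid, text=text, entities=entities, pairs=pairs)
    sentence.validate()
    return sentence


def _parse_ppi_sentence(elem: etree._Element) -> AnnotatedSentence:
    sid = elem.get("id", "")
    text = elem.get("text", "")
    entities = []
    for ent in elem.findall("entity"):
        eid = ent.get("id", "")
        start, end = _parse_char_offset(ent.get("charOffset", ""), eid)
        entities.append(
            EntityMention(
                id=eid,
                surface=ent.get("text", ""),
                char_start=start,
                char_end=end,
                etype=ent.get("type", "protein"),
            )
        )
    pairs = []
    for pair in elem.findall("interaction") + elem.findall("pair"):
        flag = pair.get("interaction", pair.get("type", "false"))
        label = "positive" if flag in ("true", "positive", "True") else "negative"
        pairs.append(GoldPair(pair.get("e1", ""), pair.get("e2", ""), label))
    sentence = AnnotatedSentence(id=sid, text=text, entities=entities, pairs=pairs)
    sentence.validate()
    return sentence


def read_relation_xml(path: str | Path, dialect: str = "ddi2013") -> list[AnnotatedSentence]:
    """Parse a corpus file into :class:`AnnotatedSentence` objects.

    Parameters
    ----------
    path:
        XML file in the chosen dialect.
    dialect:
        ``"ddi2013"`` or ``"ppi_learning_format"``.

    The number of pairs returned per sentence equals the number of pair
    elements in the file; pairs are never inferred here (for PPI corpora
    that lack explicit negatives, pair enumeration happens during
    preprocessing).
    """
    if dialect not in ("ddi2013", "ppi_learning_format"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc
    parse = _parse_ddi_sentence if dialect == "ddi2013" else _parse_ppi_sentence
    return [parse(elem) for elem in tree.iter("sentence")]


def write_relation_xml(
    sentences: Iterable[AnnotatedSentence],
    path: str | Path,
    dialect: str = "ddi2013",
    document_id: str = "d0",
) -> None:
    """Serialize sentences to XML; inverse of :func:`read_relation_xml`."""
    root = etree.Element("corpus" if dialect == "ddi2013" else "corpus")
    doc = etree.SubElement(root, "document", id=document_id)
    for sent in sentences:
        s_el = etree.SubElement(doc, "sentence", id=sent.id, text=sent.text)
        for ent in sent.entities:
            etree.SubElement(
                s_el,
                "entity",
                id=ent.id,
                charOffset=f"{ent.char_start}-{ent.char_end}",
                type=ent.etype,
                text=ent.surface,
            )
        for pair in sent.pairs:
            attrs = {"e1": pair.e1_id, "e2": pair.e2_id}
            if dialect == "ddi2013":
                if pair.label == "negative":
                    attrs["ddi"] = "false"
                else:
                    attrs["ddi"] = "true"
                    attrs["type"] = pair.label
            else:
                attrs["interaction"] = "true" if pair.label == "positive" else "false"
            etree.SubElement(s_el, "pair", **attrs)
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# internal line-delimited instance format

_HEADER = {"format": "relexcnn-instances", "version": 1}


def write_instances(instances: Sequence, path: str | Path) -> None:
    """Write instances as line-delimited JSON with a header line.

    Each record carries sentence id, entity ids, blinded token symbols and
    the class label, so the file round-trips losslessly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_HEADER) + "\n")
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "sentence_id": inst.sentence_id,
                        "e1": inst.e1_id,
                        "e2": inst.e2_id,
                        "tokens": list(inst.tokens),
                        "label": inst.label,
                        "filtered": inst.filtered,
                    }
                )
                + "\n"
            )


def read_instances(path: str | Path, labels: Sequence[str] | None = None) -> list:
    """Read the line-delimited instance format written by :func:`write_instances`.

    If ``labels`` is given, any record whose label falls outside that closed
    set raises :class:`CorpusFormatError`.
    """
    from .preprocess import Instance  # deferred: avoid import cycle

    out: list[Instance] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip():
            head = json.loads(header)
            if head.get("format") != _HEADER["format"]:
                raise CorpusFormatError(f"{path}: not an instance file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            rec = json.loads(line)
            if labels is not None and rec["label"] not in labels:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown label {rec['label']!r}"
                )
            out.append(
                Instance(
                    sentence_id=rec["sentence_id"],
                    e1_id=rec["e1"],
                    e2_id=rec["e2"],
                    tokens=tuple(rec["tokens"]),
                    label=rec["label"],
                    filtered=rec.get("filtered", "none"),
                )
            )
    return out
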