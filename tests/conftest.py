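"""Shared fixtures: hand-built DDI sentences for the worked examples and
small helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from relexcnn.corpus_io import AnnotatedSentence, EntityMention, GoldPair


def make_sentence(
    sid: str, text: str, entity_specs: list[tuple[str, str]], pairs=None
) -> AnnotatedSentence:
    """Build a sentence, locating each (id, surface) left to right.

    Repeated surfaces resolve to successive occurrences.
    """
    entities = []
    cursor_by_surface: dict[str, int] = {}
    for eid, surface in entity_specs:
        start = text.index(surface, cursor_by_surface.get(surface.casefold(), 0))
        cursor_by_surface[surface.casefold()] = start + 1
        entities.append(
            EntityMention(
                id=eid,
                surface=surface,
                char_start=start,
                char_end=start + len(surface) - 1,
            )
        )
    sent = AnnotatedSentence(
        id=sid, text=text, entities=entities, pairs=list(pairs or [])
    )
    sent.validate()
    return sent


@pytest.fixture
def nsaid_sentence() -> AnnotatedSentence:
    """Three drug mentions, three candidate pairs, none filterable."""
    text = (
        "Caution should be exercised when administering nabumetone with "
        "warfarin since interactions have been seen with other NSAIDs"
    )
    return make_sentence(
        "d0.s0",
        text,
        [("d0.s0.e0", "nabumetone"), ("d0.s0.e1", "warfarin"), ("d0.s0.e2", "NSAIDs")],
        pairs=[
            GoldPair("d0.s0.e0", "d0.s0.e1", "mechanism"),
            GoldPair("d0.s0.e0", "d0.s0.e2", "negative"),
            GoldPair("d0.s0.e1", "d0.s0.e2", "negative"),
        ],
    )


@pytest.fixture
def same_name_sentence() -> AnnotatedSentence:
    """The same drug name mentioned twice — a Rule 1 noise pair."""
    text = (
        "Anesthetics, general: exaggeration of the hypotension induced by "
        "general anesthetics"
    )
    return make_sentence(
        "d0.s1",
        text,
        [("d0.s1.e0", "Anesthetics"), ("d0.s1.e1", "anesthetics")],
        pairs=[GoldPair("d0.s1.e0", "d0.s1.e1", "negative")],
    )


@pytest.fixture
def coordinate_sentence() -> AnnotatedSentence:
    """Five drugs in a comma/or list — every pair is Rule 2 noise."""
    text = (
        "To minimize CNS depression and possible potentiation, barbiturates, "
        "antihistamines, narcotics, hypotensive agents or phenothiazines "
        "should be used with caution"
    )
    return make_sentence(
        "d0.s2",
        text,
        [
            ("d0.s2.e0", "barbiturates"),
            ("d0.s2.e1", "antihistamines"),
            ("d0.s2.e2", "narcotics"),
            ("d0.s2.e3", "hypotensive agents"),
            ("d0.s2.e4", "phenothiazines"),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
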