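"""Synthetic relation-extraction corpora with known structure.

Every stage of the pipeline is testable without external corpora:
sentences carry 2–5 annotated entities; the gold label of a pair is a
deterministic function of the single-token cue placed strictly between
its entities (exactly one cue between the pair → that cue's class,
otherwise negative), so a Bayes-optimal classifier reaches micro-F 100
on decoy-free corpora.  Decoy sentences exercise the noise filters:
same-name repetitions (Rule 1) and comma/"and"/"or" coordinate lists
(Rule 2).  Fabricated embedding channels with partial, overlapping
vocabulary coverage emulate multichannel pretrained tables; cue vectors
are class-clustered so the pretrained channels are informative.

None of this mimics real biomedical prose statistics — filler tokens
are drawn uniformly from an artificial lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedSentence, EntityMention, GoldPair
from .embeddings import SPECIALS, Vocab

DEFAULT_CUES = {
    "advice": "caution",
    "effect": "potentiates",
    "mechanism": "inhibits",
    "int": "interacts",
    "negative": "coadministered",
}

__all__ = ["SynthConfig", "DEFAULT_CUES", "generate_corpus", "generate_channels"]


@dataclass
class SynthConfig:
    """Knobs of the generator.

    ``cues`` maps each class to its single-token cue.  ``entities_range``
    is inclusive.  ``channel_fractions`` gives one fabricated channel per
    entry, each covering that fraction of the (non-special) vocabulary in
    consecutive, wrapping slices — so two 0.5 channels are complementary
    and their union covers everything; cue tokens are additionally
    present in every channel.
    """

    n_sentences: int = 500
    cues: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CUES))
    entities_range: tuple[int, int] = (2, 5)
    filler_vocab_size: int = 120
    entity_lexicon_size: int = 200
    gap_fillers: tuple[int, int] = (1, 3)
    edge_fillers: tuple[int, int] = (1, 4)
    p_decoy_same_name: float = 0.0
    p_decoy_coordinate: float = 0.0
    channel_fractions: tuple[float, ...] = (1.0, 0.5)
    embedding_dim: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_decoy_same_name, self.p_decoy_coordinate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("decoy probabilities must lie in [0, 1]")
        if self.p_decoy_same_name + self.p_decoy_coordinate > 1.0:
            raise ValueError("decoy probabilities sum to more than 1")
        lo, hi = self.entities_range
        if not 2 <= lo <= hi:
            raise ValueError("entities_range must satisfy 2 <= lo <= hi")
        if len(self.cues) != len(set(self.cues.values())):
            raise ValueError("cue tokens must be distinct")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.cues)


class _SentenceBuilder:
    """Accumulates words into text, attaching commas to the previous word
    and recording entity character spans."""

    def __init__(self) -> None:
        self.text = ""
        self.entities: list[tuple[str, int, int]] = []  # surface, start, end

    def word(self, w: str) -> None:
        sep = "" if (w == "," or not self.text) else " "
        self.text += sep + w

    def entity(self, surface: str) -> None:
        sep = " " if self.text else ""
        start = len(self.text) + len(sep)
        self.text += sep + surface
        self.entities.append((surface, start, start + len(surface) - 1))


def _recovered_label(
    words: list[str], ent_positions: list[int], i: int, j: int, cue_class: dict[str, str]
) -> str:
    """Exactly one cue strictly between the pair → that class; else negative."""
    between = words[ent_positions[i] + 1 : ent_positions[j]]
    cues = [cue_class[w] for w in between if w in cue_class]
    return cues[0] if len(cues) == 1 else "negative"


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[AnnotatedSentence], list[dict]]:
    """Generate sentences plus a ground-truth manifest.

    The manifest holds one record per candidate pair:
    ``{"sentence_id", "e1", "e2", "label", "should_remove"}`` where
    ``should_remove`` is "rule1", "rule2", or None.
    """
    rng = np.random.default_rng(config.seed)
    fillers = [f"filler{i}" for i in range(config.filler_vocab_size)]
    lexicon = [f"drug{i}" for i in range(config.entity_lexicon_size)]
    cue_class = {tok: lab for lab, tok in config.cues.items()}
    cue_tokens = list(config.cues.values())

    sentences: list[AnnotatedSentence] = []
    manifest: list[dict] = []
    for s in range(config.n_sentences):
        sid = f"synth.s{s}"
        u = rng.random()
        if u < config.p_decoy_same_name:
            kind = "same_name"
        elif u < config.p_decoy_same_name + config.p_decoy_coordinate:
            kind = "coordinate"
        else:
            kind = "normal"

        b = _SentenceBuilder()
        words: list[str] = []  # parallel word list for label recovery
        ent_positions: list[int] = []

        def filler_run(lo: int, hi: int) -> None:
            for _ in range(int(rng.integers(lo, hi + 1))):
                w = fillers[int(rng.integers(len(fillers)))]
                b.word(w)
                words.append(w)

        def put_entity(surface: str) -> None:
            ent_positions.append(len(words))
            words.append(surface)
            b.entity(surface)

        if kind == "same_name":
            name = lexicon[int(rng.integers(len(lexicon)))]
            filler_run(*config.edge_fillers)
            put_entity(name)
            filler_run(*config.gap_fillers)
            put_entity(name)
            filler_run(*config.edge_fillers)
        elif kind == "coordinate":
            n_ent = int(rng.integers(3, config.entities_range[1] + 1))
            names = list(rng.choice(lexicon, size=n_ent, replace=False))
            filler_run(*config.edge_fillers)
            for i, name in enumerate(names):
                put_entity(str(name))
                if i < n_ent - 2:
                    b.word(",")
                    words.append(",")
                elif i == n_ent - 2:
                    conj = "and" if rng.random() < 0.5 else "or"
                    b.word(conj)
                    words.append(conj)
            filler_run(*config.edge_fillers)
        else:
            n_ent = int(
                rng.integers(config.entities_range[0], config.entities_range[1] + 1)
            )
            names = list(rng.choice(lexicon, size=n_ent, replace=False))
            filler_run(*config.edge_fillers)
            for i, name in enumerate(names):
                put_entity(str(name))
                if i < n_ent - 1:
                    # each gap: fillers around exactly one class cue
                    filler_run(*config.gap_fillers)
                    cue = cue_tokens[int(rng.integers(len(cue_tokens)))]
                    b.word(cue)
                    words.append(cue)
                    filler_run(*config.gap_fillers)
            filler_run(*config.edge_fillers)

        entities = [
            EntityMention(
                id=f"{sid}.e{k}",
                surface=surf,
                char_start=start,
                char_end=end,
                etype="drug",
            )
            for k, (surf, start, end) in enumerate(b.entities)
        ]
        pairs = []
        n = len(entities)
        for i in range(n):
            for j in range(i + 1, n):
                if kind == "normal":
                    label = _recovered_label(words, ent_positions, i, j, cue_class)
                    remove = None
                else:
                    label = "negative"
                    remove = "rule1" if kind == "same_name" else "rule2"
                pairs.append(GoldPair(entities[i].id, entities[j].id, label))
                manifest.append(
                    {
                        "sentence_id": sid,
                        "e1": entities[i].id,
                        "e2": entities[j].id,
                        "label": label,
                        "should_remove": remove,
                    }
                )
        sent = AnnotatedSentence(id=sid, text=b.text, entities=entities, pairs=pairs)
        sent.validate()
        sentences.append(sent)
    return sentences, manifest


def generate_channels(
    config: SynthConfig,
    vocab: Vocab,
    out_dir: str | Path,
) -> list[Path]:
    """Write one word2vec text file per configured channel fraction.

    Channel *i* covers a consecutive wrapping slice of the shuffled
    non-special vocabulary (slices laid end to end, so fractions summing
    to 1 give complementary coverage) plus every cue token.  Same-class
    cue vectors cluster around a shared direction, closer to each other
    (cosine) than to cues of other classes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    d = config.embedding_dim
    eligible = [w for w in vocab.index if w not in SPECIALS]
    order = list(eligible)
    rng.shuffle(order)

    cue_tokens = set(config.cues.values())
    class_base = {
        lab: rng.normal(0.0, 1.0, size=d) for lab in config.cues
    }
    vectors: dict[str, np.ndarray] = {}
    for w in eligible:
        vectors[w] = rng.normal(0.0, 0.1, size=d)
    for lab, tok in config.cues.items():
        base = class_base[lab]
        vectors[tok] = base / np.linalg.norm(base) + rng.normal(0.0, 0.05, size=d)

    paths: list[Path] = []
    offset = 0
    for ci, frac in enumerate(config.channel_fractions):
        # ceil so fractions summing to 1 always cover the whole vocabulary
        n_cov = min(len(order), int(np.ceil(frac * len(order))))
        cover = [order[(offset + k) % len(order)] for k in range(n_cov)]
        offset += n_cov
        chosen = sorted(set(cover) | (cue_tokens & set(eligible)))
        path = out_dir / f"channel{ci}.vec"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(chosen)} {d}\n")
            for w in chosen:
                vals = " ".join(f"{x:.6f}" for x in vectors[w])
                fh.write(f"{w} {vals}\n")
        paths.append(path)
    return paths
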