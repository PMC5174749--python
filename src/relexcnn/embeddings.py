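"""Vocabulary building and multichannel embedding assembly.

Each *channel* is one pretrained word-embedding table (word2vec text
format).  Stacking ``c`` channels over a shared task vocabulary of size
``v`` with dimension ``d`` gives the lookup tensor ``D`` of shape
``(c, v, d)`` — the analogue of RGB channels for a sentence.

Vocabulary words missing from a channel's table (and the artificial
blinding symbols) are initialized i.i.d. uniform in [-0.25, 0.25]; the
padding symbol is pinned to the zero vector and excluded from gradient
updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD = "<PAD>"
UNK = "<UNK>"
SPECIALS = (PAD, UNK, "Entity1", "Entity2", "EntityOther")
PAD_INDEX = 0
OOV_INIT_RANGE = 0.25

__all__ = [
    "PAD",
    "UNK",
    "SPECIALS",
    "PAD_INDEX",
    "Vocab",
    "EmbeddingChannel",
    "MultichannelEmbedding",
    "build_vocab",
    "load_channel",
    "assemble",
    "encode",
    "decode",
]


@dataclass
class Vocab:
    """Dense symbol→index map over training tokens plus the specials."""

    index: dict[str, int]

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, self.index[UNK])

    @property
    def symbols(self) -> list[str]:
        out = [""] * len(self.index)
        for tok, i in self.index.items():
            out[i] = tok
        return out


def build_vocab(token_sequences: Iterable[Sequence[str]]) -> Vocab:
    """Vocabulary over all tokens seen in training, specials first.

    PAD always receives index 0.
    """
    index: dict[str, int] = {}
    for sym in SPECIALS:
        index[sym] = len(index)
    for seq in token_sequences:
        for tok in seq:
            if tok not in index:
                index[tok] = len(index)
    return Vocab(index)


@dataclass
class EmbeddingChannel:
    """One channel: a (v, d) matrix aligned to the vocabulary."""

    name: str
    vectors: np.ndarray
    coverage: int = 0


@dataclass
class MultichannelEmbedding:
    """The stacked lookup tensor D of shape (c, v, d)."""

    D: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    @property
    def c(self) -> int:
        return self.D.shape[0]

    @property
    def v(self) -> int:
        return self.D.shape[1]

    @property
    def d(self) -> int:
        return self.D.shape[2]


def read_word2vec_text(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Parse a word2vec text file into {word: vector}.

    An optional "count dim" header line is tolerated.  Every row must
    share one dimension; a mismatched row raises with its word named.
    """
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        lines = []
        if first.strip():
            parts = first.rstrip("\n").split()
            if len(parts) == 2 and parts[0].isdigit() and parts[1].isdigit():
                dim = int(parts[1])  # header "vocab_count dim"
            else:
                lines.append(first)
        for line in lines + fh.readlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split()
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            if len(values) != dim:
                raise ValueError(
                    f"{path}: row for {word!r} has {len(values)} values, "
                    f"expected {dim}"
                )
            table[word] = np.asarray(values, dtype=np.float64)
    return table, (dim or 0)


def load_channel(
    path: str | Path,
    vocab: Vocab,
    d: int,
    rng_seed: int | np.random.SeedSequence = 0,
    name: str | None = None,
) -> EmbeddingChannel:
    """Build one channel matrix aligned to ``vocab``.

    Vocab words present in the file keep their stored vectors; absent
    words and all specials except PAD draw i.i.d. uniform components in
    [-0.25, 0.25]; PAD stays zero.  The blinding symbols are artificial
    and never looked up in the table.
    """
    table, file_dim = read_word2vec_text(path)
    if table and file_dim != d:
        raise ValueError(f"{path}: file dimension {file_dim} != requested {d}")
    rng = np.random.default_rng(rng_seed)
    vectors = rng.uniform(-OOV_INIT_RANGE, OOV_INIT_RANGE, size=(len(vocab), d))
    coverage = 0
    for tok, i in vocab.index.items():
        if tok in SPECIALS:
            continue
        vec = table.get(tok)
        if vec is not None:
            vectors[i] = vec
            coverage += 1
    vectors[vocab.index[PAD]] = 0.0
    return EmbeddingChannel(
        name=name or Path(path).stem, vectors=vectors, coverage=coverage
    )


def assemble(channels: Sequence[EmbeddingChannel]) -> MultichannelEmbedding:
    """Stack channels into the (c, v, d) tensor in the given order."""
    if not channels:
        raise ValueError("at least one channel is required")
    shapes = {ch.vectors.shape for ch in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel shape mismatch: {sorted(shapes)}")
    D = np.stack([ch.vectors for ch in channels], axis=0)
    return MultichannelEmbedding(D=D, channel_names=[ch.name for ch in channels])


def encode(tokens: Sequence[str], vocab: Vocab) -> np.ndarray:
    """Map token symbols to vocabulary indices; unseen tokens map to UNK."""
    return np.asarray([vocab[t] for t in tokens], dtype=np.int64)


def decode(indices: Sequence[int], vocab: Vocab) -> list[str]:
    symbols = vocab.symbols
    return [symbols[i] for i in indices]
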