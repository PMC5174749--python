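"""Model/Results interface over the pipeline.

:class:`RelationCNN` is built from blinded training instances plus one
or more embedding channels; :meth:`RelationCNN.fit` runs minibatch
Adadelta training and returns a :class:`RelationCNNResults` carrying the
fitted parameters, the loss history, prediction and scoring methods, a
``summary()`` table, and checkpoint persistence.

    >>> model = RelationCNN(train_instances, channel_paths=["pmc.vec"],
    ...                     embedding_dim=200, windows=(6, 7, 8, 9))
    >>> results = model.fit(epochs=10, seed=0)
    >>> print(results.summary())
    >>> labels, probs = results.predict(test_instances)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation
from .corpus_io import AnnotatedSentence
from .embeddings import (
    MultichannelEmbedding,
    Vocab,
    assemble,
    build_vocab,
    load_channel,
)
from .network import ModelParams, load_checkpoint, save_checkpoint
from .preprocess import Instance, build_dataset
from .training import TrainConfig, predict_batches, train

__all__ = ["RelationCNN", "RelationCNNResults"]


class RelationCNN:
    """Multichannel CNN relation classifier, statsmodels-style.

    Parameters
    ----------
    instances:
        Blinded training instances (from :func:`relexcnn.preprocess.build_dataset`).
    channel_paths:
        One word2vec text file per embedding channel.  Missing vocabulary
        words are randomly initialized; every channel is fine-tuned
        during training.
    embedding_dim:
        Dimension d shared by all channels.
    windows, n_filters, batch_size, ...:
        Forwarded to :class:`relexcnn.training.TrainConfig`.
    """

    def __init__(
        self,
        instances: Sequence[Instance],
        channel_paths: Sequence[str | Path],
        embedding_dim: int,
        class_labels: Sequence[str] | None = None,
        **config_kwargs,
    ):
        if not instances:
            raise ValueError("no training instances")
        if not channel_paths:
            raise ValueError("at least one embedding channel is required")
        self.instances = list(instances)
        self.channel_paths = [Path(p) for p in channel_paths]
        self.embedding_dim = int(embedding_dim)
        self.class_labels = tuple(
            class_labels
            if class_labels is not None
            else sorted({i.label for i in self.instances})
        )
        self.config = TrainConfig(**config_kwargs)
        self.vocab: Vocab = build_vocab(i.tokens for i in self.instances)

    @classmethod
    def from_corpus(
        cls,
        sentences: Sequence[AnnotatedSentence],
        channel_paths: Sequence[str | Path],
        embedding_dim: int,
        apply_filters: bool = True,
        **config_kwargs,
    ) -> "RelationCNN":
        """Build directly from annotated sentences: enumerate pairs,
        blind, and (optionally) apply the noise filters."""
        kept, _ = build_dataset(sentences, apply_filters=apply_filters)
        return cls(kept, channel_paths, embedding_dim, **config_kwargs)

    def _build_embedding(self, seed: int) -> MultichannelEmbedding:
        seeds = np.random.SeedSequence(seed).spawn(len(self.channel_paths))
        channels = [
            load_channel(path, self.vocab, self.embedding_dim, rng_seed=s)
            for path, s in zip(self.channel_paths, seeds)
        ]
        return assemble(channels)

    def fit(
        self, epochs: int | None = None, seed: int | None = None
    ) -> "RelationCNNResults":
        """Train and return a results object.

        ``epochs``/``seed`` override the constructor-time config; all
        randomness (OOV init, filter init, shuffling, input noise) flows
        from the single seed.
        """
        config = self.config
        if epochs is not None:
            config = replace(config, epochs=epochs)
        if seed is not None:
            config = replace(config, seed=seed)
        embedding = self._build_embedding(config.seed + 1)
        params, loss_log = train(
            self.instances,
            embedding,
            self.vocab,
            config,
            class_labels=self.class_labels,
        )
        return RelationCNNResults(
            model=self,
            params=params,
            vocab=self.vocab,
            loss_history=list(loss_log),
            config=config,
        )


@dataclass
class RelationCNNResults:
    """Fitted parameters plus diagnostics and prediction methods."""

    params: ModelParams
    vocab: Vocab
    loss_history: list[float]
    config: TrainConfig
    model: RelationCNN | None = field(default=None, repr=False)

    def predict(
        self, instances: Sequence[Instance]
    ) -> tuple[list[str], np.ndarray]:
        """Predicted labels and class probabilities (no input noise)."""
        return predict_batches(instances, self.params, self.vocab)

    def score(
        self,
        instances: Sequence[Instance],
        positive_classes: Sequence[str] | None = None,
    ) -> evaluation.EvalReport:
        """Evaluate on labeled instances: per-class P/R/F, overall
        micro-F over positive classes, and detection F."""
        if positive_classes is None:
            positive_classes = [
                lab for lab in self.params.class_labels if lab != "negative"
            ]
        predicted, _ = self.predict(instances)
        gold = [i.label for i in instances]
        return evaluation.score(gold, predicted, positive_classes)

    def summary(self) -> str:
        c, v, d = self.params.D.shape
        cfg = self.config
        lines = [
            "Multichannel CNN relation classifier",
            "=" * 44,
            f"{'channels (c)':<24}{c}",
            f"{'vocabulary (v)':<24}{v}",
            f"{'embedding dim (d)':<24}{d}",
            f"{'window sizes (H)':<24}{list(self.params.windows)}",
            f"{'filters per window (M)':<24}{self.params.n_filters}",
            f"{'classes (O)':<24}{list(self.params.class_labels)}",
            f"{'batch size (L)':<24}{cfg.batch_size}",
            f"{'epochs':<24}{cfg.epochs}",
            f"{'noise mean/std':<24}{cfg.noise_mean}/{cfg.noise_std}",
            f"{'softmax max-norm':<24}{cfg.maxnorm}",
            f"{'seed':<24}{cfg.seed}",
            "-" * 44,
            f"{'epoch':<8}{'mean NLL':>12}",
        ]
        for e, loss in enumerate(self.loss_history, start=1):
            lines.append(f"{e:<8}{loss:>12.6f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        channel_names = (
            [p.name for p in self.model.channel_paths] if self.model else []
        )
        save_checkpoint(
            path,
            self.params,
            self.vocab,
            channel_names=channel_names,
            extra={
                "loss_history": self.loss_history,
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(self.config).items()
                },
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "RelationCNNResults":
        params, vocab, meta = load_checkpoint(path)
        extra = meta.get("extra", {})
        cfg_dict = dict(extra.get("config", {}))
        if "windows" in cfg_dict:
            cfg_dict["windows"] = tuple(cfg_dict["windows"])
        config = TrainConfig(**cfg_dict) if cfg_dict else TrainConfig(
            windows=params.windows, n_filters=params.n_filters
        )
        return cls(
            params=params,
            vocab=vocab,
            loss_history=list(extra.get("loss_history", [])),
            config=config,
        )
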