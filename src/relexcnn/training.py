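"""Minibatch NLL training with Adadelta, input noise, and max-norm.

The loss over a minibatch of L instances is the summed negative
log-likelihood loss = Σ_i −log p(y_i | x_i).  Parameters are updated by
Adadelta (decay ρ=0.95, ε=1e−6 by default), which adapts a per-component
step size from running averages of squared gradients and squared updates
and so needs no hand-tuned learning rate.

Two regularizers stand in for dropout: small Gaussian noise added to the
input embeddings of real token positions during training, and an L2
max-norm constraint on the rows of the softmax weight matrix, re-applied
after every update step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .embeddings import MultichannelEmbedding, PAD_INDEX, Vocab, encode
from .network import ModelParams, backward_batch, forward_batch, init_params, pad_batch
from .preprocess import Instance

NLL_CLAMP = 1e-12

__all__ = [
    "TrainConfig",
    "AdadeltaState",
    "nll_loss",
    "add_input_noise",
    "adadelta_step",
    "apply_maxnorm",
    "train",
    "predict_batches",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the classifier and its optimizer.

    Defaults follow the drug-interaction configuration: 200 filters per
    window size, windows {6,7,8,9}, minibatches of 20, 10 epochs,
    Gaussian input noise with mean 0.001, and a max-norm of 5 on the
    softmax weights.  The protein-interaction task uses windows
    {3,4,5,6} (shorter sentences); pass ``windows=(3, 4, 5, 6)``.
    """

    n_filters: int = 200
    windows: tuple[int, ...] = (6, 7, 8, 9)
    batch_size: int = 20
    epochs: int = 10
    noise_mean: float = 0.001
    noise_std: float = 0.001
    maxnorm: float = 5.0
    rho: float = 0.95
    eps: float = 1e-6
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.maxnorm <= 0:
            raise ValueError("maxnorm must be positive")
        self.windows = tuple(sorted(int(h) for h in self.windows))


@dataclass
class AdadeltaState:
    """Per-parameter accumulators; shapes mirror θ, initialized to zero."""

    sq_grad: dict[str, np.ndarray] = field(default_factory=dict)
    sq_update: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def for_params(cls, params: ModelParams) -> "AdadeltaState":
        groups = params.flat_groups()
        return cls(
            sq_grad={k: np.zeros_like(v) for k, v in groups.items()},
            sq_update={k: np.zeros_like(v) for k, v in groups.items()},
        )


def nll_loss(probabilities: np.ndarray, gold: np.ndarray) -> float:
    """Summed −log p(gold) over the batch; zero probabilities clamp to
    1e−12 with a warning."""
    probabilities = np.atleast_2d(probabilities)
    gold = np.atleast_1d(gold)
    p = probabilities[np.arange(len(gold)), gold]
    if np.any(p <= 0.0):
        warnings.warn("gold-class probability of 0 clamped to 1e-12")
        p = np.clip(p, NLL_CLAMP, None)
    return float(-np.log(p).sum())


def add_input_noise(
    V: np.ndarray,
    noise_mean: float,
    noise_std: float,
    rng: np.random.Generator,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """V + elementwise N(noise_mean, noise_std²); training only.

    If ``lengths`` is given (batched V of shape (B, c, N, d)), padding
    positions at or beyond each length are left untouched.
    """
    noise = rng.normal(noise_mean, noise_std, size=V.shape)
    if lengths is not None:
        N = V.shape[2]
        valid = (np.arange(N)[None, :] < np.asarray(lengths)[:, None])
        noise = noise * valid[:, None, :, None]
    return V + noise


def adadelta_step(
    params: ModelParams,
    grads: dict[str, np.ndarray],
    state: AdadeltaState,
    rho: float = 0.95,
    eps: float = 1e-6,
) -> None:
    """One in-place Adadelta update:

        E[g²] ← ρ E[g²] + (1−ρ) g²
        Δ     ← −sqrt(E[Δ²]+ε) / sqrt(E[g²]+ε) · g
        E[Δ²] ← ρ E[Δ²] + (1−ρ) Δ²
        θ     ← θ + Δ

    The PAD embedding row is excluded (its gradient is already zeroed).
    """
    groups = params.flat_groups()
    for name, theta in groups.items():
        g = grads[name]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient in parameter group {name!r}"
            )
        Eg = state.sq_grad[name]
        Ed = state.sq_update[name]
        Eg *= rho
        Eg += (1.0 - rho) * g * g
        delta = -np.sqrt(Ed + eps) / np.sqrt(Eg + eps) * g
        Ed *= rho
        Ed += (1.0 - rho) * delta * delta
        theta += delta
    params.D[:, PAD_INDEX, :] = 0.0


def apply_maxnorm(W2: np.ndarray, maxnorm: float) -> np.ndarray:
    """Rescale any row of W2 whose L2 norm exceeds ``maxnorm`` back onto
    the constraint sphere; rows within the ball are untouched."""
    norms = np.linalg.norm(W2, axis=1, keepdims=True)
    scale = np.where(norms > maxnorm, maxnorm / np.where(norms == 0, 1, norms), 1.0)
    return W2 * scale


def _encode_instances(
    instances: Sequence[Instance], vocab: Vocab
) -> list[np.ndarray]:
    return [encode(inst.tokens, vocab) for inst in instances]


def train(
    instances: Sequence[Instance],
    embedding: MultichannelEmbedding,
    vocab: Vocab,
    config: TrainConfig,
    class_labels: Sequence[str] | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> tuple[ModelParams, list[float]]:
    """Train the classifier; returns (θ, per-epoch mean loss log).

    Instances are reshuffled every epoch from the seeded generator.
    Gaussian noise is resampled per batch.  A final short batch is used
    as-is.  ``epochs=0`` returns the initialization unchanged.
    """
    if not instances:
        raise ValueError("empty training set")
    if class_labels is None:
        class_labels = sorted({inst.label for inst in instances})
    label_index = {lab: i for i, lab in enumerate(class_labels)}
    for inst in instances:
        if inst.label not in label_index:
            raise ValueError(f"label {inst.label!r} outside class set")

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    init_rng = np.random.default_rng(seeds[0])
    shuffle_rng = np.random.default_rng(seeds[1])
    noise_rng = np.random.default_rng(seeds[2])

    params = init_params(
        embedding,
        config.windows,
        config.n_filters,
        class_labels,
        init_rng,
        init_scale=config.init_scale,
    )
    state = AdadeltaState.for_params(params)
    encoded = _encode_instances(instances, vocab)
    gold_all = np.asarray([label_index[i.label] for i in instances])
    max_h = max(config.windows)
    use_noise = config.noise_std > 0 or config.noise_mean != 0

    loss_log: list[float] = []
    order = np.arange(len(instances))
    for epoch in range(config.epochs):
        shuffle_rng.shuffle(order)
        total = 0.0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            idx, lengths = pad_batch([encoded[i] for i in sel], max_h)
            noise = None
            if use_noise:
                B, N = idx.shape
                shape = (B, params.D.shape[0], N, params.D.shape[2])
                noise = noise_rng.normal(config.noise_mean, config.noise_std, shape)
            cache = forward_batch(idx, lengths, params, noise=noise)
            gold = gold_all[sel]
            total += nll_loss(cache.probabilities, gold)
            grads = backward_batch(cache, gold, params)
            adadelta_step(params, grads, state, config.rho, config.eps)
            params.W2 = apply_maxnorm(params.W2, config.maxnorm)
        mean_loss = total / len(order)
        loss_log.append(mean_loss)
        if callback is not None:
            callback(epoch, mean_loss)
    return params, loss_log


def predict_batches(
    instances: Sequence[Instance],
    params: ModelParams,
    vocab: Vocab,
    batch_size: int = 128,
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class probabilities; no noise at test time.

    Ties in the argmax resolve to the lowest class index.
    """
    encoded = _encode_instances(instances, vocab)
    max_h = max(params.windows)
    labels: list[str] = []
    probs: list[np.ndarray] = []
    for start in range(0, len(encoded), batch_size):
        chunk = encoded[start : start + batch_size]
        idx, lengths = pad_batch(chunk, max_h)
        cache = forward_batch(idx, lengths, params)
        probs.append(cache.probabilities)
        for row in cache.probabilities:
            labels.append(params.class_labels[int(np.argmax(row))])
    return labels, (
        np.concatenate(probs) if probs else np.zeros((0, params.n_classes))
    )
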