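"""The multichannel CNN itself: parameters, forward pass, and backprop.

Architecture, for an encoded sentence of length N over c embedding
channels of dimension d:

1. lookup      V[i, k]   = D[i, indices[k]]                 (c, N, d)
2. convolution m_k       = relu( sum_i V_i[k:k+h-1] ⊙ W_i + b )
3. feature map C         = [m_1, ..., m_{N-h+1}]
4. max-pooling C*        = max_k C_k            (one scalar per filter)
5. concat      r         = [r*_1, ..., r*_K]    (K window sizes × M filters)
6. softmax     I = W2 r;  s_j = exp(i_j) / Σ_k exp(i_k)

All arithmetic is float64 NumPy.  Gradients for every parameter group
(D, W, W2, b) are hand-derived and checked against central finite
differences in the test suite.

Padding: sequences shorter than max(H) are right-padded with PAD;
within a batch, sequences are right-padded to the batch max length, and
window positions beyond each instance's true feature map (length
N-h+1 for true length N) are masked to -inf before pooling, so padding
never wins the max and pooled features do not depend on how much batch
padding was appended.  A sequence shorter than h keeps its single
(partially padded) window.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import PAD_INDEX, MultichannelEmbedding, Vocab

CHECKPOINT_FORMAT = "relexcnn-checkpoint"
CHECKPOINT_VERSION = 1

__all__ = [
    "ModelParams",
    "ForwardTrace",
    "init_params",
    "lookup",
    "conv_feature_map",
    "max_pool",
    "softmax",
    "forward",
    "forward_batch",
    "backward_batch",
    "pad_batch",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelParams:
    """θ = (D, W, W2, b): everything the optimizer updates.

    ``conv_w[h]`` has shape (M, c, h, d) — M filters per window size h;
    ``conv_b[h]`` has shape (M,); ``W2`` has shape (O, K·M) where K is
    the number of window sizes and O the number of classes.
    """

    D: np.ndarray
    conv_w: dict[int, np.ndarray]
    conv_b: dict[int, np.ndarray]
    W2: np.ndarray
    windows: tuple[int, ...]
    n_filters: int
    class_labels: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def check_shapes(self) -> None:
        c, _, d = self.D.shape
        for h in self.windows:
            if self.conv_w[h].shape != (self.n_filters, c, h, d):
                raise ValueError(f"filter bank for h={h} has wrong shape")
            if self.conv_b[h].shape != (self.n_filters,):
                raise ValueError(f"bias for h={h} has wrong shape")
        km = len(self.windows) * self.n_filters
        if self.W2.shape != (self.n_classes, km):
            raise ValueError(
                f"W2 shape {self.W2.shape} != ({self.n_classes}, {km})"
            )

    def flat_groups(self) -> dict[str, np.ndarray]:
        """Named parameter arrays, for the optimizer and checkpoints."""
        groups = {"D": self.D, "W2": self.W2}
        for h in self.windows:
            groups[f"conv_w_{h}"] = self.conv_w[h]
            groups[f"conv_b_{h}"] = self.conv_b[h]
        return groups


def init_params(
    embedding: MultichannelEmbedding,
    windows: Sequence[int],
    n_filters: int,
    class_labels: Sequence[str],
    rng: np.random.Generator,
    init_scale: float = 0.1,
) -> ModelParams:
    """Initialize filters and softmax weights uniformly in ±init_scale;
    D starts from the assembled pretrained channels (and is trainable)."""
    c, _, d = embedding.D.shape
    windows = tuple(sorted(windows))
    conv_w = {
        h: rng.uniform(-init_scale, init_scale, size=(n_filters, c, h, d))
        for h in windows
    }
    conv_b = {h: np.zeros(n_filters) for h in windows}
    W2 = rng.uniform(
        -init_scale, init_scale, size=(len(class_labels), len(windows) * n_filters)
    )
    params = ModelParams(
        D=embedding.D.copy(),
        conv_w=conv_w,
        conv_b=conv_b,
        W2=W2,
        windows=windows,
        n_filters=n_filters,
        class_labels=tuple(class_labels),
    )
    params.check_shapes()
    return params


# ---------------------------------------------------------------------------
# single-instance reference path (mirrors the layer-by-layer contracts)


def lookup(indices: np.ndarray, D: np.ndarray) -> np.ndarray:
    """V[i][k] = D[i][indices[k]] — shape (c, N, d)."""
    indices = np.asarray(indices)
    if indices.size and (indices.min() < 0 or indices.max() >= D.shape[1]):
        raise IndexError("token index out of range of the embedding tensor")
    return D[:, indices, :]


def conv_feature_map(
    V: np.ndarray, W: np.ndarray, b: float, activation: str = "relu"
) -> np.ndarray:
    """Feature map C of length N-h+1 for one filter W of shape (c, h, d).

    C_k = f( Σ_channels Σ_elementwise V_i[k:k+h-1] ⊙ W_i + b ).
    """
    c, N, d = V.shape
    h = W.shape[1]
    if N < h:
        raise ValueError(f"sequence length {N} shorter than window {h}")
    P = N - h + 1
    C = np.empty(P)
    for k in range(P):
        C[k] = np.sum(V[:, k : k + h, :] * W) + b
    if activation == "relu":
        C = np.maximum(C, 0.0)
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    return C


def max_pool(C: np.ndarray) -> float:
    """C* = max over the feature map (one scalar per filter)."""
    C = np.asarray(C)
    if C.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(C.max())


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ForwardTrace:
    """Every intermediate of one forward pass (single instance)."""

    V: np.ndarray
    feature_maps: dict[int, np.ndarray]  # h -> (M, N-h+1)
    r: np.ndarray
    logits: np.ndarray
    probabilities: np.ndarray

    @property
    def predicted_index(self) -> int:
        # argmax with ties broken by the lowest class index
        return int(np.argmax(self.probabilities))


def forward(indices: Sequence[int], params: ModelParams) -> ForwardTrace:
    """Layer-by-layer forward pass for one encoded sentence.

    Sequences shorter than the largest window are right-padded with PAD.
    """
    idx = np.asarray(indices, dtype=np.int64)
    true_len = idx.shape[0]
    max_h = max(params.windows)
    if true_len < max_h:
        idx = np.concatenate(
            [idx, np.full(max_h - true_len, PAD_INDEX, dtype=np.int64)]
        )
    V = lookup(idx, params.D)
    pooled = []
    feature_maps: dict[int, np.ndarray] = {}
    for h in params.windows:
        W, b = params.conv_w[h], params.conv_b[h]
        maps = np.stack(
            [conv_feature_map(V, W[m], b[m]) for m in range(params.n_filters)]
        )
        feature_maps[h] = maps
        # pool over the true-content feature map of length N-h+1; for
        # sequences shorter than h the single padded window remains
        valid = min(maps.shape[1], max(true_len - h + 1, 1))
        pooled.append(maps[:, :valid].max(axis=1))
    r = np.concatenate(pooled)
    logits = params.W2 @ r
    return ForwardTrace(
        V=V,
        feature_maps=feature_maps,
        r=r,
        logits=logits,
        probabilities=softmax(logits),
    )


# ---------------------------------------------------------------------------
# batched path used for training (vectorized, with padding masks)


def pad_batch(
    sequences: Sequence[Sequence[int]], min_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad index sequences with PAD to max(batch max, min_length).

    Returns (indices (B, N), lengths (B,)).
    """
    lengths = np.asarray([len(s) for s in sequences], dtype=np.int64)
    N = max(int(lengths.max()), min_length)
    idx = np.full((len(sequences), N), PAD_INDEX, dtype=np.int64)
    for i, seq in enumerate(sequences):
        idx[i, : len(seq)] = seq
    return idx, lengths


@dataclass
class _BatchCache:
    idx: np.ndarray
    lengths: np.ndarray
    V: np.ndarray  # (B, c, N, d), noise included if any
    pre_act: dict[int, np.ndarray]  # h -> (B, M, P) pre-activation
    argmax: dict[int, np.ndarray]  # h -> (B, M) pooled position
    r: np.ndarray  # (B, K*M)
    logits: np.ndarray
    probabilities: np.ndarray


def forward_batch(
    idx: np.ndarray,
    lengths: np.ndarray,
    params: ModelParams,
    noise: np.ndarray | None = None,
) -> _BatchCache:
    """Vectorized forward pass over a padded batch.

    ``noise`` (same shape as V) is added to the input embeddings of real
    token positions only — padding stays exactly zero.
    """
    B, N = idx.shape
    V = np.transpose(params.D[:, idx, :], (1, 0, 2, 3))  # (B, c, N, d)
    if noise is not None:
        valid = (np.arange(N)[None, :] < lengths[:, None])[:, None, :, None]
        V = V + noise * valid
    pooled = []
    pre_act: dict[int, np.ndarray] = {}
    argmax: dict[int, np.ndarray] = {}
    positions = np.arange(N)
    for h in params.windows:
        P = N - h + 1
        W = params.conv_w[h]  # (M, c, h, d)
        A = np.zeros((B, params.n_filters, P))
        for j in range(h):
            A += np.einsum("bcpd,mcd->bmp", V[:, :, j : j + P, :], W[:, :, j, :])
        A += params.conv_b[h][None, :, None]
        R = np.maximum(A, 0.0)
        # mask window positions beyond each instance's true feature map
        # (length N-h+1); padding never wins the max, and pooled features
        # are independent of how much batch padding was appended
        n_valid = np.maximum(lengths - h + 1, 1)
        invalid = positions[None, :P] >= n_valid[:, None]
        R = np.where(invalid[:, None, :], -np.inf, R)
        pre_act[h] = A
        am = R.argmax(axis=2)
        argmax[h] = am
        pooled.append(np.take_along_axis(R, am[:, :, None], axis=2)[:, :, 0])
    r = np.concatenate(pooled, axis=1)
    logits = r @ params.W2.T
    return _BatchCache(
        idx=idx,
        lengths=lengths,
        V=V,
        pre_act=pre_act,
        argmax=argmax,
        r=r,
        logits=logits,
        probabilities=softmax(logits, axis=1),
    )


def backward_batch(
    cache: _BatchCache, gold: np.ndarray, params: ModelParams
) -> dict[str, np.ndarray]:
    """Gradients of the summed NLL loss w.r.t. every group of θ.

    ``gold`` holds class indices (B,).  The PAD embedding row's gradient
    is zeroed so it never moves off zero.
    """
    B = cache.idx.shape[0]
    dlogits = cache.probabilities.copy()
    dlogits[np.arange(B), gold] -= 1.0  # d(sum NLL)/dI
    grads: dict[str, np.ndarray] = {
        "W2": dlogits.T @ cache.r,
        "D": np.zeros_like(params.D),
    }
    dr = dlogits @ params.W2  # (B, K*M)
    dV = np.zeros_like(cache.V)
    M = params.n_filters
    for ki, h in enumerate(params.windows):
        dpool = dr[:, ki * M : (ki + 1) * M]  # (B, M)
        A = cache.pre_act[h]
        am = cache.argmax[h]  # (B, M)
        picked = np.take_along_axis(A, am[:, :, None], axis=2)[:, :, 0]
        dA_at = dpool * (picked > 0.0)  # relu subgradient at the winner
        P = A.shape[2]
        dA = np.zeros_like(A)
        np.put_along_axis(dA, am[:, :, None], dA_at[:, :, None], axis=2)
        grads[f"conv_b_{h}"] = dA.sum(axis=(0, 2))
        dW = np.zeros_like(params.conv_w[h])
        W = params.conv_w[h]
        for j in range(h):
            Vslice = cache.V[:, :, j : j + P, :]
            dW[:, :, j, :] = np.einsum("bmp,bcpd->mcd", dA, Vslice)
            dV[:, :, j : j + P, :] += np.einsum("bmp,mcd->bcpd", dA, W[:, :, j, :])
        grads[f"conv_w_{h}"] = dW
    flat_idx = cache.idx.ravel()
    for ci in range(params.D.shape[0]):
        np.add.at(
            grads["D"][ci],
            flat_idx,
            dV[:, ci].reshape(-1, params.D.shape[2]),
        )
    grads["D"][:, PAD_INDEX, :] = 0.0
    return grads


# ---------------------------------------------------------------------------
# checkpoints: a single .npz archive with a JSON metadata member


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    vocab: Vocab,
    channel_names: Sequence[str] = (),
    extra: dict | None = None,
) -> None:
    """Persist θ, the vocabulary, window sizes, class labels and channel
    manifest in one versioned archive."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "windows": list(params.windows),
        "n_filters": params.n_filters,
        "class_labels": list(params.class_labels),
        "channel_names": list(channel_names),
        "vocab": vocab.symbols,
        "extra": extra or {},
    }
    # fixed member timestamps keep identical runs byte-identical
    def _member(name: str) -> zipfile.ZipInfo:
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(_member("meta.json"), json.dumps(meta, sort_keys=True))
        for name, arr in params.flat_groups().items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(_member(f"arrays/{name}.npy"), buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ModelParams, Vocab, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"{path}: not a model checkpoint")
        arrays = {}
        for info in zf.infolist():
            if info.filename.startswith("arrays/"):
                name = info.filename[len("arrays/") : -len(".npy")]
                arrays[name] = np.load(io.BytesIO(zf.read(info)))
    windows = tuple(meta["windows"])
    params = ModelParams(
        D=arrays["D"],
        conv_w={h: arrays[f"conv_w_{h}"] for h in windows},
        conv_b={h: arrays[f"conv_b_{h}"] for h in windows},
        W2=arrays["W2"],
        windows=windows,
        n_filters=meta["n_filters"],
        class_labels=tuple(meta["class_labels"]),
    )
    params.check_shapes()
    vocab = Vocab({tok: i for i, tok in enumerate(meta["vocab"])})
    return params, vocab, meta
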