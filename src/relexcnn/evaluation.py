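"""Scoring: per-class P/R/F, the overall micro-F over positive classes,
binary interaction detection, and grouped cross-validation splits.

The overall micro-average pools true/false positives and false
negatives across the positive classes only, excluding the negative
class — the DDIExtraction 2013 convention.  Detection (DEC) collapses
every positive class to a single "interaction" label and scores the
resulting binary task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

__all__ = ["ClassMetrics", "EvalReport", "score", "cv_split"]


@dataclass(frozen=True)
class ClassMetrics:
    """Precision/recall/F for one class, in percent."""

    precision: float
    recall: float
    f_score: float
    support: int


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Per-class and pooled metrics for one prediction run."""

    per_class: dict[str, ClassMetrics]
    micro: ClassMetrics
    detection: ClassMetrics
    positive_classes: tuple[str, ...]

    def summary(self) -> str:
        lines = [f"{'class':<14}{'P':>8}{'R':>8}{'F':>8}{'support':>9}"]
        for lab, m in self.per_class.items():
            lines.append(
                f"{lab:<14}{m.precision:>8.2f}{m.recall:>8.2f}"
                f"{m.f_score:>8.2f}{m.support:>9}"
            )
        m = self.micro
        lines.append(
            f"{'overall(micro)':<14}{m.precision:>8.2f}{m.recall:>8.2f}"
            f"{m.f_score:>8.2f}{m.support:>9}"
        )
        m = self.detection
        lines.append(
            f"{'detection':<14}{m.precision:>8.2f}{m.recall:>8.2f}"
            f"{m.f_score:>8.2f}{m.support:>9}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                lab: vars(m).copy() for lab, m in self.per_class.items()
            },
            "micro": vars(self.micro).copy(),
            "detection": vars(self.detection).copy(),
            "positive_classes": list(self.positive_classes),
        }


def score(
    gold: Sequence[str],
    predicted: Sequence[str],
    positive_classes: Sequence[str],
) -> EvalReport:
    """Score predictions against gold labels.

    Per-class metrics are one-vs-rest.  The micro-average pools TP/FP/FN
    over ``positive_classes`` only.  Detection collapses all positive
    classes to one binary "interaction" label before scoring.
    """
    if len(gold) != len(predicted):
        raise ValueError(
            f"gold ({len(gold)}) and predicted ({len(predicted)}) lengths differ"
        )
    positives = tuple(positive_classes)
    pos_set = set(positives)
    all_labels = sorted(set(gold) | set(predicted) | pos_set)

    per_class: dict[str, ClassMetrics] = {}
    pooled_tp = pooled_fp = pooled_fn = 0
    for lab in all_labels:
        tp = sum(1 for g, p in zip(gold, predicted) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, predicted) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, predicted) if g == lab and p != lab)
        per_class[lab] = ClassMetrics(*_prf(tp, fp, fn), support=tp + fn)
        if lab in pos_set:
            pooled_tp += tp
            pooled_fp += fp
            pooled_fn += fn
    micro = ClassMetrics(
        *_prf(pooled_tp, pooled_fp, pooled_fn), support=pooled_tp + pooled_fn
    )

    g_bin = ["interaction" if g in pos_set else "negative" for g in gold]
    p_bin = ["interaction" if p in pos_set else "negative" for p in predicted]
    tp = sum(1 for g, p in zip(g_bin, p_bin) if g == p == "interaction")
    fp = sum(1 for g, p in zip(g_bin, p_bin) if g != "interaction" and p == "interaction")
    fn = sum(1 for g, p in zip(g_bin, p_bin) if g == "interaction" and p != "interaction")
    detection = ClassMetrics(*_prf(tp, fp, fn), support=tp + fn)
    return EvalReport(
        per_class=per_class,
        micro=micro,
        detection=detection,
        positive_classes=positives,
    )


def cv_split(
    instances: Sequence,
    k: int = 10,
    seed: int = 0,
    group_key=lambda inst: inst.sentence_id,
) -> list[tuple[list, list]]:
    """k seeded train/test partitions grouped by source sentence.

    Instances sharing a group key (default: their sentence id) always
    land in the same fold, so near-duplicate pairs from one sentence
    never leak between train and test.  Groups are dealt, after a seeded
    shuffle, to whichever fold is currently smallest, keeping fold sizes
    as balanced as the grouping allows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups: dict[Hashable, list] = {}
    for inst in instances:
        groups.setdefault(group_key(inst), []).append(inst)
    if k > len(groups):
        raise ValueError(f"k={k} exceeds the number of groups ({len(groups)})")
    keys = sorted(groups, key=str)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    folds: list[list] = [[] for _ in range(k)]
    for key in keys:
        smallest = min(range(k), key=lambda i: (len(folds[i]), i))
        folds[smallest].extend(groups[key])
    out = []
    for i in range(k):
        test = list(folds[i])
        train = [inst for j in range(k) if j != i for inst in folds[j]]
        out.append((train, test))
    return out
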