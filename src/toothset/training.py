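"""Training recipe: LR schedule, label-smoothed loss, checkpoints.

The schedule is a per-step linear warmup from 0 to the base learning rate
over the warmup steps, followed by polynomial decay
``base_lr * (1 - (t - w)/(T - w)) ** power`` down to exactly 0 at the final
step (default power 1.5, warmup 60 of 300 epochs).

The loss is cross-entropy against a smoothed target distribution
``(1 - eps) * onehot + eps / C`` with the smoothing mass spread over all C
classes including the true one (default eps 0.1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._autograd import Tensor
from .model import MultiViewSetClassifier

__all__ = ["lr_at", "smoothed_cross_entropy", "save_checkpoint", "load_checkpoint"]


def lr_at(
    step: int,
    total_steps: int,
    warmup_steps: int,
    base_lr: float,
    power: float = 1.5,
) -> float:
    """Learning rate at optimizer step ``step`` (0-based, ``<= total_steps``)."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if warmup_steps >= total_steps:
        raise ValueError("warmup must be shorter than the schedule")
    if step < warmup_steps:
        return base_lr * step / warmup_steps
    remaining = 1.0 - (step - warmup_steps) / (total_steps - warmup_steps)
    return base_lr * remaining**power


def smoothed_cross_entropy(
    logits: Tensor, true_classes: Sequence[int], eps: float, n_classes: int
) -> Tensor:
    """Mean label-smoothed cross-entropy over a batch.

    ``logits`` is a (B, C) tensor; the target for each row is
    ``(1 - eps) * onehot(true) + eps / C``.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"label smoothing must be in [0, 1), got {eps}")
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("non-finite logits")
    B, C = logits.shape
    if C != n_classes:
        raise ValueError(f"logits have {C} classes, expected {n_classes}")
    target = np.full((B, C), eps / C, dtype=np.float32)
    target[np.arange(B), np.asarray(true_classes)] += 1.0 - eps
    shifted = logits - np.max(logits.data, axis=1, keepdims=True)
    log_probs = shifted - shifted.exp().sum(axis=1, keepdims=True).log()
    return -(log_probs * target).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# Checkpoints: parameters + full estimator config + class list, one .npz file.


def save_checkpoint(clf: MultiViewSetClassifier, path) -> None:
    """Persist a fitted classifier: config, classes and all parameters."""
    if not hasattr(clf, "net_"):
        raise ValueError("classifier is not fitted")
    meta = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in clf.get_params().items()
            if not hasattr(v, "__dict__") or v is None
        },
        "classes": [str(c) for c in clf.classes_],
    }
    state = {f"param::{k}": v for k, v in clf.net_.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> MultiViewSetClassifier:
    """Rebuild a fitted classifier from :func:`save_checkpoint` output."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {
            k[len("param::"):]: archive[k]
            for k in archive.files
            if k.startswith("param::")
        }
    params = dict(meta["params"])
    for key in ("adam_betas", "views"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    clf = MultiViewSetClassifier(**params)
    clf.classes_ = np.asarray(meta["classes"])
    clf.net_ = clf._build_net(len(clf.classes_))
    clf.net_.load_state_dict(state)
    return clf
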