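"""Image preprocessing: aspect-preserving letterbox resize and augmentation.

Model inputs are square (default 224x224). Arbitrary-size photographs are
scaled so the longer dimension matches the target side, preserving aspect
ratio, and the shorter dimension is padded with black, centered (an odd
leftover pixel goes to the trailing edge). Aspect ratio is itself an
informative shape cue, so it is never distorted.

Training-time augmentation applies four spatial transforms independently,
each with its own probability: random rotation, coarse dropout (cutout
occlusion), perspective distortion, and a random affine
(translation+scale). Defaults: probabilities 0.5, 0.2, 0.2, 0.2. Dropout is
image-level occlusion — it sits in a list of spatial transforms — not
network-layer dropout. All magnitudes are configurable; degenerate
magnitudes clamp to the identity. Evaluation paths never augment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from PIL import Image

__all__ = ["AugmentationPolicy", "resize_pad", "augment", "to_unit"]


def _as_array(img) -> np.ndarray:
    if isinstance(img, Image.Image):
        img = np.asarray(img)
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {arr.shape}")
    return arr


def resize_pad(img, side: int) -> np.ndarray:
    """Letterbox an image into a ``side`` x ``side`` square.

    The content is scaled so its longer dimension equals ``side`` (aspect
    ratio preserved to within one pixel of rounding) and centered; padding
    is black (0). Idempotent on already-conforming images.
    """
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    arr = _as_array(img)
    h, w = arr.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("zero-area input image")
    if h == w == side:
        return arr.copy()
    scale = side / max(h, w)
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    resized = np.asarray(
        Image.fromarray(arr).resize((new_w, new_h), Image.BILINEAR)
    )
    out = np.zeros((side, side, 3), dtype=arr.dtype)
    top = (side - new_h) // 2
    left = (side - new_w) // 2
    out[top : top + new_h, left : left + new_w] = resized
    return out


@dataclass(frozen=True)
class AugmentationPolicy:
    """Per-transform application probabilities and magnitudes."""

    p_rotation: float = 0.5
    p_dropout: float = 0.2
    p_perspective: float = 0.2
    p_affine: float = 0.2
    rotation_deg: Tuple[float, float] = (-15.0, 15.0)
    dropout_area: float = 0.10  # max occluded fraction of the image
    perspective_scale: float = 0.2  # max corner displacement, fraction of side
    affine_translate: float = 0.10  # max shift, fraction of each dimension
    affine_scale: Tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        for name in ("p_rotation", "p_dropout", "p_perspective", "p_affine"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")

    @classmethod
    def disabled(cls) -> "AugmentationPolicy":
        return cls(p_rotation=0.0, p_dropout=0.0, p_perspective=0.0, p_affine=0.0)


def _perspective_coeffs(src, dst):
    # Solve the 8-parameter projective map sending dst corners to src corners
    # (PIL's PERSPECTIVE transform samples the source at the mapped position).
    matrix = []
    for (x, y), (u, v) in zip(dst, src):
        matrix.append([x, y, 1, 0, 0, 0, -u * x, -u * y])
        matrix.append([0, 0, 0, x, y, 1, -v * x, -v * y])
    A = np.asarray(matrix, dtype=float)
    b = np.asarray(src, dtype=float).reshape(8)
    return np.linalg.solve(A, b)


def draw_plan(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    """Sample which transforms apply this call, and their magnitudes."""
    plan = {
        "rotation": rng.random() < policy.p_rotation,
        "dropout": rng.random() < policy.p_dropout,
        "perspective": rng.random() < policy.p_perspective,
        "affine": rng.random() < policy.p_affine,
    }
    lo, hi = policy.rotation_deg
    plan["angle"] = float(rng.uniform(lo, hi))
    plan["drop_frac"] = float(rng.uniform(0.25, 1.0) * policy.dropout_area)
    plan["drop_center"] = (float(rng.random()), float(rng.random()))
    plan["corner_jitter"] = rng.uniform(
        -policy.perspective_scale, policy.perspective_scale, size=(4, 2)
    )
    plan["translate"] = rng.uniform(-policy.affine_translate, policy.affine_translate, 2)
    slo, shi = policy.affine_scale
    plan["scale"] = float(rng.uniform(slo, shi))
    return plan


def augment(img, policy: AugmentationPolicy, seed: int) -> np.ndarray:
    """Apply the stochastic augmentation pipeline; deterministic given seed.

    Output dimensions always equal input dimensions.
    """
    arr = _as_array(img)
    h, w = arr.shape[:2]
    rng = np.random.default_rng(seed)
    plan = draw_plan(policy, rng)
    pil = Image.fromarray(arr)

    if plan["rotation"] and plan["angle"] != 0.0:
        pil = pil.rotate(plan["angle"], resample=Image.BILINEAR, fillcolor=(0, 0, 0))

    if plan["dropout"] and plan["drop_frac"] > 0:
        out = np.asarray(pil).copy()
        # occluded rectangle with aspect ~1, clipped to the frame
        side_frac = float(np.sqrt(plan["drop_frac"]))
        bh, bw = max(1, int(side_frac * h)), max(1, int(side_frac * w))
        cy = int(plan["drop_center"][0] * h)
        cx = int(plan["drop_center"][1] * w)
        y0, x0 = max(0, cy - bh // 2), max(0, cx - bw // 2)
        out[y0 : y0 + bh, x0 : x0 + bw] = 0
        pil = Image.fromarray(out)

    if plan["perspective"] and policy.perspective_scale > 0:
        corners = np.asarray([(0, 0), (w, 0), (w, h), (0, h)], dtype=float)
        jitter = plan["corner_jitter"] * np.asarray([w, h], dtype=float)
        coeffs = _perspective_coeffs(corners + jitter, corners)
        pil = pil.transform(
            (w, h), Image.PERSPECTIVE, tuple(coeffs), resample=Image.BILINEAR
        )

    if plan["affine"]:
        s = plan["scale"] if plan["scale"] > 0 else 1.0
        tx, ty = plan["translate"][0] * w, plan["translate"][1] * h
        # inverse map for PIL AFFINE: output pixel -> input pixel
        a = 1.0 / s
        pil = pil.transform(
            (w, h),
            Image.AFFINE,
            (a, 0.0, -tx * a + (w / 2) * (1 - a), 0.0, a, -ty * a + (h / 2) * (1 - a)),
            resample=Image.BILINEAR,
        )

    return np.asarray(pil)


def to_unit(arr: np.ndarray, standardize: bool = False) -> np.ndarray:
    """Scale 0-255 intensities to [0,1] floats; optional per-channel z-score."""
    out = np.asarray(arr, dtype=np.float32) / 255.0
    if standardize:
        mean = out.mean(axis=(0, 1), keepdims=True)
        std = out.std(axis=(0, 1), keepdims=True) + 1e-6
        out = (out - mean) / std
    return out
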