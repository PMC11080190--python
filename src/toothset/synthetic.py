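"""Procedural multi-view image generator and simulated annotators.

Real isolated-tooth photograph collections are rarely shareable, so this
module fabricates class-balanced multi-view datasets whose class evidence is
deliberately split across views, the way tooth anatomy splits it: cusp
pattern is visible only looking along the tooth axis (occlusal/apical),
while root count, crown/root proportion and root curvature are visible only
from the side (buccal/lingual/mesial/distal). A classifier therefore has to
fuse several views to recover the class — single views are systematically
ambiguous.

Rendering is deliberately simple 2-D drawing (a crown polygon, root stems,
cusp bumps on a dark background), not photorealism: it preserves the
*information structure* of the problem, not its texture statistics.

The module also simulates a panel of noisy annotators, each a row-stochastic
confusion matrix over the label space, for exercising the weighted-vote
refinement: errors concentrate on adjacent tooth positions and on the
same-position tooth of the opposite jaw, which is where human raters
actually disagree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .records import MultiViewRecord, SIDE_VIEWS, TOP_VIEWS, VIEW_TAGS
from .taxonomy import FINE_CLASSES

__all__ = [
    "SyntheticClassSpec",
    "RaterModel",
    "render_view",
    "generate_dataset",
    "SyntheticDataset",
    "simulate_annotators",
    "separable_preset",
    "tooth_preset",
    "default_rater_panel",
]

_BACKGROUND = 18
_IVORY = np.array([232, 224, 202], dtype=float)


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Renderable attributes of one synthetic class.

    ``cusp_count`` is rendered only in the occlusal/apical views and
    ``root_count`` only in the four side views; ``crown_root_ratio`` (crown
    length / root length) and ``jaw_curvature`` (signed root-tip bend;
    positive for upper-jaw-like, negative for lower) appear in side views.
    ``variants`` optionally lists alternative (cusp_count, root_count)
    pairs; each specimen samples one uniformly, which allows building class
    pairs whose single-view marginals overlap while the joint across views
    stays separable.
    """

    code: str
    cusp_count: int
    root_count: int
    crown_root_ratio: float = 1.0
    jaw_curvature: float = 0.0
    intra_class_jitter: Mapping[str, float] = field(default_factory=dict)
    variants: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self):
        if self.cusp_count < 1 or self.root_count < 1:
            raise ValueError("cusp_count and root_count must be >= 1")
        if self.crown_root_ratio <= 0:
            raise ValueError("crown_root_ratio must be positive")
        for k, v in self.intra_class_jitter.items():
            if v < 0:
                raise ValueError(f"jitter for {k!r} must be non-negative")

    def variant_pairs(self) -> Tuple[Tuple[int, int], ...]:
        if self.variants:
            return tuple(self.variants)
        return ((self.cusp_count, self.root_count),)


def _specimen_attributes(spec: SyntheticClassSpec, jitter_seed: int) -> dict:
    """Draw the specimen-level rendered attributes (shared by all 6 views)."""
    rng = np.random.default_rng(np.random.SeedSequence([jitter_seed & 0x7FFFFFFF, 11]))
    jit = dict(spec.intra_class_jitter)
    pairs = spec.variant_pairs()
    cusp, root = pairs[rng.integers(len(pairs))]
    return {
        "cusp": int(cusp),
        "root": int(root),
        "ratio": spec.crown_root_ratio
        * float(np.exp(rng.normal(0.0, jit.get("crown_root_ratio", 0.0)))),
        "curvature": spec.jaw_curvature + float(rng.normal(0.0, jit.get("jaw_curvature", 0.0))),
        "size": float(np.exp(rng.normal(0.0, jit.get("size", 0.0)))),
    }


def _draw_top_view(draw: ImageDraw.ImageDraw, view: str, attrs: dict, w: int, h: int):
    # Crown seen along the tooth axis: an ellipse with cusp_count bumps on a
    # ring. The apical view is smaller and dimmer (root end), but by design
    # neither top view encodes root_count.
    shrink = 1.0 if view == "occlusal" else 0.72
    bright = 1.0 if view == "occlusal" else 0.78
    rx = 0.36 * w * attrs["size"] * shrink
    ry = 0.36 * h * attrs["size"] * shrink
    cx, cy = w / 2, h / 2
    body = tuple((_IVORY * bright).astype(int))
    draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=body)
    n = attrs["cusp"]
    bump_r = 0.075 * min(w, h) * shrink
    phase = 0.0 if view == "occlusal" else np.pi / n
    # cusps read as dark pits/fissures against the crown surface, the way
    # occlusal anatomy photographs: high contrast, not a subtle highlight
    pit = tuple(int(c * bright * 0.45) for c in _IVORY)
    for k in range(n):
        ang = 2 * np.pi * k / n + phase
        bx = cx + 0.55 * rx * np.cos(ang)
        by = cy + 0.55 * ry * np.sin(ang)
        draw.ellipse(
            [bx - bump_r, by - bump_r, bx + bump_r, by + bump_r],
            fill=pit,
        )


_SIDE_WIDTH = {"buccal": 1.0, "lingual": 0.92, "mesial": 0.68, "distal": 0.62}


def _draw_side_view(draw: ImageDraw.ImageDraw, view: str, attrs: dict, w: int, h: int):
    # Lateral silhouette: crown block on top, root stems below. Crown/root
    # proportion follows crown_root_ratio; root tips bend by jaw_curvature.
    total = 0.82 * h * attrs["size"]
    ratio = attrs["ratio"]
    crown_h = total * ratio / (1.0 + ratio)
    root_h = total - crown_h
    top = (h - total) / 2
    neck_y = top + crown_h
    crown_w = 0.46 * w * _SIDE_WIDTH[view] * attrs["size"]
    cx = w / 2
    body = tuple(_IVORY.astype(int))
    # crown: slightly tapered toward the neck
    draw.polygon(
        [
            (cx - crown_w / 2, top),
            (cx + crown_w / 2, top),
            (cx + crown_w / 2.6, neck_y),
            (cx - crown_w / 2.6, neck_y),
        ],
        fill=body,
    )
    n = attrs["root"]
    # fixed stem width: anatomically, individual roots do not thin out as
    # the root count grows, so total root mass scales with the count
    stem_w = crown_w / 7.0
    bend = attrs["curvature"] * root_h
    root_color = tuple((_IVORY * 0.88).astype(int))
    for k in range(n):
        frac = (k + 0.5) / n
        base_x = cx - crown_w / 2.6 + frac * (2 * crown_w / 2.6)
        tip_x = base_x + bend
        tip_y = neck_y + root_h
        draw.polygon(
            [
                (base_x - stem_w, neck_y),
                (base_x + stem_w, neck_y),
                (tip_x + stem_w * 0.35, tip_y),
                (tip_x - stem_w * 0.35, tip_y),
            ],
            fill=root_color,
        )


def render_view(
    spec: SyntheticClassSpec,
    view: str,
    jitter_seed: int,
    size: Tuple[int, int] = (256, 192),
    noise_level: float = 2.0,
) -> np.ndarray:
    """Render one view of one specimen; bit-deterministic given arguments.

    ``size`` is (width, height); the default is non-square so downstream
    letterboxing is actually exercised. ``jitter_seed`` identifies the
    specimen: all six views rendered with the same seed share one draw of
    the jittered attributes.
    """
    if view not in VIEW_TAGS:
        raise ValueError(f"unknown view tag {view!r}; expected one of {VIEW_TAGS}")
    w, h = size
    if w < 8 or h < 8:
        raise ValueError(f"image dimensions too small: {size}")
    attrs = _specimen_attributes(spec, jitter_seed)
    img = Image.new("RGB", (w, h), (_BACKGROUND,) * 3)
    draw = ImageDraw.Draw(img)
    if view in TOP_VIEWS:
        _draw_top_view(draw, view, attrs, w, h)
    else:
        _draw_side_view(draw, view, attrs, w, h)
    arr = np.asarray(img, dtype=np.float32)
    if noise_level > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([jitter_seed & 0x7FFFFFFF, 29, VIEW_TAGS.index(view)])
        )
        arr = arr + noise_rng.normal(0.0, noise_level, arr.shape)
    return np.clip(arr, 0, 255).astype(np.uint8)


@dataclass
class SyntheticDataset:
    """Generated records plus the train/test split and a long-form manifest."""

    records: List[MultiViewRecord]
    train_ids: List[str]
    test_ids: List[str]
    manifest: pd.DataFrame  # columns: specimen_id, label, view, path (or "")

    def subset(self, ids: Sequence[str]) -> List[MultiViewRecord]:
        wanted = set(ids)
        return [r for r in self.records if r.specimen_id in wanted]

    @property
    def train_records(self) -> List[MultiViewRecord]:
        return self.subset(self.train_ids)

    @property
    def test_records(self) -> List[MultiViewRecord]:
        return self.subset(self.test_ids)


def generate_dataset(
    specs: Sequence[SyntheticClassSpec],
    n_per_class: int,
    train_fraction: float = 0.765,
    seed: int = 0,
    size: Tuple[int, int] = (256, 192),
    noise_level: float = 2.0,
    out_dir: Optional[str] = None,
) -> SyntheticDataset:
    """Generate a class-balanced multi-view dataset with a random split.

    Every specimen gets exactly six images, one per view tag, all rendered
    from one specimen-level attribute draw. The split is a global random
    partition with ``round(N * train_fraction)`` training specimens,
    reproducible from ``seed``. With ``out_dir`` set, images are written as
    PNG and the manifest as CSV + JSON; otherwise images stay in memory.
    """
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate class codes in specs: {codes}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    records: List[MultiViewRecord] = []
    rows = []
    for ci, spec in enumerate(specs):
        for k in range(n_per_class):
            sid = f"{spec.code}_{k:04d}"
            jitter_seed = int(
                np.random.SeedSequence([seed, ci, k]).generate_state(1)[0] & 0x7FFFFFFF
            )
            views: Dict[str, object] = {}
            for view in VIEW_TAGS:
                arr = render_view(spec, view, jitter_seed, size=size, noise_level=noise_level)
                if out_path is not None:
                    rel = f"images/{sid}_{view}.png"
                    Image.fromarray(arr).save(out_path / rel)
                    views[view] = str(out_path / rel)
                else:
                    views[view] = arr
                rows.append(
                    {
                        "specimen_id": sid,
                        "label": spec.code,
                        "view": view,
                        "path": str(views[view]) if out_path is not None else "",
                    }
                )
            records.append(MultiViewRecord(sid, views, label=spec.code))

    manifest = pd.DataFrame(rows, columns=["specimen_id", "label", "view", "path"])
    split_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
    ids = [r.specimen_id for r in records]
    order = split_rng.permutation(len(ids))
    n_train = round(len(ids) * train_fraction)
    train_ids = sorted(ids[i] for i in order[:n_train])
    test_ids = sorted(ids[i] for i in order[n_train:])

    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        by_spec = [
            {
                "specimen_id": r.specimen_id,
                "label": r.label,
                "views": {v: str(r.views[v]) for v in VIEW_TAGS},
            }
            for r in records
        ]
        (out_path / "manifest.json").write_text(json.dumps(by_spec, indent=2))
        (out_path / "split.json").write_text(
            json.dumps({"train": train_ids, "test": test_ids}, indent=2)
        )
    return SyntheticDataset(records, train_ids, test_ids, manifest)


# ---------------------------------------------------------------------------
# Annotator simulation


@dataclass(frozen=True)
class RaterModel:
    """A simulated annotator: a row-stochastic confusion matrix over classes."""

    rater_id: str
    classes: Tuple[str, ...]
    confusion: np.ndarray  # shape (C, C), rows sum to 1

    def __post_init__(self):
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (len(self.classes), len(self.classes)):
            raise ValueError(
                f"confusion shape {conf.shape} does not match {len(self.classes)} classes"
            )
        if np.any(conf < 0):
            raise ValueError("confusion entries must be non-negative")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must each sum to 1 (tolerance 1e-9)")

    def row(self, label: str) -> np.ndarray:
        try:
            idx = self.classes.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} absent from rater {self.rater_id}'s confusion matrix"
            ) from None
        return np.asarray(self.confusion, dtype=float)[idx]


def simulate_annotators(
    true_labels: Sequence[str],
    raters: Sequence[RaterModel],
    seed: int = 0,
    specimen_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Draw one vote per (specimen, rater) from each rater's confusion row.

    Returns a long-format table with columns ``specimen_id``, ``rater_id``,
    ``label``; reproducible from ``seed`` independently of iteration order
    (each cell uses its own counter-derived substream).
    """
    if specimen_ids is None:
        specimen_ids = [f"s{i:05d}" for i in range(len(true_labels))]
    if len(specimen_ids) != len(true_labels):
        raise ValueError("specimen_ids and true_labels lengths differ")
    rows = []
    for ri, rater in enumerate(raters):
        classes = np.asarray(rater.classes, dtype=object)
        for si, (sid, label) in enumerate(zip(specimen_ids, true_labels)):
            p = rater.row(label)
            rng = np.random.default_rng(np.random.SeedSequence([seed, 3, si, ri]))
            rows.append(
                {
                    "specimen_id": sid,
                    "rater_id": rater.rater_id,
                    "label": str(classes[rng.choice(len(classes), p=p)]),
                }
            )
    return pd.DataFrame(rows, columns=["specimen_id", "rater_id", "label"])


def default_rater_panel(
    classes: Tuple[str, ...] = FINE_CLASSES,
    diagonals: Mapping[str, float] = None,
) -> List[RaterModel]:
    """Four raters with confusion concentrated where humans actually err.

    The two "reliable" raters (A0, A1) carry higher diagonal mass than the
    two image-only raters (A2, A3). Off-diagonal mass goes 60% to adjacent
    tooth positions in the same jaw and 40% to the same position in the
    opposite jaw — the two standard confusion directions for teeth.
    Only defined for the built-in 16-class tooth label space.
    """
    if diagonals is None:
        diagonals = {"A0": 0.92, "A1": 0.90, "A2": 0.78, "A3": 0.74}
    raters = []
    idx = {c: i for i, c in enumerate(classes)}
    for rater_id, diag in diagonals.items():
        conf = np.zeros((len(classes), len(classes)))
        for c in classes:
            jaw, pos = c[0], int(c[1])
            neighbors = [
                f"{jaw}{p}" for p in (pos - 1, pos + 1) if 1 <= p <= 8
            ]
            counterpart = ("L" if jaw == "U" else "U") + str(pos)
            i = idx[c]
            conf[i, i] = diag
            off = 1.0 - diag
            for nb in neighbors:
                conf[i, idx[nb]] += off * 0.6 / len(neighbors)
            conf[i, idx[counterpart]] += off * 0.4
        raters.append(RaterModel(rater_id, tuple(classes), conf))
    return raters


# ---------------------------------------------------------------------------
# Presets and exact Bayes analysis of what each view can tell

#: Class codes of the designated view-complementary pair in separable_preset.
COMPLEMENTARY_PAIR = ("C1", "C2")


def separable_preset() -> List[SyntheticClassSpec]:
    """Four zero-jitter classes, two of them a view-complementary pair.

    C1 is always (3 cusps, 1 root); C2 is (3 cusps, 2 roots) or
    (5 cusps, 1 root) with equal probability. A single top view sees only
    the cusp count and a single side view only the root count, so either
    alone misclassifies half of one pair class (Bayes accuracy 75% on the
    pair); the six-view joint identifies every class exactly.
    """
    return [
        SyntheticClassSpec("C1", cusp_count=3, root_count=1, crown_root_ratio=1.1),
        SyntheticClassSpec(
            "C2", cusp_count=3, root_count=2, crown_root_ratio=1.1,
            variants=((3, 2), (5, 1)),
        ),
        SyntheticClassSpec("C3", cusp_count=6, root_count=3, crown_root_ratio=0.9),
        SyntheticClassSpec("C4", cusp_count=4, root_count=2, crown_root_ratio=1.35),
    ]


def tooth_preset(jitter_scale: float = 1.0) -> List[SyntheticClassSpec]:
    """Sixteen classes shaped like the tooth label space.

    Cusp count encodes the position 1-8 (top views), root count encodes the
    position group (1 anterior, 2 premolar, 3 molar; side views) and the
    sign of the root curvature encodes the jaw (side views). Jitter makes
    adjacent positions and jaw counterparts genuinely confusable.
    """
    jit = {
        "crown_root_ratio": 0.05 * jitter_scale,
        "jaw_curvature": 0.08 * jitter_scale,
        "size": 0.07 * jitter_scale,
    }
    specs = []
    for jaw, curv in (("U", 0.35), ("L", -0.35)):
        for pos in range(1, 9):
            group_roots = 1 if pos <= 3 else (2 if pos <= 5 else 3)
            specs.append(
                SyntheticClassSpec(
                    code=f"{jaw}{pos}",
                    cusp_count=pos,
                    root_count=group_roots,
                    crown_root_ratio=1.25 - 0.06 * pos,
                    jaw_curvature=curv,
                    intra_class_jitter=jit,
                )
            )
    return specs


def _evidence(spec: SyntheticClassSpec, cusp: int, root: int, view: Optional[str]):
    """The zero-jitter attribute tuple observable from one view (or all six)."""
    top = ("cusp", cusp)
    side = ("root", root, round(spec.crown_root_ratio, 9), round(spec.jaw_curvature, 9))
    if view is None:
        return top + side
    if view in TOP_VIEWS:
        return top
    if view in SIDE_VIEWS:
        return side
    raise ValueError(f"unknown view tag {view!r}")


def bayes_accuracy(
    specs: Sequence[SyntheticClassSpec],
    view: Optional[str] = None,
    restrict_to: Optional[Sequence[str]] = None,
) -> float:
    """Exact Bayes accuracy at zero jitter, by exhaustive attribute comparison.

    ``view=None`` uses the full six-view evidence; otherwise only what the
    named view renders. ``restrict_to`` conditions the problem on a subset
    of classes (uniform prior over them).
    """
    wanted = set(restrict_to) if restrict_to is not None else {s.code for s in specs}
    posterior: Dict[tuple, Dict[str, float]] = {}
    n_classes = len(wanted)
    for spec in specs:
        if spec.code not in wanted:
            continue
        pairs = spec.variant_pairs()
        for cusp, root in pairs:
            e = _evidence(spec, cusp, root, view)
            posterior.setdefault(e, {})
            posterior[e][spec.code] = (
                posterior[e].get(spec.code, 0.0) + 1.0 / (n_classes * len(pairs))
            )
    return float(sum(max(post.values()) for post in posterior.values()))
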