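"""Manifests, run configuration and report I/O.

The canonical manifest is a long-format CSV with one row per image and
columns ``specimen_id, label, view, path``; a JSON variant (one object per
specimen with a ``views`` mapping) is accepted interchangeably. Every
specimen must carry exactly six rows, one per view tag. Labels may be
canonical codes (``U6``) or two-digit FDI codes (``16``/``26``), which are
normalized on load; left/right is collapsed.

Run configuration is a YAML document with sections ``data``, ``augment``,
``model``, ``train``, ``eval`` plus a global ``seed`` and ``out_dir``.
Unknown keys are rejected; the fully resolved configuration (all defaults
materialized) is serialized with every run, and its hash stamped into
reports for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .evaluation import EvalReport
from .records import MultiViewRecord, VIEW_TAGS
from .taxonomy import normalize_label

__all__ = [
    "load_manifest",
    "write_manifest",
    "load_annotations",
    "load_config",
    "config_hash",
    "write_report",
    "load_report",
]


def _normalize_if_tooth(label) -> str:
    """Normalize tooth/FDI codes; pass other class codes through verbatim
    (the toolkit also serves generic multi-view set problems)."""
    try:
        return normalize_label(label)
    except ValueError:
        return str(label).strip()


def _records_from_rows(rows: List[dict], base: Optional[Path]) -> List[MultiViewRecord]:
    by_spec: Dict[str, dict] = {}
    order: List[str] = []
    for row in rows:
        sid = str(row["specimen_id"])
        if sid not in by_spec:
            by_spec[sid] = {"views": {}, "label": None}
            order.append(sid)
        view = str(row["view"]).strip().lower()
        if view not in VIEW_TAGS:
            raise ValueError(
                f"specimen {sid!r}: unknown view tag {view!r}; expected one of {VIEW_TAGS}"
            )
        if view in by_spec[sid]["views"]:
            raise ValueError(f"specimen {sid!r}: duplicate view {view!r}")
        path = row["path"]
        if base is not None and path and not Path(path).is_absolute():
            path = str(base / path)
        by_spec[sid]["views"][view] = path
        label = row.get("label")
        if label is not None and str(label) != "" and not pd.isna(label):
            by_spec[sid]["label"] = _normalize_if_tooth(label)

    records = []
    for sid in order:
        entry = by_spec[sid]
        missing = [v for v in VIEW_TAGS if v not in entry["views"]]
        if missing:
            raise ValueError(f"specimen {sid!r}: missing views {missing}")
        records.append(MultiViewRecord(sid, entry["views"], label=entry["label"]))
    return records


def load_manifest(path) -> List[MultiViewRecord]:
    """Read a CSV (long) or JSON (per-specimen) manifest into records.

    Relative image paths are resolved against the manifest's directory.
    An empty manifest is valid and yields an empty list.
    """
    path = Path(path)
    base = path.parent
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text() or "[]")
        rows = [
            {
                "specimen_id": spec["specimen_id"],
                "label": spec.get("label"),
                "view": view,
                "path": p,
            }
            for spec in doc
            for view, p in spec["views"].items()
        ]
        return _records_from_rows(rows, base)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    required = {"specimen_id", "view", "path"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)} (plus optional label)"
        )
    return _records_from_rows(frame.to_dict("records"), base)


def write_manifest(records: Sequence[MultiViewRecord], path) -> None:
    """Write records as a long-format CSV manifest."""
    rows = [
        {
            "specimen_id": r.specimen_id,
            "label": r.label or "",
            "view": view,
            "path": r.views[view] if isinstance(r.views[view], str) else "",
        }
        for r in records
        for view in VIEW_TAGS
    ]
    pd.DataFrame(rows, columns=["specimen_id", "label", "view", "path"]).to_csv(
        path, index=False
    )


def load_annotations(path) -> pd.DataFrame:
    """Read a rater annotation CSV (specimen_id, rater_id, label)."""
    frame = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "rater_id", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    frame["label"] = frame["label"].map(_normalize_if_tooth)
    return frame


# ---------------------------------------------------------------------------
# Run configuration

CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs/default",
    "data": {
        "preset": "tooth",  # or "separable"
        "n_per_class": 50,
        "train_fraction": 0.765,
        "image_width": 256,
        "image_height": 192,
        "noise_level": 2.0,
        "jitter_scale": 1.0,
    },
    "augment": {
        "p_rotation": 0.5,
        "p_dropout": 0.2,
        "p_perspective": 0.2,
        "p_affine": 0.2,
        "rotation_deg": [-15.0, 15.0],
        "dropout_area": 0.10,
        "perspective_scale": 0.2,
        "affine_translate": 0.10,
        "affine_scale": [0.9, 1.1],
        "enabled": True,
    },
    "model": {
        "encoder": "tiny",
        "embedding_dim": 512,
        "fusion_layers": 2,
        "fusion_heads": 8,
        "mlp_ratio": 4,
        "pooling": "learned_token",
        "view_embedding": True,
        "image_size": 224,
    },
    "train": {
        "epochs": 300,
        "warmup_epochs": 60,
        "poly_power": 1.5,
        "base_lr": 1e-4,
        "weight_decay": 0.5,
        "adam_betas": [0.9, 0.99],
        "decoupled_decay": True,
        "label_smoothing": 0.1,
        "batch_specimens": 16,
    },
    "eval": {
        "ks": [1, 2, 3],
        "granularities": ["16-type", "6-type", "3-type"],
        "n_boot": 2000,
    },
    "consensus": {
        "weights": {"A0": 2.0, "A1": 2.0, "A2": 1.0, "A3": 1.0},
        "threshold": 4.0,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and key != "weights":
            if not isinstance(value, dict):
                raise ValueError(f"configuration section {path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(source=None) -> dict:
    """Resolve a YAML config file (or dict) against the defaults.

    Unknown keys raise; the returned dict has every default materialized.
    """
    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        override = yaml.safe_load(Path(source).read_text()) or {}
    return _merge(CONFIG_DEFAULTS, override)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration, for provenance."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def classifier_from_config(config: dict):
    """Build an unfitted MultiViewSetClassifier from a resolved config."""
    from .model import MultiViewSetClassifier
    from .preprocessing import AugmentationPolicy

    aug_cfg = dict(config["augment"])
    enabled = aug_cfg.pop("enabled")
    policy = (
        AugmentationPolicy(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in aug_cfg.items()
            }
        )
        if enabled
        else None
    )
    m, t = config["model"], config["train"]
    return MultiViewSetClassifier(
        encoder=m["encoder"],
        embedding_dim=m["embedding_dim"],
        fusion_layers=m["fusion_layers"],
        fusion_heads=m["fusion_heads"],
        mlp_ratio=m["mlp_ratio"],
        pooling=m["pooling"],
        view_embedding=m["view_embedding"],
        image_size=m["image_size"],
        epochs=t["epochs"],
        warmup_epochs=t["warmup_epochs"],
        poly_power=t["poly_power"],
        base_lr=t["base_lr"],
        weight_decay=t["weight_decay"],
        adam_betas=tuple(t["adam_betas"]),
        decoupled_decay=t["decoupled_decay"],
        label_smoothing=t["label_smoothing"],
        batch_specimens=t["batch_specimens"],
        augment_policy=policy,
        seed=config["seed"],
    )


# ---------------------------------------------------------------------------
# Reports


def write_report(report: EvalReport, path) -> None:
    """Serialize an EvalReport to JSON (NaN encoded as null)."""
    doc = report.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=False))


def load_report(path) -> EvalReport:
    doc = json.loads(Path(path).read_text())
    return EvalReport(n=doc["n"], granularities=doc["granularities"], meta=doc["meta"])
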