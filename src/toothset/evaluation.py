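"""Hierarchical evaluation: top-k accuracy, confusion, per-class rates,
ROC/AUC, and chance-corrected agreement.

All metrics compare model output against the pseudo-ground-truth (P-GT)
labels, at each classification granularity. Coarser granularities are
evaluated from the same fine-class probability matrix by *merging
probabilities*: a super-category's probability is the sum of its members'
probabilities (the argmax-then-merge alternative is reported alongside).

Rank convention for top-k: the rank of the true class is one plus the
number of classes with strictly greater probability, so ties resolve in
favor of the true class; ties are measure-zero for real models.

Agreement: Cohen's kappa (two labelings, asymptotic 95% CI) and Fleiss'
kappa (a panel of raters, percentile-bootstrap 95% CI over specimens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats import inter_rater as _ir

from .records import MultiViewRecord, VIEW_TAGS
from .taxonomy import DEFAULT_TAXONOMY, as_granularity, regroup_label

__all__ = [
    "rank_of_true",
    "topk_accuracy",
    "regroup_probabilities",
    "regroup_labels",
    "confusion",
    "sensitivity_specificity",
    "roc_auc",
    "cohen_kappa",
    "fleiss_kappa",
    "EvalReport",
    "evaluate_probabilities",
    "export_embeddings",
    "feature_heatmaps",
]


def _label_indices(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([index[l] for l in labels])
    except KeyError as exc:
        raise ValueError(
            f"label {exc.args[0]!r} is not among the evaluated classes"
        ) from None


def rank_of_true(probs: np.ndarray, true_idx: np.ndarray) -> np.ndarray:
    """1-based rank of the true class in each row, ties favoring the truth."""
    true_p = probs[np.arange(len(probs)), true_idx]
    return 1 + (probs > true_p[:, None]).sum(axis=1)


def topk_accuracy(
    probs: np.ndarray, labels: Sequence, classes: Sequence, k: int
) -> float:
    """Fraction of rows whose true class ranks within the top k."""
    probs = np.asarray(probs, dtype=float)
    if not 1 <= k <= probs.shape[1]:
        raise ValueError(f"k must be in [1, {probs.shape[1]}], got {k}")
    if len(labels) != len(probs):
        raise ValueError("labels and probability rows are misaligned")
    true_idx = _label_indices(labels, classes)
    return float(np.mean(rank_of_true(probs, true_idx) <= k))


def regroup_probabilities(
    probs: np.ndarray,
    classes: Sequence[str],
    target,
    taxonomy=DEFAULT_TAXONOMY,
) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Merge fine-class probability columns into super-category columns.

    Returns the coarse matrix and its column codes. Rows keep their total
    mass, so distributions stay distributions.
    """
    gran = as_granularity(target)
    probs = np.asarray(probs, dtype=float)
    if probs.shape[1] != len(classes):
        raise ValueError("probability columns and class list are misaligned")
    if gran.level == "16-type":  # the finest level: no merging, any class set
        return probs.copy(), tuple(classes)
    out = np.zeros((probs.shape[0], gran.n_classes))
    col = {c: i for i, c in enumerate(gran.classes)}
    for j, cls in enumerate(classes):
        out[:, col[regroup_label(cls, gran, taxonomy)]] += probs[:, j]
    return out, tuple(gran.classes)


def regroup_labels(labels: Sequence[str], target, taxonomy=DEFAULT_TAXONOMY) -> List[str]:
    gran = as_granularity(target)
    if gran.level == "16-type":
        return list(labels)
    return [regroup_label(l, gran, taxonomy) for l in labels]


def confusion(
    labels: Sequence, predictions: Sequence, classes: Sequence
) -> np.ndarray:
    """Count matrix: entry (i, j) = specimens with true class i predicted j."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions are misaligned")
    return _sk_confusion(labels, predictions, labels=list(classes))


def sensitivity_specificity(conf: np.ndarray) -> Dict[str, np.ndarray]:
    """One-vs-rest sensitivity and specificity per class, plus macro means.

    Classes with zero support have undefined sensitivity (NaN) and are
    excluded from the macro mean with a warning.
    """
    conf = np.asarray(conf, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {conf.shape}")
    n = conf.sum()
    tp = np.diag(conf)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = n - tp - fn - fp
    support = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(support > 0, tp / (tp + fn), np.nan)
        spec = tn / (tn + fp)
    if np.isnan(sens).any():
        warnings.warn(
            "classes with zero support excluded from macro sensitivity",
            stacklevel=2,
        )
    return {
        "sensitivity": sens,
        "specificity": spec,
        "macro_sensitivity": float(np.nanmean(sens)),
        "macro_specificity": float(np.nanmean(spec)),
    }


def roc_auc(
    probs: np.ndarray, labels: Sequence, classes: Sequence
) -> Dict[str, object]:
    """One-vs-rest ROC per class (threshold sweep), AUC by the trapezoid rule.

    A class that is all-positive or all-negative in the sample has no ROC;
    its AUC is reported as NaN and skipped in the macro mean.
    """
    probs = np.asarray(probs, dtype=float)
    true_idx = _label_indices(labels, classes)
    aucs = np.full(len(classes), np.nan)
    for j in range(len(classes)):
        positives = true_idx == j
        if positives.all() or not positives.any():
            continue
        fpr, tpr, _ = _sk_roc_curve(positives.astype(int), probs[:, j])
        aucs[j] = float(np.trapezoid(tpr, fpr))
    macro = float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan")
    return {"auc": aucs, "macro_auc": macro}


def cohen_kappa(
    labels_a: Sequence, labels_b: Sequence
) -> Dict[str, float]:
    """Cohen's kappa between two labelings with an asymptotic 95% CI."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings are misaligned")
    a = pd.Categorical(labels_a)
    cats = sorted(set(a.categories) | set(pd.Categorical(labels_b).categories))
    table = pd.crosstab(
        pd.Categorical(labels_a, categories=cats),
        pd.Categorical(labels_b, categories=cats),
        dropna=False,
    ).to_numpy()
    marg_a = table.sum(axis=1) / table.sum()
    marg_b = table.sum(axis=0) / table.sum()
    p_e = float(marg_a @ marg_b)
    if p_e >= 1.0 - 1e-12:
        # both labelings constant and identical: perfect but degenerate
        warnings.warn("degenerate kappa: both labelings constant", stacklevel=2)
        return {"kappa": 1.0, "ci_low": 1.0, "ci_high": 1.0}
    res = _ir.cohens_kappa(table, return_results=True)
    return {
        "kappa": float(res.kappa),
        "ci_low": float(res.kappa_low),
        "ci_high": float(res.kappa_upp),
    }


def _fleiss_counts(label_matrix: np.ndarray) -> Tuple[np.ndarray, List]:
    cats = sorted(set(label_matrix.ravel().tolist()))
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((label_matrix.shape[0], len(cats)), dtype=int)
    for i, row in enumerate(label_matrix):
        for lab in row:
            counts[i, index[lab]] += 1
    return counts, cats


def fleiss_kappa(
    label_matrix,
    n_boot: int = 2000,
    seed: int = 0,
) -> Dict[str, float]:
    """Fleiss' kappa for a (specimens x raters) label matrix.

    Every specimen must be rated by the same number of raters. The 95% CI
    is a seeded percentile bootstrap over specimens (``n_boot`` resamples).
    """
    mat = np.asarray(label_matrix, dtype=object)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D (specimens x raters) matrix with >= 2 raters")
    counts, _ = _fleiss_counts(mat)
    kappa = float(_ir.fleiss_kappa(counts))
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        resample = counts[rng.integers(0, n, size=n)]
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = _ir.fleiss_kappa(resample)
    boots = boots[np.isfinite(boots)]
    lo, hi = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if len(boots)
        else (float("nan"), float("nan"))
    )
    return {"kappa": kappa, "ci_low": lo, "ci_high": hi}


def fleiss_kappa_table(
    annotations: pd.DataFrame,
    granularity="16-type",
    n_boot: int = 2000,
    seed: int = 0,
    taxonomy=DEFAULT_TAXONOMY,
) -> Dict[str, float]:
    """Fleiss' kappa from a long (specimen_id, rater_id, label) table."""
    wide = annotations.pivot(index="specimen_id", columns="rater_id", values="label")
    if wide.isna().any().any():
        raise ValueError("unequal rater counts per specimen")
    gran = as_granularity(granularity)
    values = wide.to_numpy()
    if gran.level != "16-type":
        values = np.vectorize(lambda l: regroup_label(l, gran, taxonomy))(values)
    return fleiss_kappa(values, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# The full report


@dataclass
class EvalReport:
    """All metrics at every evaluated granularity, JSON-serializable."""

    n: int
    granularities: Dict[str, dict]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [clean(v) for v in np.asarray(obj).tolist()]
            if isinstance(obj, (np.floating, float)):
                return None if not np.isfinite(obj) else float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return clean({"n": self.n, "granularities": self.granularities, "meta": self.meta})


def evaluate_probabilities(
    probs: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str],
    granularities: Sequence = ("16-type", "6-type", "3-type"),
    ks: Sequence[int] = (1, 2, 3),
    taxonomy=DEFAULT_TAXONOMY,
    kappa: bool = True,
    meta: Optional[dict] = None,
) -> EvalReport:
    """Evaluate a fine-class probability matrix at every granularity.

    For each granularity the fine probabilities are merged (sum over
    member classes) and the P-GT labels regrouped; top-k accuracies,
    the confusion matrix, per-class sensitivity/specificity, one-vs-rest
    AUCs and Cohen's kappa between P-GT and argmax prediction are computed
    on the merged problem. The argmax-then-merge top-1 is reported
    alongside the default merge-then-argmax.
    """
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    if n != len(labels):
        raise ValueError("labels and probability rows are misaligned")
    fine_pred_idx = probs.argmax(axis=1)
    fine_pred = [classes[i] for i in fine_pred_idx]
    out: Dict[str, dict] = {}
    for target in granularities:
        gran = as_granularity(target)
        g_probs, g_classes = regroup_probabilities(probs, classes, gran, taxonomy)
        g_labels = regroup_labels(labels, gran, taxonomy)
        g_pred = [g_classes[i] for i in g_probs.argmax(axis=1)]
        g_pred_argmax_merge = regroup_labels(fine_pred, gran, taxonomy)
        conf = confusion(g_labels, g_pred, g_classes)
        rates = sensitivity_specificity(conf)
        roc = roc_auc(g_probs, g_labels, g_classes)
        entry = {
            "classes": list(g_classes),
            "topk": {
                str(int(k)): topk_accuracy(g_probs, g_labels, g_classes, k)
                for k in ks
                if k <= len(g_classes)
            },
            "top1_argmax_merged": float(
                np.mean(np.asarray(g_pred_argmax_merge) == np.asarray(g_labels))
            ),
            "confusion": conf,
            "sensitivity": rates["sensitivity"],
            "specificity": rates["specificity"],
            "macro_sensitivity": rates["macro_sensitivity"],
            "macro_specificity": rates["macro_specificity"],
            "auc": roc["auc"],
            "macro_auc": roc["macro_auc"],
        }
        if kappa:
            entry["cohen_kappa"] = cohen_kappa(g_labels, g_pred)
        out[gran.level] = entry
    return EvalReport(n=n, granularities=out, meta=meta or {})


# ---------------------------------------------------------------------------
# Model introspection exports


def export_embeddings(clf, records: Sequence[MultiViewRecord]) -> pd.DataFrame:
    """One row per specimen: id, the d-dim set embedding, predicted class.

    Suitable input for any 2-D neighbor-embedding projection.
    """
    emb = clf.embed(list(records))
    pred = clf.predict(list(records))
    frame = pd.DataFrame(emb, columns=[f"e{i}" for i in range(emb.shape[1])])
    frame.insert(0, "specimen_id", [r.specimen_id for r in records])
    frame["predicted"] = pred
    return frame


def feature_heatmaps(
    clf, record: MultiViewRecord, n_channels: int = 15, alpha: float = 0.55
) -> Dict[str, np.ndarray]:
    """Absolute-value channel heatmaps of the encoder's final feature map,
    upsampled and alpha-blended over each original view image.

    Returns per view an array (n_channels, H, W, 3) of uint8 overlays; the
    heat is rendered in the red channel, the original image dimmed under it.
    """
    from PIL import Image

    out = {}
    for view in VIEW_TAGS:
        img = record.image(view)
        fmap = np.abs(clf.view_feature_map(img))  # (C, h, w), non-negative
        if n_channels > fmap.shape[0]:
            raise ValueError(
                f"requested {n_channels} channels, encoder has {fmap.shape[0]}"
            )
        h, w = img.shape[:2]
        overlays = np.empty((n_channels, h, w, 3), dtype=np.uint8)
        for c in range(n_channels):
            chan = fmap[c]
            peak = chan.max()
            norm = chan / peak if peak > 0 else np.zeros_like(chan)
            heat = np.asarray(
                Image.fromarray((norm * 255).astype(np.uint8)).resize(
                    (w, h), Image.BILINEAR
                ),
                dtype=float,
            ) / 255.0
            base = img.astype(float) * (1 - alpha)
            base[..., 0] += alpha * 255.0 * heat
            overlays[c] = np.clip(base, 0, 255).astype(np.uint8)
        out[view] = overlays
    return out
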