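"""toothset: multi-view image-set classification toolkit.

Classifies an object photographed from several standardized directions —
the motivating case is an isolated tooth photographed from six views — by
encoding every view with one shared-weight convolutional encoder, fusing
the view features with a Transformer attention encoder, and reading out
class probabilities. Around the classifier the package provides weighted
multi-rater vote refinement into pseudo-ground-truth labels, a hierarchical
(16/6/3-type) evaluation protocol with top-k accuracy, per-class rates,
ROC/AUC and kappa agreement, and a procedural synthetic data generator
whose class evidence is split across views.
"""

from .consensus import AnnotationSet, RefinementResult, refine, refine_table, score_categories
from .evaluation import (
    EvalReport,
    cohen_kappa,
    confusion,
    evaluate_probabilities,
    export_embeddings,
    feature_heatmaps,
    fleiss_kappa,
    fleiss_kappa_table,
    regroup_probabilities,
    roc_auc,
    sensitivity_specificity,
    topk_accuracy,
)
from .manifest import load_config, load_manifest, load_report, write_manifest, write_report
from .model import MultiViewSetClassifier, records_to_array
from .preprocessing import AugmentationPolicy, augment, resize_pad
from .records import SIDE_VIEWS, TOP_VIEWS, VIEW_TAGS, MultiViewRecord
from .synthetic import (
    RaterModel,
    SyntheticClassSpec,
    bayes_accuracy,
    default_rater_panel,
    generate_dataset,
    render_view,
    separable_preset,
    simulate_annotators,
    tooth_preset,
)
from .taxonomy import (
    FINE_CLASSES,
    DEFAULT_TAXONOMY,
    Granularity,
    LabelTaxonomy,
    normalize_label,
    regroup_counts,
    regroup_label,
)
from .training import lr_at, load_checkpoint, save_checkpoint, smoothed_cross_entropy

__version__ = "0.1.0"

__all__ = [
    "AnnotationSet",
    "AugmentationPolicy",
    "DEFAULT_TAXONOMY",
    "EvalReport",
    "FINE_CLASSES",
    "Granularity",
    "LabelTaxonomy",
    "MultiViewRecord",
    "MultiViewSetClassifier",
    "RaterModel",
    "RefinementResult",
    "SIDE_VIEWS",
    "SyntheticClassSpec",
    "TOP_VIEWS",
    "VIEW_TAGS",
    "augment",
    "bayes_accuracy",
    "cohen_kappa",
    "confusion",
    "default_rater_panel",
    "evaluate_probabilities",
    "export_embeddings",
    "feature_heatmaps",
    "fleiss_kappa",
    "fleiss_kappa_table",
    "generate_dataset",
    "load_checkpoint",
    "load_config",
    "load_manifest",
    "load_report",
    "lr_at",
    "normalize_label",
    "records_to_array",
    "refine",
    "refine_table",
    "regroup_counts",
    "regroup_label",
    "regroup_probabilities",
    "render_view",
    "resize_pad",
    "roc_auc",
    "save_checkpoint",
    "score_categories",
    "sensitivity_specificity",
    "separable_preset",
    "simulate_annotators",
    "smoothed_cross_entropy",
    "tooth_preset",
    "topk_accuracy",
    "write_manifest",
    "write_report",
]
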