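"""Weighted-vote consensus for multi-rater labels (pseudo-ground-truth).

When the true class of a specimen is unknowable, multiple raters of varying
reliability each assign a label, and a weighted vote converts the votes into
a single pseudo-ground-truth (P-GT) label — or removes the specimen as
ambiguous. Each rater carries a fixed positive weight; a category's score is
the summed weight of the raters voting for it. A specimen is accepted iff
some category's score reaches the acceptance threshold, and the accepted
label is the unique highest-scoring such category.

The default configuration has four raters with weights 2, 2, 1, 1 and
threshold 4 (total weight 6). Under these defaults acceptance is equivalent
to a two-condition rule: either the two weight-2 raters agree, or one
weight-2 rater agrees with both weight-1 raters — and no vote assignment can
put two categories at the threshold simultaneously (that would need total
weight >= 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

__all__ = [
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLD",
    "AnnotationSet",
    "SpecimenOutcome",
    "RefinementResult",
    "score_categories",
    "refine",
]

DEFAULT_WEIGHTS: Dict[str, float] = {"A0": 2.0, "A1": 2.0, "A2": 1.0, "A3": 1.0}
DEFAULT_THRESHOLD: float = 4.0

#: Sentinel outcome for specimens filtered out as ambiguous.
REMOVED = "REMOVED"


@dataclass(frozen=True)
class AnnotationSet:
    """One specimen's rater votes, rater weights and acceptance threshold."""

    specimen_id: str
    votes: Mapping[str, str]
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        for rater, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"rater {rater!r} has non-positive weight {w}")


@dataclass(frozen=True)
class SpecimenOutcome:
    """Refinement outcome for one specimen: accepted label or REMOVED."""

    specimen_id: str
    label: Optional[str]  # None iff removed
    scores: Dict[str, float]

    @property
    def removed(self) -> bool:
        return self.label is None


@dataclass(frozen=True)
class RefinementResult:
    """Per-specimen outcomes plus kept/removed bookkeeping."""

    outcomes: List[SpecimenOutcome]

    @property
    def kept(self) -> int:
        return sum(not o.removed for o in self.outcomes)

    @property
    def removed(self) -> int:
        return sum(o.removed for o in self.outcomes)

    @property
    def accepted_labels(self) -> Dict[str, str]:
        return {o.specimen_id: o.label for o in self.outcomes if not o.removed}

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "removed": self.removed,
            "per_specimen_scores": {
                o.specimen_id: {
                    "outcome": o.label if not o.removed else REMOVED,
                    "scores": o.scores,
                }
                for o in self.outcomes
            },
        }


def score_categories(
    votes: Mapping[str, str], weights: Mapping[str, float]
) -> Dict[str, float]:
    """Sum rater weights per voted category.

    Votes and weights must cover exactly the same raters; the scores always
    sum to the total rater weight.
    """
    extra_votes = sorted(set(votes) - set(weights))
    extra_weights = sorted(set(weights) - set(votes))
    if extra_votes or extra_weights:
        raise ValueError(
            "votes and weights cover different raters: "
            f"vote-without-weight={extra_votes}, weight-without-vote={extra_weights}"
        )
    scores: Dict[str, float] = {}
    for rater, label in votes.items():
        scores[label] = scores.get(label, 0.0) + float(weights[rater])
    return scores


def _resolve(annotation: AnnotationSet) -> SpecimenOutcome:
    scores = score_categories(annotation.votes, annotation.weights)
    reaching = [c for c, s in scores.items() if s >= annotation.threshold]
    if not reaching:
        return SpecimenOutcome(annotation.specimen_id, None, scores)
    best = max(reaching, key=lambda c: scores[c])
    # A tie at the top among threshold-reaching categories is ambiguous by
    # construction; treat as removed. Unreachable under the default
    # weights/threshold (two categories at >=4 would need total weight 8).
    ties = [c for c in reaching if scores[c] == scores[best]]
    if len(ties) > 1:
        return SpecimenOutcome(annotation.specimen_id, None, scores)
    return SpecimenOutcome(annotation.specimen_id, best, scores)


def refine(annotations: Sequence[AnnotationSet]) -> RefinementResult:
    """Apply the weighted vote to every specimen.

    Accepted specimens get their argmax category as P-GT; specimens where no
    category reaches the threshold (or two tie at the maximum, under
    non-default configurations) are removed. ``kept + removed`` always
    equals the number of input specimens.
    """
    seen = set()
    outcomes = []
    for ann in annotations:
        if ann.specimen_id in seen:
            raise ValueError(f"duplicate specimen id {ann.specimen_id!r}")
        seen.add(ann.specimen_id)
        outcomes.append(_resolve(ann))
    return RefinementResult(outcomes)


def refine_table(
    table,
    weights: Mapping[str, float] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> RefinementResult:
    """Refine a long-format annotation table.

    ``table`` is a pandas DataFrame with columns ``specimen_id``,
    ``rater_id``, ``label``. Every specimen must carry exactly one vote per
    rater in ``weights`` (defaults to the four-rater 2/2/1/1 scheme).
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    annotations = []
    for specimen_id, group in table.groupby("specimen_id", sort=True):
        votes = dict(zip(group["rater_id"], group["label"]))
        if len(votes) != len(group):
            raise ValueError(f"specimen {specimen_id!r} has duplicate rater votes")
        annotations.append(
            AnnotationSet(str(specimen_id), votes, weights, threshold)
        )
    return refine(annotations)
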