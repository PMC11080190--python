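"""Label space for isolated-tooth classification and its nested granularities.

The fine label space has 16 classes: eight tooth positions per jaw, written
``U1``..``U8`` (upper/maxillary) and ``L1``..``L8`` (lower/mandibular),
without distinguishing left from right. Two coarser partitions are defined
by merging positions into tooth types:

* 6-type — anterior (positions 1-3), premolar (4-5) and molar (6-8),
  separately per jaw: ``UA, UP, UM, LA, LP, LM``.
* 3-type — the same position groups with the jaw discarded: ``A, P, M``.

The three levels are nested: 16 -> 6 -> 3 is a chain of surjections, so any
count vector or probability vector at a finer level can be aggregated to a
coarser one without loss of total mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

__all__ = [
    "FINE_CLASSES",
    "SIX_TYPE_CLASSES",
    "THREE_TYPE_CLASSES",
    "GRANULARITIES",
    "Granularity",
    "LabelTaxonomy",
    "DEFAULT_TAXONOMY",
    "normalize_label",
    "regroup_label",
    "regroup_counts",
]

#: Fine classes in canonical report order: upper jaw 1-8, then lower jaw 1-8.
FINE_CLASSES: tuple = tuple(f"U{i}" for i in range(1, 9)) + tuple(
    f"L{i}" for i in range(1, 9)
)

SIX_TYPE_CLASSES = ("UA", "UP", "UM", "LA", "LP", "LM")
THREE_TYPE_CLASSES = ("A", "P", "M")

GRANULARITIES = ("16-type", "6-type", "3-type")


def _position_group(position: int) -> str:
    """Map a tooth position 1-8 to its type letter: anterior/premolar/molar."""
    if 1 <= position <= 3:
        return "A"
    if position in (4, 5):
        return "P"
    if 6 <= position <= 8:
        return "M"
    raise ValueError(f"tooth position out of range 1-8: {position}")


@dataclass(frozen=True)
class Granularity:
    """A classification granularity: its name and ordered category codes."""

    level: str
    classes: tuple

    def __post_init__(self):
        if self.level not in GRANULARITIES:
            raise ValueError(
                f"unknown granularity {self.level!r}; expected one of {GRANULARITIES}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.classes)


GRANULARITY_16 = Granularity("16-type", FINE_CLASSES)
GRANULARITY_6 = Granularity("6-type", SIX_TYPE_CLASSES)
GRANULARITY_3 = Granularity("3-type", THREE_TYPE_CLASSES)

_GRANULARITY_BY_NAME = {
    "16-type": GRANULARITY_16,
    "6-type": GRANULARITY_6,
    "3-type": GRANULARITY_3,
    "16": GRANULARITY_16,
    "6": GRANULARITY_6,
    "3": GRANULARITY_3,
    16: GRANULARITY_16,
    6: GRANULARITY_6,
    3: GRANULARITY_3,
}


def as_granularity(target) -> Granularity:
    """Coerce a granularity name (``"6-type"``, ``6`` ...) to a Granularity."""
    if isinstance(target, Granularity):
        return target
    try:
        return _GRANULARITY_BY_NAME[target]
    except KeyError:
        raise ValueError(
            f"unknown granularity {target!r}; expected one of {GRANULARITIES}"
        ) from None


@dataclass(frozen=True)
class LabelTaxonomy:
    """The 16 fine classes plus the merge maps to the 6- and 3-type levels.

    The built-in taxonomy covers the tooth label space; a custom taxonomy
    (other fine classes, other groupings) can be supplied for generic
    multi-view set problems, as long as the group maps are total and nested.
    """

    fine_classes: tuple = FINE_CLASSES
    merge_16_to_6: Mapping[str, str] = field(
        default_factory=lambda: {
            c: c[0] + ("A" if int(c[1]) <= 3 else "P" if int(c[1]) <= 5 else "M")
            for c in FINE_CLASSES
        }
    )
    merge_6_to_3: Mapping[str, str] = field(
        default_factory=lambda: {c: c[1] for c in SIX_TYPE_CLASSES}
    )

    @property
    def merge_16_to_3(self) -> Dict[str, str]:
        """Composition of the two merge steps; nestedness makes it total."""
        return {c: self.merge_6_to_3[g] for c, g in self.merge_16_to_6.items()}

    def granularity(self, target) -> Granularity:
        return as_granularity(target)

    def to_json(self) -> str:
        """Serialize as a ``{fine_classes, groups}`` JSON document."""
        return json.dumps(
            {
                "fine_classes": list(self.fine_classes),
                "groups": {
                    "6-type": dict(self.merge_16_to_6),
                    "3-type": dict(self.merge_6_to_3),
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LabelTaxonomy":
        doc = json.loads(text)
        return cls(
            fine_classes=tuple(doc["fine_classes"]),
            merge_16_to_6=dict(doc["groups"]["6-type"]),
            merge_6_to_3=dict(doc["groups"]["3-type"]),
        )


DEFAULT_TAXONOMY = LabelTaxonomy()

# FDI two-digit quadrant codes: 1x/2x are upper right/left, 3x/4x lower
# left/right. Left/right is collapsed, so only the jaw half survives.
_FDI_QUADRANT_TO_JAW = {"1": "U", "2": "U", "3": "L", "4": "L"}


def normalize_label(label) -> str:
    """Normalize a label to a canonical ``U#``/``L#`` code.

    Accepts canonical codes (any case) and two-digit FDI notation
    (e.g. ``16`` and ``26`` both normalize to ``U6``).
    """
    code = str(label).strip().upper()
    if code in FINE_CLASSES:
        return code
    if len(code) == 2 and code.isdigit():
        quadrant, position = code[0], code[1]
        if quadrant in _FDI_QUADRANT_TO_JAW and "1" <= position <= "8":
            return _FDI_QUADRANT_TO_JAW[quadrant] + position
    raise ValueError(f"unknown tooth label code: {label!r}")


def regroup_label(label: str, target, taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY) -> str:
    """Map a fine class to its super-category at ``target`` granularity.

    Identity at 16-type; e.g. ``U6`` -> ``UM`` at 6-type, ``L4`` -> ``P`` at
    3-type.
    """
    gran = as_granularity(target)
    if label not in taxonomy.merge_16_to_6:
        raise ValueError(f"unknown tooth label code: {label!r}")
    if gran.level == "16-type":
        return label
    coarse6 = taxonomy.merge_16_to_6[label]
    if gran.level == "6-type":
        return coarse6
    return taxonomy.merge_6_to_3[coarse6]


def regroup_counts(
    counts: Mapping[str, int], target, taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY
) -> Dict[str, int]:
    """Aggregate a per-fine-class count vector to ``target`` granularity.

    Every fine class must be present (use 0 for empty classes); the grand
    total is preserved exactly.
    """
    gran = as_granularity(target)
    missing = [c for c in taxonomy.fine_classes if c not in counts]
    if missing:
        raise ValueError(f"counts missing classes: {missing}")
    out: Dict[str, int] = {c: 0 for c in gran.classes}
    for cls in taxonomy.fine_classes:
        n = counts[cls]
        if n < 0:
            raise ValueError(f"negative count for class {cls}: {n}")
        out[regroup_label(cls, gran, taxonomy)] += n
    return out


def class_members(category: str, target, taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY):
    """The fine classes that merge into ``category`` at ``target``."""
    gran = as_granularity(target)
    return tuple(
        c for c in taxonomy.fine_classes if regroup_label(c, gran, taxonomy) == category
    )


def regroup_indices(target, taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY):
    """For each fine-class index, the index of its category at ``target``.

    Convenience for vectorized aggregation of count/probability matrices.
    """
    gran = as_granularity(target)
    index = {c: i for i, c in enumerate(gran.classes)}
    return [
        index[regroup_label(c, gran, taxonomy)] for c in taxonomy.fine_classes
    ]
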