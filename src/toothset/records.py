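"""The in-memory unit of data: one specimen's six view-tagged images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from PIL import Image

__all__ = ["VIEW_TAGS", "TOP_VIEWS", "SIDE_VIEWS", "MultiViewRecord"]

#: Canonical view order used everywhere a view axis appears.
VIEW_TAGS = ("occlusal", "apical", "buccal", "lingual", "mesial", "distal")
#: Views of the crown along the tooth axis (show the chewing surface).
TOP_VIEWS = ("occlusal", "apical")
#: Lateral views (show the root complex and crown/root proportion).
SIDE_VIEWS = ("buccal", "lingual", "mesial", "distal")


@dataclass
class MultiViewRecord:
    """One specimen: six view-tagged images plus an optional class label.

    ``views`` maps each view tag to either an in-memory HxWx3 uint8 array or
    a path to a PNG/JPEG file (loaded lazily by :meth:`image`).
    """

    specimen_id: str
    views: Dict[str, object]
    label: Optional[str] = None

    def __post_init__(self):
        missing = [v for v in VIEW_TAGS if v not in self.views]
        extra = [v for v in self.views if v not in VIEW_TAGS]
        if missing or extra:
            raise ValueError(
                f"specimen {self.specimen_id!r}: missing views {missing}, "
                f"unknown views {extra}"
            )

    def image(self, view: str) -> np.ndarray:
        """The HxWx3 uint8 image for one view, loading from disk if needed."""
        if view not in self.views:
            raise KeyError(f"specimen {self.specimen_id!r} has no view {view!r}")
        src = self.views[view]
        if isinstance(src, np.ndarray):
            return src
        try:
            with Image.open(src) as im:
                return np.asarray(im.convert("RGB"))
        except OSError as exc:
            raise OSError(f"cannot read image file {src!r}: {exc}") from exc

    def stacked(self) -> np.ndarray:
        """All six views in canonical order; requires equal image sizes."""
        return np.stack([self.image(v) for v in VIEW_TAGS])
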