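"""Morphological cleanup of thresholded network output.

The network emits a sigmoid probability map; prediction masks are obtained
by thresholding and then cleaned up by mathematical morphology: small
foreground fragments (8-connected, area < ``min_object_area``) are
removed and small enclosed background holes (4-connected, not touching the
image border, area <= ``max_hole_area``) are filled.  The operation is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=int)          # 8-connectivity (foreground)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity (holes)


@dataclass
class CleanupConfig:
    """Binarization threshold and area cut-offs (in pixels) for cleanup."""

    threshold: float = 0.5
    min_object_area: int = 64
    max_hole_area: int = 64

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        if self.min_object_area < 0 or self.max_hole_area < 0:
            raise ValueError("areas must be >= 0")


def binarize(prob_map, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: pixel = 1 iff p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    p = np.asarray(prob_map)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0,1]")
    return (p >= threshold).astype(np.uint8)


def morph_cleanup(mask, config: CleanupConfig | None = None) -> np.ndarray:
    """Remove small foreground components, then fill small holes."""
    config = config or CleanupConfig()
    m = np.asarray(mask)
    if not np.isin(m, (0, 1, False, True)).all():
        raise ValueError("mask must be binary")
    m = m.astype(bool)
    if not m.any():
        return m.astype(np.uint8)

    # drop 8-connected foreground components with area < min_object_area
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())
        keep = areas >= config.min_object_area
        keep[0] = False
        m = keep[labels]

    # fill 4-connected background components that do not touch the border
    # and have area <= max_hole_area
    bg_labels, n_bg = ndimage.label(~m, structure=_STRUCT4)
    if n_bg:
        border = np.zeros_like(m)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touches = np.zeros(n_bg + 1, dtype=bool)
        touches[np.unique(bg_labels[border])] = True
        areas = np.bincount(bg_labels.ravel(), minlength=n_bg + 1)
        fill = (~touches) & (areas <= config.max_hole_area)
        fill[0] = False
        m = m | fill[bg_labels]

    return m.astype(np.uint8)
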