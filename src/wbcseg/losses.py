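"""Training losses: pixelwise binary cross-entropy and focal loss.

Both losses accept either plain NumPy arrays (returning a float) or
autograd tensors (returning a scalar tensor usable for backpropagation);
labels are always plain binary arrays.  Probabilities are clamped to
[eps, 1 - eps] with eps = 1e-7 before the logarithm, so perfectly
confident predictions stay finite.

BCE is the mean of -[y log p + (1-y) log(1-p)] over the N pixels.  The
focal loss reweights each pixel's cross-entropy term by alpha (1-p)^gamma
for foreground and (1-alpha) p^gamma for background (defaults alpha=0.25,
gamma=2), emphasizing hard, misclassified pixels — the rationale for using
it on lymphocyte/monocyte-like images whose cytoplasm color is close to
the background.  With gamma=0, alpha=0.5 it reduces exactly to 0.5 * BCE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

EPS = 1e-7


@dataclass
class FocalParams:
    """Focal-loss parameters: class-balance weight alpha in (0,1) and
    focusing exponent gamma >= 0."""
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def _validate(p, y) -> np.ndarray:
    p_data = p.data if isinstance(p, Tensor) else np.asarray(p)
    y = np.asarray(y)
    if p_data.shape != y.shape:
        raise ValueError(f"prediction shape {p_data.shape} does not match "
                         f"label shape {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be strictly binary")
    return y.astype(np.float32)


def bce_loss(p, y):
    """Mean binary cross-entropy over pixels."""
    y = _validate(p, y)
    if isinstance(p, Tensor):
        pc = nn.clamp(p, EPS, 1.0 - EPS)
        return -nn.mean(y * nn.log(pc) + (1.0 - y) * nn.log(1.0 - pc))
    pc = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log1p(-pc)))


def focal_loss(p, y, params: FocalParams | None = None):
    """Mean focal loss over pixels (per-pixel terms averaged over N,
    matching the BCE reduction)."""
    params = params or FocalParams()
    a, g = params.alpha, params.gamma
    y = _validate(p, y)
    if isinstance(p, Tensor):
        pc = nn.clamp(p, EPS, 1.0 - EPS)
        pos = -a * nn.power(1.0 - pc, g) * nn.log(pc)
        neg = -(1.0 - a) * nn.power(pc, g) * nn.log(1.0 - pc)
        return nn.mean(y * pos + (1.0 - y) * neg)
    pc = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    pos = -a * (1.0 - pc) ** g * np.log(pc)
    neg = -(1.0 - a) * pc ** g * np.log1p(-pc)
    return float(np.mean(y * pos + (1.0 - y) * neg))


def get_loss(name: str, focal: FocalParams | None = None):
    """Resolve a loss by name ('bce' or 'focal') to a callable (p, y)."""
    if name == "bce":
        return bce_loss
    if name == "focal":
        params = focal or FocalParams()
        return lambda p, y: focal_loss(p, y, params)
    raise ValueError(f"unknown loss {name!r}; expected 'bce' or 'focal'")
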