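"""PNG image/mask I/O. Images are RGB float32 in [0,1] in memory; masks
are single-channel {0,1} in memory and 0/255 on disk."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def write_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(path)


def read_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return arr / 255.0


def write_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1, False, True)).all():
        raise ValueError("mask must be binary")
    Image.fromarray((m.astype(np.uint8) * 255), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)
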