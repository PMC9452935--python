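import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Desk-scale architecture: width 1/8 at side 64."""
    from wbcseg import NetworkConfig
    return NetworkConfig(input_side=64, width_multiplier=1 / 8)


# ---------------------------------------------------------------------
# independent oracles used across test modules
# ---------------------------------------------------------------------

def pixel_set(mask):
    return {tuple(p) for p in np.argwhere(np.asarray(mask).astype(bool))}


def brute_force_metrics(pred, gt):
    """Double-loop pixel-set implementations of all five metrics."""
    a, b = pixel_set(pred), pixel_set(gt)
    inter = len(a & b)
    if not a and not b:
        ratios = dict(dice=1.0, miou=1.0, ppv=1.0, sensitivity=1.0)
    else:
        ratios = dict(
            dice=2 * inter / (len(a) + len(b)) if (a or b) else 1.0,
            miou=inter / len(a | b) if (a | b) else 1.0,
            ppv=inter / len(a) if a else 0.0,
            sensitivity=inter / len(b) if b else 0.0,
        )
    hd = None
    if a and b:
        hd = max(min(((ax - bx) ** 2 + (ay - by) ** 2) ** 0.5
                     for bx, by in b) for ax, ay in a)
    ratios["hd"] = hd
    return ratios


def flood_fill_components(mask, connectivity=8):
    """Connected components by BFS flood fill; returns list of pixel sets."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy, sx in np.argwhere(mask & ~seen):
        if seen[sy, sx]:
            continue
        comp, queue = set(), [(sy, sx)]
        seen[sy, sx] = True
        while queue:
            y, x = queue.pop()
            comp.add((y, x))
            for dy, dx in nbrs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                    seen[ny, nx] = True
                    queue.append((ny, nx))
        comps.append(comp)
    return comps


@pytest.fixture
def oracles():
    return dict(metrics=brute_force_metrics, components=flood_fill_components)
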