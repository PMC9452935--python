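"""Synthetic single-leukocyte image generator, augmentation and splits.

Real single-WBC crops are hard to segment for three stated reasons: the
cytoplasm color is close to the background color (worst for lymphocytes
and monocytes), brightness is uneven across the field, and cell boundaries
are irregular and blurred.  The generator emulates exactly these factors
on a square canvas with one cell per image:

* cell support: a star-convex perturbed ellipse (low-order random radial
  harmonics scaled by ``boundary_irregularity``; 0 gives an exact ellipse);
* 1–3 darker nucleus lobes inside the cell;
* cytoplasm color placed at RGB distance ``color_proximity`` from the
  background color (small distance = lymphocyte/monocyte-like difficulty);
* a smooth multiplicative brightness field and Gaussian blur.

The binary ground-truth mask is the exact pre-blur cell support, so labels
stay unambiguous at blurred boundaries.  Everything is a pure function of
the configured seed.

Augmentation follows the usual families for this task — rotation, flips,
scaling, brightness and contrast — with geometric ops applied identically
to image and mask (nearest-neighbour for the mask) and photometric ops to
the image only.  ``expand_dataset`` grows a source set to a target size by
seeded round-robin augmentation; ``split_dataset`` partitions 8:1:1 (or
any positive ratios) after a seeded shuffle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import read_image, read_mask, write_image, write_mask

# stain-like palette anchors (normalized RGB)
_BG_BASE = np.array([0.82, 0.76, 0.84])
_CYT_DIR = np.array([-0.35, -0.75, 0.12])   # cytoplasm shift off background
_NUC_DARK = np.array([0.30, 0.15, 0.45])    # dark purple nucleus anchor


@dataclass
class SceneConfig:
    """Parameters of the synthetic cell-image generator.

    ``cell_radius_range`` is in fractions of the image side;
    ``color_proximity`` is the RGB distance between cytoplasm and
    background (smaller = harder); ``brightness_jitter`` is the range of
    the multiplicative brightness field; ``blur_sigma`` is in pixels.
    """

    side: int = 256
    cell_radius_range: tuple = (0.15, 0.35)
    boundary_irregularity: float = 0.15
    color_proximity: float = 0.25
    nucleus_contrast: float = 0.5
    brightness_jitter: tuple = (0.85, 1.15)
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cell_radius_range
        if not 0.0 < lo < hi < 0.5:
            raise ValueError(f"degenerate cell_radius_range {self.cell_radius_range}")
        if not 0.0 <= self.boundary_irregularity <= 1.0:
            raise ValueError("boundary_irregularity must be in [0,1]")
        if not 0.0 <= self.color_proximity <= 1.0:
            raise ValueError("color_proximity must be in [0,1]")
        blo, bhi = self.brightness_jitter
        if not 0.0 < blo <= bhi:
            raise ValueError("brightness_jitter range must be positive")
        if self.side < 16:
            raise ValueError("side must be at least 16 pixels")


def _star_mask(side, center, axes, angle, mu_grid):
    """Pixels whose polar radius (in the cell frame) is inside the
    harmonic-modulated ellipse boundary."""
    cy, cx = center
    a, b = axes
    yy, xx = np.mgrid[0:side, 0:side]
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    theta = np.arctan2(v, u)
    rho = np.hypot(u, v)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if mu_grid is None:
        return rho <= r_ell
    grid_theta = np.linspace(-np.pi, np.pi, mu_grid.size, endpoint=False)
    mu = np.interp(theta, grid_theta, mu_grid, period=2 * np.pi)
    return rho <= r_ell * mu


def _radial_modulation(rng, irregularity: float, n_grid: int = 720):
    """Zero-mean low-order harmonic perturbation, normalized so the
    modulated boundary encloses (to first order) the ellipse's area."""
    theta = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    s = np.zeros(n_grid)
    for m in range(2, 6):
        amp = rng.normal(0.0, 1.0 / m, size=2)
        s += amp[0] * np.cos(m * theta) + amp[1] * np.sin(m * theta)
    s -= s.mean()
    peak = np.abs(s).max()
    if peak > 0:
        s /= peak
    mu = 1.0 + irregularity * s
    mu /= np.sqrt(np.mean(mu ** 2))   # keep enclosed area ≈ ellipse area
    return mu


def _smooth_noise(rng, side, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma)
    span = f.max() - f.min()
    return (f - f.min()) / span if span > 0 else np.zeros_like(f)


def generate_cell_image(config: SceneConfig, return_scene: bool = False):
    """Render one synthetic cell image and its binary mask.

    Returns ``(image, mask)`` — image H×W×3 float32 in [0,1], mask H×W
    uint8 — or ``(image, mask, scene)`` with the generating geometry when
    ``return_scene`` is true.  Same config (same seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    side = config.side
    lo, hi = config.cell_radius_range

    center = side * (0.5 + rng.uniform(-0.08, 0.08, size=2))   # (cy, cx)
    axes = side * rng.uniform(lo, hi, size=2)                  # (a, b)
    angle = rng.uniform(0.0, np.pi)
    mu = (_radial_modulation(rng, config.boundary_irregularity)
          if config.boundary_irregularity > 0 else None)
    cell = _star_mask(side, center, axes, angle, mu)

    # nucleus: 1–3 darker elliptical lobes inside the cell
    n_lobes = int(rng.integers(1, 4))
    r_min = min(axes)
    nucleus = np.zeros((side, side), dtype=bool)
    for _ in range(n_lobes):
        psi = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.0, 0.45) * r_min
        lobe_c = (center[0] + dist * math.sin(psi), center[1] + dist * math.cos(psi))
        lobe_axes = r_min * rng.uniform(0.22, 0.45, size=2)
        lobe_angle = rng.uniform(0.0, np.pi)
        nucleus |= _star_mask(side, lobe_c, lobe_axes, lobe_angle, None)
    nucleus &= cell

    # colors: cytoplasm at RGB distance color_proximity from the background
    bg = _BG_BASE + rng.uniform(-0.04, 0.04, size=3)
    direction = _CYT_DIR + rng.normal(0.0, 0.12, size=3)
    direction /= np.linalg.norm(direction)
    cyt = bg + config.color_proximity * direction
    nuc = (1.0 - config.nucleus_contrast) * cyt \
        + config.nucleus_contrast * _NUC_DARK

    img = np.empty((side, side, 3))
    img[:] = bg
    bg_tex = 0.05 * (_smooth_noise(rng, side, side / 16) - 0.5)
    cyt_tex = 0.06 * (_smooth_noise(rng, side, 2.0) - 0.5)
    img += bg_tex[..., None]
    img[cell] = cyt + cyt_tex[cell, None]
    img[nucleus] = nuc + 0.5 * cyt_tex[nucleus, None]

    blo, bhi = config.brightness_jitter
    brightness = blo + (bhi - blo) * _smooth_noise(rng, side, side / 4)
    img *= brightness[..., None]
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (config.blur_sigma,
                                            config.blur_sigma, 0))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    mask = cell.astype(np.uint8)
    if return_scene:
        scene = {"center": tuple(center), "axes": tuple(axes), "angle": angle,
                 "n_lobes": n_lobes, "background_color": bg,
                 "cytoplasm_color": cyt}
        return img, mask, scene
    return img, mask


def generate_dataset(config: SceneConfig, n: int):
    """n independent scenes with per-image seeds derived from config.seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2 ** 31)
    out = []
    for s in seeds:
        cfg = SceneConfig(**{**config.__dict__, "seed": int(s)})
        out.append(generate_cell_image(cfg))
    return out


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

_DEFAULT_OPS = (
    ("rotate", {"degrees": (-180.0, 180.0)}),
    ("hflip", {"p": 0.5}),
    ("vflip", {"p": 0.5}),
    ("scale", {"range": (0.8, 1.2)}),
    ("brightness", {"range": (0.8, 1.2)}),
    ("contrast", {"range": (0.8, 1.2)}),
)

_KNOWN_OPS = {"rotate", "hflip", "vflip", "scale", "brightness", "contrast"}


@dataclass
class AugmentationSpec:
    """Ordered augmentation pipeline: (name, params) pairs plus a seed.
    Geometric ops (rotate/flip/scale) transform image and mask together;
    photometric ops (brightness/contrast) leave the mask untouched."""

    ops: tuple = _DEFAULT_OPS
    seed: int = 0

    def __post_init__(self):
        self.ops = tuple((name, dict(params)) for name, params in self.ops)
        for name, _ in self.ops:
            if name not in _KNOWN_OPS:
                raise ValueError(f"unknown augmentation op {name!r}; "
                                 f"known: {sorted(_KNOWN_OPS)}")


def _affine_pair(image, mask, matrix, offset):
    img_out = np.stack([ndimage.affine_transform(image[..., c], matrix, offset,
                                                 order=1, mode="nearest")
                        for c in range(image.shape[-1])], axis=-1)
    mask_out = ndimage.affine_transform(mask, matrix, offset, order=0,
                                        mode="constant", cval=0)
    return img_out, mask_out


def augment(image, mask, spec: AugmentationSpec):
    """Apply the spec's ops in order; pure function of inputs and seed."""
    image = np.asarray(image, dtype=np.float32).copy()
    mask = np.asarray(mask, dtype=np.uint8).copy()
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} differ")
    rng = np.random.default_rng(spec.seed)
    for name, params in spec.ops:
        if name == "rotate":
            lo, hi = params.get("degrees", (-180.0, 180.0))
            angle = float(rng.uniform(lo, hi))
            if math.isclose(angle % 90.0, 0.0, abs_tol=1e-9) or \
                    math.isclose(angle % 90.0, 90.0, abs_tol=1e-9):
                k = int(round(angle / 90.0)) % 4
                image = np.rot90(image, k, axes=(0, 1)).copy()
                mask = np.rot90(mask, k, axes=(0, 1)).copy()
            else:
                image = ndimage.rotate(image, angle, axes=(1, 0),
                                       reshape=False, order=1, mode="nearest")
                mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                                      order=0, mode="constant", cval=0)
        elif name == "hflip":
            if rng.random() < params.get("p", 0.5):
                image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
        elif name == "vflip":
            if rng.random() < params.get("p", 0.5):
                image, mask = image[::-1].copy(), mask[::-1].copy()
        elif name == "scale":
            lo, hi = params.get("range", (0.8, 1.2))
            s = float(rng.uniform(lo, hi))
            h, w = mask.shape
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            matrix = np.array([[1.0 / s, 0.0], [0.0, 1.0 / s]])
            offset = np.array([cy - cy / s, cx - cx / s])
            image, mask = _affine_pair(image, mask, matrix, offset)
        elif name == "brightness":
            lo, hi = params.get("range", (0.8, 1.2))
            image = np.clip(image * rng.uniform(lo, hi), 0.0, 1.0)
        elif name == "contrast":
            lo, hi = params.get("range", (0.8, 1.2))
            f = rng.uniform(lo, hi)
            m = image.mean()
            image = np.clip((image - m) * f + m, 0.0, 1.0)
    return image.astype(np.float32), mask.astype(np.uint8)


# ---------------------------------------------------------------------
# dataset expansion and splitting
# ---------------------------------------------------------------------

def expand_dataset(pairs, target_n: int, spec: AugmentationSpec | None = None):
    """Grow ``pairs`` to ``target_n`` items by seeded round-robin
    augmentation.  Originals come first; each extra item cycles through the
    sources, so every source is used ceil or floor of target_n / n times.
    Items are dicts with image, mask and provenance."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("expand_dataset needs at least one source pair")
    n = len(pairs)
    if target_n < n:
        raise ValueError(f"target_n={target_n} below the {n} source pairs")
    spec = spec or AugmentationSpec()
    items = [{"image": img, "mask": msk, "source_index": i,
              "ops": (), "augment_seed": None}
             for i, (img, msk) in enumerate(pairs)]
    n_extra = target_n - n
    if n_extra:
        seeds = np.random.SeedSequence(spec.seed).generate_state(n_extra) % (2 ** 31)
        for j in range(n_extra):
            src = j % n
            item_spec = AugmentationSpec(ops=spec.ops, seed=int(seeds[j]))
            img, msk = augment(pairs[src][0], pairs[src][1], item_spec)
            items.append({"image": img, "mask": msk, "source_index": src,
                          "ops": tuple(name for name, _ in item_spec.ops),
                          "augment_seed": int(seeds[j])})
    return items


def split_dataset(items, ratios=(8, 1, 1), seed: int = 0):
    """Seeded shuffle, then contiguous partition with floor-then-distribute
    rounding (remainders go to the largest fractional parts, ties broken by
    partition order).  Partitions are disjoint and exhaustive."""
    items = list(items)
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(items) < len(ratios):
        raise ValueError(f"{len(items)} items cannot fill {len(ratios)} partitions")
    n = len(items)
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    sizes = [int(math.floor(e)) for e in exact]
    rem = n - sum(sizes)
    frac_order = sorted(range(len(ratios)),
                        key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in frac_order[:rem]:
        sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append([items[i] for i in perm[start:start + s]])
        start += s
    return tuple(out)


# ---------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------

def save_dataset(root, items, splits=None, extras=None) -> None:
    """Write items as images/*.png + masks/*.png with a JSON manifest
    (provenance, optional split assignment, any extra metadata)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    manifest = {"n_items": len(items), "items": [], "splits": splits,
                "extras": extras or {}}
    for i, item in enumerate(items):
        name = f"{i:05d}.png"
        write_image(root / "images" / name, item["image"])
        write_mask(root / "masks" / name, item["mask"])
        manifest["items"].append({
            "file": name,
            "source_index": item.get("source_index", i),
            "ops": list(item.get("ops", ())),
            "augment_seed": item.get("augment_seed"),
        })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(root):
    """Read a saved dataset back as a list of item dicts."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    items = []
    for entry in manifest["items"]:
        items.append({
            "image": read_image(root / "images" / entry["file"]),
            "mask": read_mask(root / "masks" / entry["file"]),
            "source_index": entry["source_index"],
            "ops": tuple(entry["ops"]),
            "augment_seed": entry["augment_seed"],
        })
    return items, manifest
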