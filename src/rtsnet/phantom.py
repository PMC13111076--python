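"""Synthetic ultrasound phantoms with known nodule masks.

Real thyroid B-mode images show bright parenchyma, darker (hypoechoic)
roughly elliptical nodules, strong multiplicative speckle, and occasional
posterior acoustic shadowing below an attenuating nodule.  The generator
emulates exactly these features — nothing physical (no beamforming, no
depth-dependent attenuation) — so that every downstream stage of the
pipeline can be exercised against pixel-accurate ground truth without any
external data.

The noise model is multiplicative gamma speckle with unit mean and shape
``speckle_shape`` (relative std ``1/sqrt(shape)``), the standard
fully-developed-speckle approximation.  Nodules are filled rotated
ellipses whose pre-noise intensity sits ``nodule_contrast`` below the
surrounding parenchyma.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError

BACKGROUND_LEVEL = 0.55     # mean parenchyma intensity before speckle
TEXTURE_STD = 0.03          # std of the smooth background texture field
SHADOW_SCALE = 0.5          # intensity multiplier inside a posterior shadow


@dataclass(frozen=True)
class Nodule:
    """One drawn lesion: centre (row, col), semi-axes, rotation angle."""
    cy: float
    cx: float
    a: float        # semi-axis along the rotated x' direction (pixels)
    b: float        # semi-axis along the rotated y' direction (pixels)
    theta: float    # rotation, radians
    shadow: bool


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 96
    n_nodules_range: tuple[int, int] = (1, 2)
    radius_range_px: tuple[int, int] = (8, 20)
    nodule_contrast: float = 0.35
    speckle_shape: float = 10.0
    shadow_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ConfigurationError("image_size must be >= 8")
        lo, hi = self.n_nodules_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("n_nodules_range must be a non-negative "
                                     "inclusive interval")
        rlo, rhi = self.radius_range_px
        if not (2 <= rlo <= rhi):
            raise ConfigurationError("radius_range_px lower bound must be >= 2 "
                                     "and the interval non-empty")
        if rhi >= self.image_size / 2:
            raise ConfigurationError("radius_range_px upper bound must be "
                                     "< image_size/2")
        if not (0.0 < self.nodule_contrast <= 1.0):
            raise ConfigurationError("nodule_contrast must lie in (0, 1]")
        if self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be positive")
        if not (0.0 <= self.shadow_prob <= 1.0):
            raise ConfigurationError("shadow_prob must lie in [0, 1]")


@dataclass
class PhantomSample:
    """One generated image with its ground truth.

    ``clean`` is the pre-speckle intensity layer; the contrast contract
    (nodule interior darker than surround by at least half the configured
    contrast) is stated on this layer, where it is exact.
    """
    image: np.ndarray                 # (S, S) float32 in [0, 1]
    mask: np.ndarray                  # (S, S) uint8 in {0, 1}
    clean: np.ndarray                 # (S, S) float32, noise-free layer
    nodules: list[Nodule] = field(default_factory=list)

    @property
    def n_nodules(self) -> int:
        return len(self.nodules)


def ellipse_interior(size: int, nod: Nodule) -> np.ndarray:
    """Boolean membership grid of a rotated filled ellipse (0-based,
    row-major, origin top-left)."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - nod.cy
    dx = xx - nod.cx
    c, s = np.cos(nod.theta), np.sin(nod.theta)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    return (xr / nod.a) ** 2 + (yr / nod.b) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Draw one phantom. Identical ``config`` (including its ``seed``)
    yields bit-identical output."""
    rng = np.random.default_rng(config.seed)
    S = config.image_size

    # smooth background texture: coarse gaussian field, bilinearly upsampled
    coarse = rng.normal(0.0, TEXTURE_STD, size=(8, 8))
    texture = ndimage.zoom(coarse, S / 8.0, order=1, grid_mode=True,
                           mode="nearest")
    clean = BACKGROUND_LEVEL + texture

    n = int(rng.integers(config.n_nodules_range[0],
                         config.n_nodules_range[1] + 1))
    rlo, rhi = config.radius_range_px
    mask = np.zeros((S, S), dtype=bool)
    nodules: list[Nodule] = []
    for _ in range(n):
        r = int(rng.integers(rlo, rhi + 1))
        a = r * rng.uniform(0.8, 1.2)
        b = r * rng.uniform(0.8, 1.2)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b)
        cy = rng.uniform(margin, S - 1 - margin)
        cx = rng.uniform(margin, S - 1 - margin)
        shadow = bool(rng.random() < config.shadow_prob)
        nod = Nodule(cy, cx, a, b, theta, shadow)
        nodules.append(nod)
        inside = ellipse_interior(S, nod)
        clean[inside] = BACKGROUND_LEVEL - config.nodule_contrast + texture[inside]
        mask |= inside

    # posterior acoustic shadow: darkened wedge below the nodule, narrowing
    # with depth; the mask is untouched (a shadow is not a nodule)
    for nod in nodules:
        if not nod.shadow:
            continue
        half_w = max(abs(nod.a * np.cos(nod.theta)),
                     abs(nod.b * np.sin(nod.theta)), 2.0)
        y0 = int(np.ceil(nod.cy + max(nod.a, nod.b)))
        if y0 >= S:
            continue
        yy, xx = np.mgrid[0:S, 0:S]
        depth = (yy - y0) / max(S - y0, 1)
        wedge = (yy >= y0) & (np.abs(xx - nod.cx) <= half_w * (1.0 - 0.3 * depth))
        clean[wedge] *= SHADOW_SCALE

    clean = np.clip(clean, 0.0, 1.0)
    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape,
                        size=(S, S))
    image = np.clip(clean * speckle, 0.0, 1.0)
    return PhantomSample(image=image.astype(np.float32),
                         mask=mask.astype(np.uint8),
                         clean=clean.astype(np.float32),
                         nodules=nodules)


def _to_png(arr01: np.ndarray, path: Path) -> None:
    # round-half-even to 8 bit
    Image.fromarray(np.round(arr01 * 255.0).astype(np.uint8), mode="L").save(path)


def write_dataset(config: PhantomConfig, n: int, out_dir: str | Path) -> list[dict]:
    """Write ``n`` phantom image/mask PNG pairs plus a CSV manifest.

    Sample ``i`` is drawn with seed ``config.seed + i`` so the set is
    reproducible and every sample is independent.  Layout::

        out_dir/images/<stem>.png   8-bit grayscale
        out_dir/masks/<stem>.png    {0, 255}
        out_dir/manifest.csv        stem, n_nodules, seed
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i in range(n):
        cfg_i = dataclasses.replace(config, seed=config.seed + i)
        sample = generate_phantom(cfg_i)
        stem = f"phantom_{i:04d}"
        _to_png(sample.image, out / "images" / f"{stem}.png")
        _to_png(sample.mask.astype(np.float64), out / "masks" / f"{stem}.png")
        manifest.append({"stem": stem, "n_nodules": sample.n_nodules,
                         "seed": cfg_i.seed})
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["stem", "n_nodules", "seed"])
        w.writeheader()
        w.writerows(manifest)
    return manifest
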