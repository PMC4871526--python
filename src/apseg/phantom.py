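"""Synthetic colonoscopy-like phantoms and mask corpora.

Real optical-colonoscopy frames show a roughly convex polyp that is
brighter or darker than a noisy, unevenly lit mucosal background, and
polyp boundaries are often locally weak (low contrast over part of the
rim).  The generator reproduces exactly those ingredients and nothing
more:

* a rasterized disk / ellipse / perturbed blob as the object, returned as
  the exact ground-truth mask;
* a smooth random background texture whose amplitude tracks the noise
  level, plus additive i.i.d. Gaussian pixel noise;
* a radial vignette (brightness falloff toward the border) mimicking
  endoscope illumination;
* an optional *weak-boundary gap*: over a contiguous angular sector
  covering ``gap_fraction`` of the rim, the object's contrast fades
  linearly to zero at the boundary, so no intensity edge exists there.

Everything is deterministic given ``rng_seed``.  A companion generator
produces corpora of binary object masks for shape-prior training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .errors import InvalidInputError, InvalidSpecError
from .image_graph import IntensityGrid

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_mask_corpus",
    "generate_phantom_set",
]

_SHAPES = ("disk", "ellipse", "perturbed-blob")

# default frame clearance: masks must stay strictly inside the region the
# default viewfinder (margin 0.05, thickness 1) reserves for the object
_DEFAULT_MARGIN = 0.05
_DEFAULT_THICKNESS = 1

# in the gap sector the object's contrast fades linearly with distance to
# the boundary starting from its innermost point, so the radial intensity
# gradient stays below the pixel-noise scale: no detectable edge remains
_GAP_RAMP_START = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    radii are (row semi-axis, col semi-axis) in pixels; ``contrast`` may be
    negative for depressed (darker-than-background) polyps.  ``center``
    defaults to the image centre.
    """

    rows: int = 96
    cols: int = 96
    polyp_shape: str = "disk"
    center: tuple[int, int] | None = None
    radii: tuple[float, float] = (14.0, 14.0)
    rotation: float = 0.0
    contrast: float = 0.35
    noise_sigma: float = 0.02
    vignette_strength: float = 0.1
    gap_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.polyp_shape not in _SHAPES:
            raise InvalidSpecError(f"unknown polyp_shape {self.polyp_shape!r}")
        if self.noise_sigma < 0 or self.vignette_strength < 0:
            raise InvalidSpecError("noise_sigma and vignette_strength must be >= 0")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise InvalidSpecError("gap_fraction must be in [0, 1)")
        if min(self.radii) <= 0:
            raise InvalidSpecError("radii must be positive")


def _rasterize(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.rows, spec.cols
    cr, cc = spec.center if spec.center is not None else (rows // 2, cols // 2)
    mask = np.zeros((rows, cols), dtype=np.uint8)
    if spec.polyp_shape == "disk":
        rr, cx = draw_disk((cr, cc), spec.radii[0], shape=(rows, cols))
    elif spec.polyp_shape == "ellipse":
        rr, cx = draw_ellipse(
            cr, cc, spec.radii[0], spec.radii[1], shape=(rows, cols), rotation=spec.rotation
        )
    else:  # perturbed-blob: radius modulated by low-order harmonics
        theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
        r = np.full_like(theta, spec.radii[0])
        for k in (2, 3, 5):
            r = r * (1.0 + 0.08 * rng.uniform(-1, 1) * np.cos(k * theta + rng.uniform(0, 2 * np.pi)))
        pr = cr + r * np.sin(theta)
        pc = cc + r * (spec.radii[1] / spec.radii[0]) * np.cos(theta)
        rr, cx = draw_polygon(pr, pc, shape=(rows, cols))
    mask[rr, cx] = 1
    if mask.sum() == 0:
        raise InvalidSpecError("phantom mask is empty")
    # the object must stay strictly inside the default viewfinder interior
    off_r = int(np.floor(_DEFAULT_MARGIN * rows)) + _DEFAULT_THICKNESS
    off_c = int(np.floor(_DEFAULT_MARGIN * cols)) + _DEFAULT_THICKNESS
    rr_all, cc_all = np.nonzero(mask)
    if (
        rr_all.min() <= off_r
        or rr_all.max() >= rows - 1 - off_r
        or cc_all.min() <= off_c
        or cc_all.max() >= cols - 1 - off_c
    ):
        raise InvalidSpecError(
            "phantom shape exceeds the image region inside the seed frame"
        )
    return mask


def _gap_multiplier(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Contrast multiplier implementing the weak-boundary angular gap."""
    mult = np.ones(mask.shape, dtype=np.float64)
    if spec.gap_fraction <= 0:
        return mult
    rr, cc = np.nonzero(mask)
    cr, cc0 = rr.mean(), cc.mean()
    theta = np.arctan2(rr - cr, cc - cc0)
    start = rng.uniform(-np.pi, np.pi)
    width = 2.0 * np.pi * spec.gap_fraction
    in_gap = np.mod(theta - start, 2.0 * np.pi) < width
    # normalized depth: 0 at the mask boundary, 1 at the innermost point
    d_in = distance_transform_edt(mask)
    depth = d_in[rr, cc] / d_in.max()
    u = 1.0 - depth  # 0 at centre, 1 at boundary
    ramp = np.clip((1.0 - u) / (1.0 - _GAP_RAMP_START), 0.0, 1.0)
    vals = np.where(in_gap, ramp, 1.0)
    mult[rr, cc] = vals
    return mult


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityGrid, np.ndarray]:
    """Rasterize one phantom; returns (intensity grid, ground-truth mask).

    The image is background texture + contrast * mask (faded across the
    optional gap sector), multiplied by the vignette, plus Gaussian noise,
    clipped to [0, 1].  Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mask = _rasterize(spec, rng)
    rows, cols = spec.rows, spec.cols

    base = np.full((rows, cols), 0.45)
    texture_amp = 2.0 * spec.noise_sigma
    if texture_amp > 0:
        raw = rng.standard_normal((rows, cols))
        smooth = gaussian_filter(raw, sigma=max(rows, cols) / 12.0)
        std = smooth.std()
        if std > 0:
            base = base + texture_amp * smooth / std

    contrast_map = spec.contrast * mask * _gap_multiplier(mask, spec, rng)
    img = base + contrast_map

    if spec.vignette_strength > 0:
        r = np.arange(rows)[:, None] - (rows - 1) / 2.0
        c = np.arange(cols)[None, :] - (cols - 1) / 2.0
        d2 = (r / rows * 2.0) ** 2 + (c / cols * 2.0) ** 2
        img = img * (1.0 - spec.vignette_strength * d2 / 2.0)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(rows, cols))

    return IntensityGrid(np.clip(img, 0.0, 1.0)), mask


def generate_mask_corpus(
    n: int,
    rng_seed: int = 0,
    rows: int = 96,
    cols: int = 96,
    radius_range: tuple[float, float] = (10.0, 16.0),
    eccentricity_range: tuple[float, float] = (0.9, 1.1),
    center_jitter: int = 8,
    shape_family: tuple[str, ...] = ("disk", "ellipse"),
) -> list[np.ndarray]:
    """Random binary object masks for shape-prior training.

    Radii are drawn uniformly from ``radius_range``; ellipses get a second
    semi-axis scaled by a factor from ``eccentricity_range`` and a random
    rotation; centres are jittered uniformly within ``center_jitter``
    pixels of the image centre.  Reproducible by ``rng_seed``.
    """
    if n < 1:
        raise InvalidInputError(f"corpus size must be >= 1, got {n}")
    rng = np.random.default_rng(rng_seed)
    masks = []
    for _ in range(n):
        shape = shape_family[rng.integers(len(shape_family))]
        r0 = rng.uniform(*radius_range)
        r1 = r0 * rng.uniform(*eccentricity_range) if shape == "ellipse" else r0
        jr = int(rng.integers(-center_jitter, center_jitter + 1)) if center_jitter else 0
        jc = int(rng.integers(-center_jitter, center_jitter + 1)) if center_jitter else 0
        spec = PhantomSpec(
            rows=rows,
            cols=cols,
            polyp_shape=shape,
            center=(rows // 2 + jr, cols // 2 + jc),
            radii=(r0, r1),
            rotation=rng.uniform(0.0, np.pi),
            noise_sigma=0.0,
            vignette_strength=0.0,
            rng_seed=int(rng.integers(2**31)),
        )
        masks.append(_rasterize(spec, np.random.default_rng(spec.rng_seed)))
    return masks


def generate_phantom_set(
    n: int,
    rng_seed: int = 0,
    gap_fraction: float = 0.0,
    rows: int = 128,
    cols: int = 128,
    noise_sigma: float = 0.02,
) -> list[tuple[PhantomSpec, IntensityGrid, np.ndarray]]:
    """Standard evaluation population: centred mid-size polyps.

    Objects are disks/ellipses with semi-axes drawn from the mid range
    (13-16 px) of the training corpus distribution and mild eccentricity
    (0.95-1.05), centred in a field of view several object diameters wide.
    This emulates the automatic-mode acquisition geometry in which the
    polyp is captured at a fixed position inside the viewfinder, and keeps
    the high-confidence (gamma = 0.8) attraction region a conservative
    core of every object — the regime the attraction mechanism assumes.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        r0 = rng.uniform(13.0, 16.0)
        spec = PhantomSpec(
            rows=rows,
            cols=cols,
            polyp_shape="disk" if rng.uniform() < 0.5 else "ellipse",
            center=(rows // 2, cols // 2),
            radii=(r0, r0 * rng.uniform(0.95, 1.05)),
            rotation=float(rng.uniform(0.0, np.pi)),
            noise_sigma=noise_sigma,
            gap_fraction=gap_fraction,
            rng_seed=int(rng.integers(2**31)),
        )
        grid, mask = generate_phantom(spec)
        out.append((spec, grid, mask))
    return out
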