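"""Placing the shape prior at a seed: the attraction field.

Given a trained, thresholded shape prior and a single foreground seed, the
attraction field consists of

* the **attraction region** — the nonzero support of the threshold matrix
  translated so the prior's canvas centre coincides with the seed (cells
  falling outside the image are clipped);
* the **shifted threshold matrix** — the translated SP values themselves,
  which become per-pixel target probabilities;
* **range bases** tau^f (the shifted values) and tau^b = 1 - tau^f on the
  region, zero elsewhere — the probabilities the attraction term pulls the
  foreground/background solutions toward;
* **attraction factors** a_i = exp(-|g_i - g_s|), an intensity-similarity
  weight between each region pixel and the seed pixel, so pixels that look
  like the seed are attracted more strongly.

The diagonal matrix A = diag(a_i restricted to the region) enters the
seeded linear systems of :mod:`apseg.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sparse

from .errors import EmptyPriorError, InvalidLabelError, InvalidSeedError
from .image_graph import IntensityGrid
from .seeding import BACKGROUND, FOREGROUND
from .shape_prior import ShapePrior

__all__ = [
    "AttractionField",
    "place_prior",
    "attraction_factors",
    "range_base",
    "attraction_matrix",
]


@dataclass(frozen=True)
class AttractionField:
    """Shape prior placed at a foreground seed on a concrete image.

    ``region`` and ``shifted_t`` are image-shaped; ``factors`` is filled by
    :func:`attraction_factors` and is zero outside the region.
    """

    region: np.ndarray  # bool, image shape
    shifted_t: np.ndarray  # float64, image shape, zero outside region
    seed: tuple[int, int]
    seed_intensity: float
    factors: np.ndarray | None = None  # float64, image shape, zero outside region


def place_prior(prior: ShapePrior, seed: tuple[int, int], grid: IntensityGrid) -> AttractionField:
    """Translate the threshold matrix so the canvas centre lands on the seed.

    The attraction region is the nonzero support of the shifted matrix,
    clipped to the image bounds.
    """
    if prior.threshold_matrix is None:
        raise EmptyPriorError("prior has no threshold matrix; run threshold_prior first")
    t = prior.threshold_matrix
    if not np.any(t):
        raise EmptyPriorError("thresholded prior has empty support")
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < grid.rows and 0 <= sc < grid.cols):
        raise InvalidSeedError(
            f"seed ({sr}, {sc}) outside a {grid.rows}x{grid.cols} image"
        )

    cr, cc = prior.canvas_center
    dr, dc = sr - cr, sc - cc  # canvas (m, n) -> image (m + dr, n + dc)

    # overlap of the shifted canvas with the image, in both index frames
    img_r0, img_r1 = max(0, dr), min(grid.rows, prior.canvas_rows + dr)
    img_c0, img_c1 = max(0, dc), min(grid.cols, prior.canvas_cols + dc)
    shifted = np.zeros((grid.rows, grid.cols), dtype=np.float64)
    if img_r1 > img_r0 and img_c1 > img_c0:
        shifted[img_r0:img_r1, img_c0:img_c1] = t[
            img_r0 - dr : img_r1 - dr, img_c0 - dc : img_c1 - dc
        ]
    region = shifted > 0.0
    return AttractionField(
        region=region,
        shifted_t=shifted,
        seed=(sr, sc),
        seed_intensity=float(grid.values[sr, sc]),
    )


def attraction_factors(
    field: AttractionField, grid: IntensityGrid, sharpness: float = 1.0
) -> AttractionField:
    """Fill a_i = exp(-sharpness * |g_i - g_s|) on the attraction region.

    On unit-range intensities the plain factors live in [exp(-1), 1]; the
    optional ``sharpness`` multiplier steepens the intensity dependence
    without changing the default behaviour (sharpness = 1).
    """
    a = np.where(
        field.region,
        np.exp(-sharpness * np.abs(grid.values - field.seed_intensity)),
        0.0,
    )
    return replace(field, factors=a)


def range_base(field: AttractionField, label: str, floor: float = 0.0) -> np.ndarray:
    """Per-node target probabilities tau^label, flattened row-major.

    tau^f is the shifted threshold value, tau^b its complement, both zero
    outside the region.  A positive ``floor`` clamps in-region values from
    below (needed by the Pearson variant, whose system matrix divides by
    tau and would blow up where tau^b = 0).
    """
    if label == FOREGROUND:
        tau = np.where(field.region, field.shifted_t, 0.0)
    elif label == BACKGROUND:
        tau = np.where(field.region, 1.0 - field.shifted_t, 0.0)
    else:
        raise InvalidLabelError(f"unknown label {label!r}; expected 'f' or 'b'")
    if floor > 0.0:
        tau = np.where(field.region & (tau < floor), floor, tau)
    return tau.ravel()


def attraction_matrix(field: AttractionField) -> sparse.dia_matrix:
    """Diagonal n x n matrix with a_i on region nodes, zero elsewhere."""
    if field.factors is None:
        raise InvalidSeedError("attraction factors not computed; call attraction_factors")
    return sparse.diags(field.factors.ravel())
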