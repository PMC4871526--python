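"""Learning the shape probability matrix from binary ground-truth masks.

The shape prior captures where, relative to its centroid, an object class
(here: colorectal polyps) tends to put its mass.  Training is a four-step
frequency estimate:

1. collect a corpus of binary ground-truth masks (1 = object);
2. translate each mask so its centroid sits at the centre of a common
   canvas ("calibration");
3. per canvas cell, count the fraction of masks covering it — the shape
   probability matrix ``SP(m, n) = Fr(m, n) / Ns`` with values on the grid
   ``{0, 1/Ns, ..., 1}``;
4. threshold: ``T(m, n) = SP(m, n)`` where ``SP >= gamma`` else 0.  The
   nonzero support of ``T`` is the shape prior region used downstream to
   build an attraction field around a foreground seed.

Masks are plain ``uint8``/bool numpy arrays; helpers read/write them as
PNG with white objects on a black background.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    EmptyMaskError,
    InvalidInputError,
    InvalidParameterError,
    PriorFormatError,
)

__all__ = [
    "ShapePrior",
    "mask_centroid",
    "calibrate_masks",
    "shape_probability",
    "threshold_prior",
    "train_prior",
    "save_prior",
    "load_prior",
    "load_mask",
    "save_mask",
]

_FORMAT_VERSION = 1


def _as_binary(mask: np.ndarray, *, require_foreground: bool = False) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2 or m.size == 0:
        raise InvalidInputError(f"mask must be a non-empty 2-D array, got shape {m.shape}")
    u = np.unique(m)
    if not np.isin(u, (0, 1)).all():
        raise InvalidInputError("mask values must be strictly 0/1")
    m = m.astype(np.uint8)
    if require_foreground and m.sum() == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return m


@dataclass(frozen=True)
class ShapePrior:
    """Shape probability matrix with optional threshold matrix.

    ``sp`` holds per-cell coverage frequencies in [0, 1] on the grid
    ``k / n_samples``; ``threshold_matrix`` (once :func:`threshold_prior`
    has run) retains SP values at or above ``gamma`` and zeros elsewhere.
    """

    sp: np.ndarray
    n_samples: int
    gamma: float | None = None
    threshold_matrix: np.ndarray | None = None

    @property
    def canvas_rows(self) -> int:
        return self.sp.shape[0]

    @property
    def canvas_cols(self) -> int:
        return self.sp.shape[1]

    @property
    def canvas_center(self) -> tuple[int, int]:
        return (self.canvas_rows - 1) // 2, (self.canvas_cols - 1) // 2


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of a mask's foreground pixels."""
    m = _as_binary(mask, require_foreground=True)
    rr, cc = np.nonzero(m)
    return float(rr.mean()), float(cc.mean())


def _round_half_down(x: float) -> int:
    # 2.5 -> 2; used for centroid-to-integer shifts so masks stay binary
    return int(np.ceil(x - 0.5))


def calibrate_masks(
    masks: list[np.ndarray],
    canvas_rows: int | None = None,
    canvas_cols: int | None = None,
) -> list[np.ndarray]:
    """Translate each mask so its centroid lands at the canvas centre.

    The canvas defaults to the dimensions of the largest training mask;
    masks of differing sizes share that common canvas.  Shifts are whole
    pixels (centroids rounded half-down); any pixel pushed off the canvas
    is clipped with a warning.
    """
    if not masks:
        raise InvalidInputError("empty mask list")
    bins = [_as_binary(m, require_foreground=True) for m in masks]
    if canvas_rows is None:
        canvas_rows = max(m.shape[0] for m in bins)
    if canvas_cols is None:
        canvas_cols = max(m.shape[1] for m in bins)
    center = ((canvas_rows - 1) // 2, (canvas_cols - 1) // 2)

    out = []
    for k, m in enumerate(bins):
        cr, cc = mask_centroid(m)
        dr = center[0] - _round_half_down(cr)
        dc = center[1] - _round_half_down(cc)
        rr, cc_idx = np.nonzero(m)
        rr = rr + dr
        cc_idx = cc_idx + dc
        keep = (rr >= 0) & (rr < canvas_rows) & (cc_idx >= 0) & (cc_idx < canvas_cols)
        if not keep.all():
            warnings.warn(
                f"mask {k}: {int((~keep).sum())} shifted pixels fell outside the "
                f"{canvas_rows}x{canvas_cols} canvas and were clipped",
                stacklevel=2,
            )
        canvas = np.zeros((canvas_rows, canvas_cols), dtype=np.uint8)
        canvas[rr[keep], cc_idx[keep]] = 1
        out.append(canvas)
    return out


def shape_probability(calibrated_masks: list[np.ndarray]) -> ShapePrior:
    """Per-cell coverage frequency across centred masks (SP = Fr / Ns)."""
    if not calibrated_masks:
        raise InvalidInputError("empty mask list")
    bins = [_as_binary(m) for m in calibrated_masks]
    shape = bins[0].shape
    for k, m in enumerate(bins):
        if m.shape != shape:
            raise InvalidInputError(
                f"mask {k} has shape {m.shape}, expected {shape}; calibrate first"
            )
    stack = np.stack(bins).astype(np.float64)
    sp = stack.mean(axis=0)
    return ShapePrior(sp=sp, n_samples=len(bins))


def threshold_prior(prior: ShapePrior, gamma: float) -> ShapePrior:
    """Keep SP values at or above gamma (inclusive), zero the rest."""
    if not (0.0 <= gamma <= 1.0):
        raise InvalidParameterError(f"gamma must be in [0, 1], got {gamma}")
    t = np.where(prior.sp >= gamma, prior.sp, 0.0)
    return replace(prior, gamma=float(gamma), threshold_matrix=t)


def train_prior(
    masks: list[np.ndarray],
    gamma: float = 0.8,
    canvas_rows: int | None = None,
    canvas_cols: int | None = None,
) -> ShapePrior:
    """Calibrate, estimate and threshold in one call."""
    calibrated = calibrate_masks(masks, canvas_rows, canvas_cols)
    return threshold_prior(shape_probability(calibrated), gamma)


def save_prior(prior: ShapePrior, path) -> None:
    """Serialize a prior to an NPZ container with a version and checksum."""
    sp = np.ascontiguousarray(prior.sp, dtype=np.float64)
    payload = {
        "format_version": np.int64(_FORMAT_VERSION),
        "sp": sp,
        "n_samples": np.int64(prior.n_samples),
        "sp_sha256": np.bytes_(hashlib.sha256(sp.tobytes()).hexdigest().encode()),
        "has_threshold": np.bool_(prior.threshold_matrix is not None),
    }
    if prior.threshold_matrix is not None:
        payload["gamma"] = np.float64(prior.gamma)
        payload["threshold_matrix"] = np.ascontiguousarray(
            prior.threshold_matrix, dtype=np.float64
        )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_prior(path) -> ShapePrior:
    """Load a prior saved by :func:`save_prior`, verifying its integrity."""
    try:
        with open(path, "rb") as fh:
            data = np.load(io.BytesIO(fh.read()))
    except (OSError, ValueError) as exc:
        raise PriorFormatError(f"cannot read prior file {path}: {exc}") from exc
    required = {"format_version", "sp", "n_samples", "sp_sha256", "has_threshold"}
    if not required.issubset(data.files):
        raise PriorFormatError(f"prior file {path} is missing fields")
    if int(data["format_version"]) != _FORMAT_VERSION:
        raise PriorFormatError(
            f"unsupported prior format version {int(data['format_version'])}"
        )
    sp = np.asarray(data["sp"], dtype=np.float64)
    if sp.ndim != 2:
        raise PriorFormatError("prior sp matrix is not 2-D")
    digest = hashlib.sha256(np.ascontiguousarray(sp).tobytes()).hexdigest()
    stored = bytes(data["sp_sha256"]).decode()
    if digest != stored:
        raise PriorFormatError(f"prior file {path} failed its checksum")
    gamma = None
    t = None
    if bool(data["has_threshold"]):
        gamma = float(data["gamma"])
        t = np.asarray(data["threshold_matrix"], dtype=np.float64)
        if t.shape != sp.shape:
            raise PriorFormatError("threshold matrix shape does not match sp")
    return ShapePrior(sp=sp, n_samples=int(data["n_samples"]), gamma=gamma, threshold_matrix=t)


def load_mask(path) -> np.ndarray:
    """Read a binary mask PNG (white object on black background)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return (img > (img.max() / 2 if img.max() > 1 else 0)).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (white = object)."""
    import imageio.v3 as iio

    m = _as_binary(mask)
    iio.imwrite(path, (m * 255).astype(np.uint8))
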