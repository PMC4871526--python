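"""Seed sets and the viewfinder seed initialization.

Interactive graph segmentation needs labelled seed pixels.  The workflow
implemented here keeps user interaction minimal: background seeds form a
rectangular frame (a "viewfinder") just inside the image border, and a
single foreground seed sits inside the frame — by default at the image
centre, which makes segmentation fully automatic whenever the object of
interest (the polyp) is framed near the centre of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, InvalidSeedError

__all__ = ["SeedSet", "ViewfinderSpec", "viewfinder_seeds", "seed_map"]

FOREGROUND = "f"
BACKGROUND = "b"
LABELS = (FOREGROUND, BACKGROUND)


@dataclass(frozen=True)
class SeedSet:
    """Foreground/background seed nodes, as flat row-major pixel indices.

    The marked-node ordering used everywhere downstream is foreground seeds
    first, then background seeds.  ``indicator(label)`` returns the 0/1
    vector m^c over that ordering; the two indicators sum to one on every
    marked node.
    """

    foreground: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        fg = np.atleast_1d(np.asarray(self.foreground, dtype=np.int64))
        bg = np.atleast_1d(np.asarray(self.background, dtype=np.int64))
        if fg.size < 1 or bg.size < 1:
            raise InvalidSeedError("need at least one foreground and one background seed")
        if np.unique(fg).size != fg.size or np.unique(bg).size != bg.size:
            raise InvalidSeedError("duplicate seed indices within a label")
        if np.intersect1d(fg, bg).size > 0:
            raise InvalidSeedError("foreground and background seeds overlap")
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "background", bg)

    @property
    def marked(self) -> np.ndarray:
        return np.concatenate([self.foreground, self.background])

    @property
    def n_marked(self) -> int:
        return self.foreground.size + self.background.size

    def indicator(self, label: str) -> np.ndarray:
        """0/1 vector m^c over the marked ordering (fg block, then bg)."""
        if label == FOREGROUND:
            return np.concatenate(
                [np.ones(self.foreground.size), np.zeros(self.background.size)]
            )
        if label == BACKGROUND:
            return np.concatenate(
                [np.zeros(self.foreground.size), np.ones(self.background.size)]
            )
        raise InvalidSeedError(f"unknown label {label!r}")


@dataclass(frozen=True)
class ViewfinderSpec:
    """Geometry of the automatic frame-plus-centre seed placement.

    margin_fraction
        Distance of the frame from the image border, as a fraction of each
        dimension (strictly between 0 and 0.5).  The pixel offset used is
        ``floor(margin_fraction * dimension)``.
    frame_thickness
        Thickness of the background frame in pixels.
    fg_position
        ``"center"`` or an explicit ``(row, col)`` strictly inside the frame.
    """

    margin_fraction: float = 0.05
    frame_thickness: int = 1
    fg_position: object = "center"

    def __post_init__(self) -> None:
        if not (0.0 < self.margin_fraction < 0.5):
            raise InvalidGeometryError(
                f"margin_fraction must be in (0, 0.5), got {self.margin_fraction}"
            )
        if self.frame_thickness < 1:
            raise InvalidGeometryError(
                f"frame_thickness must be >= 1, got {self.frame_thickness}"
            )


def viewfinder_seeds(rows: int, cols: int, spec: ViewfinderSpec | None = None) -> SeedSet:
    """Generate frame background seeds plus one foreground seed.

    The background seeds are every pixel of a rectangular ring whose outer
    boundary is ``floor(margin * dim)`` pixels from each border and which is
    ``frame_thickness`` pixels thick.  The foreground seed defaults to the
    image centre ``(rows // 2, cols // 2)``.
    """
    if spec is None:
        spec = ViewfinderSpec()
    off_r = int(np.floor(spec.margin_fraction * rows))
    off_c = int(np.floor(spec.margin_fraction * cols))
    t = spec.frame_thickness
    top, bottom = off_r, rows - 1 - off_r
    left, right = off_c, cols - 1 - off_c
    # the frame interior must be nonempty after removing the ring itself
    if bottom - top < 2 * t + 2 or right - left < 2 * t + 2:
        raise InvalidGeometryError(
            f"viewfinder frame is degenerate for a {rows}x{cols} image "
            f"(margin={spec.margin_fraction}, thickness={t})"
        )

    in_frame = np.zeros((rows, cols), dtype=bool)
    in_frame[top : bottom + 1, left : right + 1] = True
    interior = np.zeros((rows, cols), dtype=bool)
    interior[top + t : bottom + 1 - t, left + t : right + 1 - t] = True
    ring = in_frame & ~interior
    background = np.flatnonzero(ring)

    if spec.fg_position == "center":
        fr, fc = rows // 2, cols // 2
    else:
        fr, fc = spec.fg_position
    if not interior[fr, fc]:
        raise InvalidGeometryError(
            f"foreground seed ({fr}, {fc}) is not strictly inside the frame"
        )
    foreground = np.array([fr * cols + fc], dtype=np.int64)
    return SeedSet(foreground=foreground, background=background)


def seed_map(seeds: SeedSet, rows: int, cols: int) -> np.ndarray:
    """Render seeds as a raster: 0 unknown, 1 foreground, 2 background."""
    out = np.zeros(rows * cols, dtype=np.uint8)
    out[seeds.foreground] = 1
    out[seeds.background] = 2
    return out.reshape(rows, cols)
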