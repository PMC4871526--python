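"""Image-to-graph conversion for seeded graph-based segmentation.

An image is modelled as an undirected weighted lattice graph: one node per
pixel, edges between neighbouring pixels (4- or 8-connectivity), and edge
weights that decay exponentially with the intensity difference,

    w_ij = exp(-beta * |g_i - g_j|) + epsilon_w,

where ``g`` are intensities normalized to [0, 1], ``beta`` controls contrast
sensitivity, and ``epsilon_w`` is a small positive floor that keeps the
lattice connected and the seeded linear systems positive definite.

The combinatorial Laplacian ``L`` of this graph carries weighted degrees on
the diagonal and ``-w_ij`` off the diagonal.  Partitioning the nodes into
marked (seeded) and unmarked sets yields the blocks ``L_U`` (unmarked rows
and columns) and ``B`` (marked rows, unmarked columns) that appear in every
seeded solve performed by :mod:`apseg.solver`.

Node indexing is 0-based row-major throughout: node ``i`` sits at pixel
``(i // cols, i % cols)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
from skimage.color import rgb2gray

from .errors import InvalidInputError, InvalidParameterError, InvalidSeedError
from .seeding import SeedSet

__all__ = [
    "IntensityGrid",
    "LatticeGraph",
    "GraphOperators",
    "to_intensity_grid",
    "build_lattice_graph",
    "graph_operators",
    "load_image",
    "export_grid",
]


@dataclass(frozen=True)
class IntensityGrid:
    """A 2-D image as normalized scalar intensities in [0, 1]."""

    values: np.ndarray  # float64, shape (rows, cols)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.size < 2:
            raise InvalidInputError(
                f"intensity grid must be 2-D with at least 2 pixels, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("intensity grid contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise InvalidInputError("intensity grid values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.values.size

    def node_index(self, row: int, col: int) -> int:
        """Flat row-major node index of pixel (row, col)."""
        return row * self.cols + col

    def node_coords(self, index: int) -> tuple[int, int]:
        """Pixel (row, col) of a flat node index."""
        return divmod(index, self.cols)


@dataclass(frozen=True)
class LatticeGraph:
    """Weighted pixel-lattice graph.

    ``edges`` holds each unordered neighbour pair exactly once as ``(i, j)``
    with ``i < j``; ``weights`` aligns with it.
    """

    shape: tuple[int, int]
    edges: np.ndarray  # (n_edges, 2) int64, i < j
    weights: np.ndarray  # (n_edges,) float64, > 0
    beta: float
    epsilon_w: float
    connectivity: int

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass(frozen=True)
class GraphOperators:
    """Laplacian of a lattice graph with its seed-partitioned blocks.

    ``marked`` lists seeded nodes (foreground seeds first, then background),
    ``unmarked`` the remaining nodes in ascending order.  ``lap_unmarked``
    is the unmarked diagonal block L_U and ``boundary`` the marked-unmarked
    off-diagonal block B (marked rows, unmarked columns), so the seeded
    right-hand sides are ``-B.T @ m``.
    """

    laplacian: sparse.csr_matrix  # full n x n Laplacian
    marked: np.ndarray  # int64 node indices, fg first then bg
    unmarked: np.ndarray  # int64 node indices, ascending
    lap_unmarked: sparse.csr_matrix  # L_U, |V_U| x |V_U|
    boundary: sparse.csr_matrix  # B, |V_M| x |V_U|

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]

    @property
    def n_unmarked(self) -> int:
        return self.unmarked.size

    def scatter(self, marked_values: np.ndarray, unmarked_values: np.ndarray) -> np.ndarray:
        """Reassemble a full per-node vector from marked/unmarked pieces."""
        full = np.empty(self.n_nodes, dtype=np.float64)
        full[self.marked] = marked_values
        full[self.unmarked] = unmarked_values
        return full

    def gather(self, full: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a full per-node vector into (marked, unmarked) pieces."""
        full = np.asarray(full)
        return full[self.marked], full[self.unmarked]


def to_intensity_grid(raster: np.ndarray) -> IntensityGrid:
    """Convert a 2-D or 3-channel raster to a normalized intensity grid.

    3-channel input is collapsed to luminance (Rec. 709 weights); the result
    is linearly rescaled so the minimum maps to 0 and the maximum to 1.  A
    constant image maps to all zeros.
    """
    arr = np.asarray(raster)
    if arr.size == 0:
        raise InvalidInputError("empty raster")
    if arr.ndim == 3 and arr.shape[2] == 3:
        arr = rgb2gray(arr)
    elif arr.ndim != 2:
        raise InvalidInputError(
            f"expected a 2-D or 3-channel raster, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64, copy=True)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("raster contains non-finite pixel values")
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return IntensityGrid(arr)


def load_image(path) -> IntensityGrid:
    """Read an image file (PNG/TIFF/...) and normalize it to a grid."""
    import imageio.v3 as iio

    return to_intensity_grid(iio.imread(path))


def export_grid(grid: IntensityGrid, path) -> None:
    """Write a grid as a plain-text matrix (one row per line) for debugging."""
    np.savetxt(path, grid.values, fmt="%.8f")


_OFFSETS_4 = ((0, 1), (1, 0))
_OFFSETS_8 = ((0, 1), (1, 0), (1, 1), (1, -1))


def build_lattice_graph(
    grid: IntensityGrid,
    beta: float = 310.0,
    connectivity: int = 4,
    epsilon_w: float = 1e-6,
) -> LatticeGraph:
    """Build the weighted lattice graph of an intensity grid.

    Parameters
    ----------
    grid
        Normalized intensity grid.
    beta
        Contrast-sensitivity parameter of the Gaussian weight
        ``exp(-beta * |g_i - g_j|)``; must be >= 0.  Values in the low
        hundreds are typical for unit-range intensities.
    connectivity
        4 (edges to right/down neighbours) or 8 (adds both diagonals).
    epsilon_w
        Nonnegative weight floor added to every edge.
    """
    if beta < 0:
        raise InvalidParameterError(f"beta must be >= 0, got {beta}")
    if epsilon_w < 0:
        raise InvalidParameterError(f"epsilon_w must be >= 0, got {epsilon_w}")
    if connectivity not in (4, 8):
        raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")

    rows, cols = grid.rows, grid.cols
    idx = np.arange(rows * cols, dtype=np.int64).reshape(rows, cols)
    g = grid.values

    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    srcs, dsts, diffs = [], [], []
    for dr, dc in offsets:
        # slices selecting each (pixel, neighbour) pair once; all offsets
        # point to strictly larger flat indices, so i < j holds by design
        r0 = slice(0, rows - dr)
        r1 = slice(dr, rows)
        if dc >= 0:
            c0, c1 = slice(0, cols - dc), slice(dc, cols)
        else:
            c0, c1 = slice(-dc, cols), slice(0, cols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        srcs.append(a)
        dsts.append(b)
        diffs.append(np.abs(g[r0, c0].ravel() - g[r1, c1].ravel()))

    i = np.concatenate(srcs)
    j = np.concatenate(dsts)
    d = np.concatenate(diffs)
    weights = np.exp(-beta * d) + epsilon_w
    edges = np.stack([i, j], axis=1)
    return LatticeGraph(
        shape=(rows, cols),
        edges=edges,
        weights=weights,
        beta=float(beta),
        epsilon_w=float(epsilon_w),
        connectivity=connectivity,
    )


def graph_laplacian(graph: LatticeGraph) -> sparse.csr_matrix:
    """Assemble the sparse combinatorial Laplacian of a lattice graph."""
    n = graph.n_nodes
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.weights
    adj = sparse.coo_matrix((w, (i, j)), shape=(n, n))
    adj = adj + adj.T
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - adj
    return lap.tocsr()


def graph_operators(graph: LatticeGraph, seeds: SeedSet) -> GraphOperators:
    """Build the Laplacian and its marked/unmarked partition for a seed set.

    Foreground seeds come first in the marked ordering, background seeds
    second, matching the label-indicator vectors of :class:`SeedSet`.
    """
    n = graph.n_nodes
    marked = seeds.marked
    if marked.size == 0:
        raise InvalidSeedError("at least one seed is required")
    if marked.min() < 0 or marked.max() >= n:
        raise InvalidSeedError(
            f"seed index out of range for a graph with {n} nodes"
        )
    lap = graph_laplacian(graph)
    unmarked = np.setdiff1d(np.arange(n, dtype=np.int64), marked)
    lap_u = lap[unmarked][:, unmarked].tocsr()
    bnd = lap[marked][:, unmarked].tocsr()
    return GraphOperators(
        laplacian=lap,
        marked=marked,
        unmarked=unmarked,
        lap_unmarked=lap_u,
        boundary=bnd,
    )
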