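"""Assembling and solving the attraction-propagation linear systems.

For each label c in {f, b} the model minimizes, over the transition
probabilities x^c of the unseeded nodes,

    sum_{i in region} D(a_i, x_i^c, tau_i^c)
        + sum_{edges ij} w_ij (x_i^c - x_j^c)^2,

with seeded nodes fixed to their 0/1 indicators.  Three attraction
distances D are supported, each leading to a sparse symmetric positive
definite system over the unmarked block:

=========  =============================  ===============================
variant    system matrix                  right-hand side
=========  =============================  ===============================
pea        L_U + (1/2) A_U diag(1/tau)    -B^T m^c + diag(A_U)
inn        L_U                            -B^T m^c + A_U tau_U^c
l2         L_U + A_U                      -B^T m^c + A_U tau_U^c
rw         L_U                            -B^T m^c
=========  =============================  ===============================

where L_U and B are the seed-partitioned Laplacian blocks, A_U the
unmarked attraction diagonal and m^c the seed indicator.  With an empty
attraction region (A = 0) every variant collapses to the classical
random-walker system, so ``rw`` is exactly the zero-attraction limit.

The Pearson matrix depends on the label through 1/tau, so it is assembled
per label; ``inn`` and ``l2`` share one factorization across labels.  The
``l2`` and ``rw`` solutions satisfy x^f + x^b = 1 per node and lie in
[0, 1]; ``pea`` and ``inn`` probabilities may leave [0, 1] and are
reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .attraction import AttractionField, attraction_factors, place_prior, range_base
from .errors import InvalidLabelError, InvalidParameterError, InvalidSeedError, SolverError
from .image_graph import (
    GraphOperators,
    IntensityGrid,
    LatticeGraph,
    build_lattice_graph,
    graph_operators,
)
from .seeding import BACKGROUND, FOREGROUND, LABELS, SeedSet
from .shape_prior import ShapePrior, threshold_prior

__all__ = [
    "VARIANTS",
    "SystemBundle",
    "ProbabilityField",
    "SegmentationResult",
    "evaluate_objective",
    "assemble_system",
    "solve_probabilities",
    "assign_labels",
    "segment",
]

VARIANTS = ("pea", "inn", "l2", "rw")

_RESIDUAL_RTOL = 1e-8


@dataclass(frozen=True)
class SystemBundle:
    """Per-label system matrices and right-hand sides over the unmarked block."""

    variant: str
    matrices: dict  # label -> csc_matrix, |V_U| x |V_U|
    rhs: dict  # label -> ndarray, |V_U|
    ops: GraphOperators
    seeds: SeedSet


@dataclass(frozen=True)
class ProbabilityField:
    """Per-node, per-label transition probabilities in image (row-major) order."""

    x: dict  # label -> ndarray of length n_nodes
    shape: tuple[int, int]

    def image(self, label: str) -> np.ndarray:
        return self.x[label].reshape(self.shape)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary mask plus the probabilities and settings that produced it."""

    mask: np.ndarray  # uint8, image shape
    probabilities: ProbabilityField
    variant: str
    beta: float
    gamma: float | None


def evaluate_objective(
    variant: str,
    x: np.ndarray,
    field: AttractionField | None,
    graph: LatticeGraph,
    label: str,
    epsilon_tau: float = 1e-6,
) -> float:
    """Value of the per-label objective at a full per-node vector ``x``.

    The smoothness part is sum_ij w_ij (x_i - x_j)^2 over all edges; the
    attraction part sums D(a_i, x_i, tau_i) over region nodes with D the
    variant's distance (Pearson: a (x - tau)^2 / (2 tau); inner product:
    a x tau; L2: a (x - tau)^2).  ``rw`` or ``field=None`` has no
    attraction part.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    if label not in LABELS:
        raise InvalidLabelError(f"unknown label {label!r}")
    x = np.asarray(x, dtype=np.float64).ravel()
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    smooth = float(np.sum(graph.weights * (x[i] - x[j]) ** 2))
    if variant == "rw" or field is None:
        return smooth
    a = field.factors.ravel()
    region = field.region.ravel()
    tau = range_base(field, label, floor=epsilon_tau if variant == "pea" else 0.0)
    ar, xr, tr = a[region], x[region], tau[region]
    if variant == "pea":
        if np.any(tr <= 0):
            raise SolverError("Pearson objective has tau = 0 on a region node")
        attr = float(np.sum(ar * (xr - tr) ** 2 / (2.0 * tr)))
    elif variant == "inn":
        attr = float(np.sum(ar * xr * tr))
    else:  # l2
        attr = float(np.sum(ar * (xr - tr) ** 2))
    return smooth + attr


def assemble_system(
    variant: str,
    ops: GraphOperators,
    a: np.ndarray | None = None,
    tau: dict | None = None,
    seeds: SeedSet | None = None,
    epsilon_tau: float = 1e-6,
) -> SystemBundle:
    """Build the per-label unmarked systems for one variant.

    ``a`` is the full-length attraction diagonal (zero outside the region)
    and ``tau`` maps each label to its full-length range base; ``a=None``
    (or variant ``rw``) yields the zero-attraction random-walker system.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    if seeds is None:
        raise InvalidSeedError("assemble_system requires the seed set")
    lap_u = ops.lap_unmarked
    n_u = lap_u.shape[0]
    if variant != "rw" and a is not None:
        a_u = np.asarray(a, dtype=np.float64).ravel()[ops.unmarked]
        tau_u = {
            c: np.asarray(tau[c], dtype=np.float64).ravel()[ops.unmarked] for c in LABELS
        }
    else:
        a_u = None

    matrices: dict = {}
    rhs: dict = {}
    for c in LABELS:
        m_c = seeds.indicator(c)
        base = -ops.boundary.T @ m_c
        if a_u is None:
            matrices[c] = lap_u.tocsc()
            rhs[c] = base
        elif variant == "pea":
            t = np.maximum(tau_u[c], epsilon_tau)
            if np.any((a_u > 0) & (tau_u[c] <= 0) & (epsilon_tau <= 0)):
                raise SolverError("Pearson system has tau = 0 on a region node and no floor")
            ratio = np.where(a_u > 0, a_u / t, 0.0)
            matrices[c] = (lap_u + 0.5 * sparse.diags(ratio)).tocsc()
            rhs[c] = base + a_u
        elif variant == "inn":
            matrices[c] = lap_u.tocsc()
            rhs[c] = base + a_u * tau_u[c]
        else:  # l2
            matrices[c] = (lap_u + sparse.diags(a_u)).tocsc()
            rhs[c] = base + a_u * tau_u[c]
        assert rhs[c].shape == (n_u,)
    return SystemBundle(variant=variant, matrices=matrices, rhs=rhs, ops=ops, seeds=seeds)


def _describe_unseeded_component(bundle: SystemBundle) -> str:
    """Name a connected component of the graph with no seed, if any."""
    lap = bundle.ops.laplacian
    adj = sparse.csr_matrix(
        (np.abs(lap.data) * (lap.data < 0), lap.indices, lap.indptr), shape=lap.shape
    )
    adj.eliminate_zeros()
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    seeded = set(labels[bundle.seeds.marked])
    for comp in range(n_comp):
        if comp not in seeded:
            nodes = np.flatnonzero(labels == comp)
            return (
                f"component of {nodes.size} nodes (first node {int(nodes[0])}) "
                "contains no seed"
            )
    return "no unseeded component found; matrix may be ill-conditioned"


def _solve_one(
    matrix: sparse.csc_matrix,
    rhs_vectors: list[np.ndarray],
    bundle: "SystemBundle",
) -> list[np.ndarray]:
    try:
        lu = spla.splu(matrix)
        return [lu.solve(b) for b in rhs_vectors]
    except (RuntimeError, ValueError) as exc:
        desc = _describe_unseeded_component(bundle)
        if "no seed" in desc:
            raise SolverError(f"singular system: {desc}") from exc
        # fall back to conjugate gradient; matrix is symmetric by construction
        out = []
        for b in rhs_vectors:
            x, info = spla.cg(
                matrix, b, rtol=1e-10, atol=0.0, maxiter=10 * matrix.shape[0]
            )
            if info != 0:
                raise SolverError(f"conjugate gradient failed with info={info}; {desc}")
            out.append(x)
        return out


def solve_probabilities(bundle: SystemBundle) -> ProbabilityField:
    """Solve the per-label systems and scatter back to image order.

    A sparse direct factorization is used (shared across labels when the
    matrix is label-independent), with a conjugate-gradient fallback.  The
    solve is rejected unless the max-norm residual is below
    ``1e-8 * (1 + ||b||_inf)``.
    """
    ops = bundle.ops
    labels = list(LABELS)
    label_dependent = bundle.variant == "pea" and bundle.matrices["f"] is not bundle.matrices["b"]
    if label_dependent:
        sols = {
            c: _solve_one(bundle.matrices[c], [bundle.rhs[c]], bundle)[0] for c in labels
        }
    else:
        xs = _solve_one(bundle.matrices["f"], [bundle.rhs[c] for c in labels], bundle)
        sols = dict(zip(labels, xs))

    x = {}
    rows_cols = None
    for c in labels:
        b = bundle.rhs[c]
        resid = np.abs(bundle.matrices[c] @ sols[c] - b).max() if b.size else 0.0
        tol = _RESIDUAL_RTOL * (1.0 + (np.abs(b).max() if b.size else 0.0))
        if not np.isfinite(resid) or resid > tol:
            raise SolverError(
                f"solve for label {c!r} reached residual {resid:.3e} > {tol:.3e}; "
                + _describe_unseeded_component(bundle)
            )
        x[c] = ops.scatter(bundle.seeds.indicator(c), sols[c])
    n = ops.n_nodes
    # shape is recovered by the caller; store a 1 x n default if unknown
    rows_cols = getattr(ops, "shape", None)
    return ProbabilityField(x=x, shape=rows_cols if rows_cols else (1, n))


def assign_labels(prob: ProbabilityField, seeds: SeedSet | None = None) -> np.ndarray:
    """Per-node argmax over labels; ties go to foreground.

    Seeded nodes keep their fixed labels automatically because their
    probabilities are the exact 0/1 indicators.
    """
    fg = prob.x[FOREGROUND] >= prob.x[BACKGROUND]
    return fg.astype(np.uint8).reshape(prob.shape)


def segment(
    grid: IntensityGrid,
    seeds: SeedSet,
    prior: ShapePrior | None = None,
    variant: str = "l2",
    beta: float = 310.0,
    gamma: float | None = None,
    connectivity: int = 4,
    epsilon_w: float = 1e-6,
    epsilon_tau: float = 1e-6,
    sharpness: float = 1.0,
) -> SegmentationResult:
    """Run the full seeded attraction-propagation pipeline on one image.

    Builds the weighted lattice graph, partitions its Laplacian by the
    seeds, places the shape prior at the (single) foreground seed, solves
    the variant's two linear systems and thresholds the probabilities into
    a binary mask.  ``prior=None``, variant ``"rw"``, or a prior whose
    thresholded support is empty all reduce to the plain random walker.

    ``gamma`` optionally re-thresholds the prior before placement;
    otherwise the prior's stored threshold is used.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    graph = build_lattice_graph(grid, beta=beta, connectivity=connectivity, epsilon_w=epsilon_w)
    ops = graph_operators(graph, seeds)

    field = None
    used_gamma = None
    if prior is not None and variant != "rw":
        if seeds.foreground.size != 1:
            raise InvalidSeedError(
                "attraction propagation uses exactly one foreground seed"
            )
        p = prior
        if gamma is not None:
            p = threshold_prior(prior, gamma)
        if p.threshold_matrix is None:
            raise InvalidParameterError(
                "prior is unthresholded and no gamma was given"
            )
        used_gamma = p.gamma
        if np.any(p.threshold_matrix):
            seed_rc = grid.node_coords(int(seeds.foreground[0]))
            field = attraction_factors(place_prior(p, seed_rc, grid), grid, sharpness)

    if field is not None:
        a = field.factors.ravel()
        tau = {c: range_base(field, c) for c in LABELS}
        bundle = assemble_system(variant, ops, a, tau, seeds, epsilon_tau=epsilon_tau)
    else:
        bundle = assemble_system(variant, ops, None, None, seeds)
    prob = solve_probabilities(bundle)
    prob = ProbabilityField(x=prob.x, shape=(grid.rows, grid.cols))
    mask = assign_labels(prob, seeds)
    return SegmentationResult(
        mask=mask,
        probabilities=prob,
        variant=variant,
        beta=float(beta),
        gamma=used_gamma,
    )
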