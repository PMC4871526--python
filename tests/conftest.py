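import numpy as np
import pytest

from apseg import IntensityGrid, SeedSet, build_lattice_graph, graph_operators
from apseg.attraction import AttractionField, attraction_factors


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def micro_setup():
    """1x3 constant image: one unknown node between a fg and a bg seed.

    Edge weights are exactly 1 (beta = 0, no weight floor); the middle
    pixel carries attraction a = 1 and target tau^f = 0.8.  The resulting
    one-unknown systems can be solved by hand for every variant.
    """
    grid = IntensityGrid(np.full((1, 3), 0.5))
    graph = build_lattice_graph(grid, beta=0.0, epsilon_w=0.0)
    seeds = SeedSet(np.array([0]), np.array([2]))
    ops = graph_operators(graph, seeds)
    field = AttractionField(
        region=np.array([[False, True, False]]),
        shifted_t=np.array([[0.0, 0.8, 0.0]]),
        seed=(0, 1),
        seed_intensity=0.5,
    )
    field = attraction_factors(field, grid)
    return grid, graph, seeds, ops, field


def random_instance(rng, rows=10, cols=10, n_fg=1, n_bg=6, beta=40.0, with_region=True):
    """A random small segmentation instance (grid, graph, seeds, a, tau)."""
    from apseg import range_base
    from apseg.attraction import AttractionField, attraction_factors

    grid = IntensityGrid(rng.uniform(size=(rows, cols)))
    graph = build_lattice_graph(grid, beta=beta, epsilon_w=1e-6)
    n = rows * cols
    marked = rng.choice(n, size=n_fg + n_bg, replace=False)
    seeds = SeedSet(marked[:n_fg], marked[n_fg:])
    field = None
    a = tau = None
    if with_region:
        region = rng.uniform(size=(rows, cols)) < 0.3
        region.flat[marked] = False  # seeded nodes never enter the solved system
        shifted = np.where(region, rng.uniform(0.2, 0.95, size=(rows, cols)), 0.0)
        if region.any():
            sr, sc = divmod(int(seeds.foreground[0]), cols)
            field = AttractionField(
                region=region, shifted_t=shifted, seed=(sr, sc),
                seed_intensity=float(grid.values[sr, sc]),
            )
            field = attraction_factors(field, grid)
            a = field.factors.ravel()
            tau = {c: range_base(field, c) for c in ("f", "b")}
    return grid, graph, seeds, field, a, tau
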