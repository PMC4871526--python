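import numpy as np
import pytest

from apseg import (
    IntensityGrid,
    SeedSet,
    assemble_system,
    assign_labels,
    build_lattice_graph,
    evaluate_objective,
    graph_operators,
    place_prior,
    range_base,
    segment,
    solve_probabilities,
    threshold_prior,
    train_prior,
    viewfinder_seeds,
)
from apseg.errors import InvalidParameterError, InvalidSeedError, SolverError
from apseg.solver import ProbabilityField

from conftest import random_instance


def dense_rw_reference(graph, seeds):
    """Independent dense random-walker solve (loop-built Laplacian)."""
    n = graph.n_nodes
    lap = np.zeros((n, n))
    for (i, j), w in zip(graph.edges, graph.weights):
        lap[i, j] -= w
        lap[j, i] -= w
        lap[i, i] += w
        lap[j, j] += w
    marked = list(seeds.marked)
    unmarked = [k for k in range(n) if k not in set(marked)]
    out = {}
    for label in ("f", "b"):
        m = seeds.indicator(label)
        x_u = np.linalg.solve(
            lap[np.ix_(unmarked, unmarked)], -lap[np.ix_(unmarked, marked)] @ m
        )
        full = np.empty(n)
        full[marked] = m
        full[unmarked] = x_u
        out[label] = full
    return out


class TestObjective:
    def test_constant_solution_at_tau_zeroes_quadratic_terms(self, micro_setup):
        grid, graph, seeds, ops, field = micro_setup
        x = np.full(3, 0.8)
        assert evaluate_objective("l2", x, field, graph, "f") == pytest.approx(0.0)
        assert evaluate_objective("pea", x, field, graph, "f") == pytest.approx(0.0)

    def test_scalar_values_on_single_region_node(self, micro_setup):
        grid, graph, seeds, ops, field = micro_setup
        # a=1, tau^f=0.8, x=0.6 on the region node; constant x kills smoothness
        x = np.full(3, 0.6)
        assert evaluate_objective("l2", x, field, graph, "f") == pytest.approx(0.04)
        assert evaluate_objective("pea", x, field, graph, "f") == pytest.approx(0.025)
        assert evaluate_objective("inn", x, field, graph, "f") == pytest.approx(0.48)

    def test_smoothness_term_alone(self):
        grid = IntensityGrid(np.array([[0.0, 1.0]]))
        graph = build_lattice_graph(grid, beta=np.log(2.0), epsilon_w=0.0)
        x = np.array([1.0, 0.0])
        assert evaluate_objective("rw", x, None, graph, "f") == pytest.approx(0.5)


class TestAssembly:
    def test_micro_example_matrices(self, micro_setup):
        grid, graph, seeds, ops, field = micro_setup
        a = field.factors.ravel()
        tau = {c: range_base(field, c) for c in ("f", "b")}
        l2 = assemble_system("l2", ops, a, tau, seeds)
        np.testing.assert_allclose(l2.matrices["f"].toarray(), [[3.0]])
        np.testing.assert_allclose(l2.rhs["f"], [1.8])
        pea = assemble_system("pea", ops, a, tau, seeds)
        np.testing.assert_allclose(pea.matrices["f"].toarray(), [[2.625]])
        np.testing.assert_allclose(pea.rhs["f"], [2.0])
        np.testing.assert_allclose(pea.matrices["b"].toarray(), [[4.5]])
        inn = assemble_system("inn", ops, a, tau, seeds)
        np.testing.assert_allclose(inn.matrices["f"].toarray(), [[2.0]])
        np.testing.assert_allclose(inn.rhs["f"], [1.8])

    def test_empty_region_reduces_to_rw_system(self, micro_setup, rng):
        grid, graph, seeds, ops, field = micro_setup
        rw = assemble_system("rw", ops, None, None, seeds)
        for variant in ("pea", "inn", "l2"):
            zero = assemble_system(
                variant, ops, np.zeros(3), {c: np.zeros(3) for c in ("f", "b")}, seeds
            )
            for c in ("f", "b"):
                np.testing.assert_allclose(
                    zero.matrices[c].toarray(), rw.matrices[c].toarray()
                )
                np.testing.assert_allclose(zero.rhs[c], rw.rhs[c])

    def test_unknown_variant_rejected(self, micro_setup):
        grid, graph, seeds, ops, field = micro_setup
        with pytest.raises(InvalidParameterError):
            assemble_system("gc", ops, None, None, seeds)


class TestSolve:
    def test_micro_example_probabilities(self, micro_setup):
        grid, graph, seeds, ops, field = micro_setup
        a = field.factors.ravel()
        tau = {c: range_base(field, c) for c in ("f", "b")}
        expected = {
            "l2": (0.6, 0.4),
            "pea": (2 / 2.625, 2 / 4.5),
            "inn": (0.9, 0.6),
            "rw": (0.5, 0.5),
        }
        for variant, (xf, xb) in expected.items():
            bundle = assemble_system(
                variant,
                ops,
                None if variant == "rw" else a,
                None if variant == "rw" else tau,
                seeds,
            )
            prob = solve_probabilities(bundle)
            assert prob.x["f"][1] == pytest.approx(xf, abs=1e-12)
            assert prob.x["b"][1] == pytest.approx(xb, abs=1e-12)
            # marked nodes carry their exact indicators
            assert prob.x["f"][0] == 1.0 and prob.x["f"][2] == 0.0
            assert prob.x["b"][0] == 0.0 and prob.x["b"][2] == 1.0

    def test_matches_dense_rw_reference(self, rng):
        for _ in range(10):
            grid, graph, seeds, *_ = random_instance(rng, 8, 8, with_region=False)
            ops = graph_operators(graph, seeds)
            bundle = assemble_system("rw", ops, None, None, seeds)
            prob = solve_probabilities(bundle)
            ref = dense_rw_reference(graph, seeds)
            for c in ("f", "b"):
                np.testing.assert_allclose(prob.x[c], ref[c], atol=1e-8)

    def test_l2_and_rw_probabilities_conserve_and_stay_in_range(self, rng):
        for _ in range(20):
            grid, graph, seeds, field, a, tau = random_instance(rng)
            ops = graph_operators(graph, seeds)
            for variant in ("l2", "rw"):
                bundle = assemble_system(
                    variant, ops, a if variant == "l2" else None,
                    tau if variant == "l2" else None, seeds,
                )
                prob = solve_probabilities(bundle)
                total = prob.x["f"] + prob.x["b"]
                np.testing.assert_allclose(total, 1.0, atol=1e-8)
                for c in ("f", "b"):
                    assert prob.x[c].min() >= -1e-8
                    assert prob.x[c].max() <= 1 + 1e-8

    def test_singular_system_names_unseeded_component(self):
        # a zero-weight bridge isolates node 2 from all seeds
        from apseg.image_graph import LatticeGraph

        graph = LatticeGraph(
            shape=(1, 3),
            edges=np.array([[0, 1], [1, 2]]),
            weights=np.array([1.0, 0.0]),
            beta=1.0,
            epsilon_w=0.0,
            connectivity=4,
        )
        seeds = SeedSet(np.array([0]), np.array([1]))
        ops = graph_operators(graph, seeds)
        bundle = assemble_system("rw", ops, None, None, seeds)
        with pytest.raises(SolverError, match="no seed"):
            solve_probabilities(bundle)

    def test_monotone_attraction_pull(self):
        # on a constant image, scaling the attraction by t in [0,1] moves
        # x^f on region nodes monotonically from the RW value toward tau
        m = np.ones((5, 5), dtype=np.uint8)
        prior = threshold_prior(
            train_prior([m], canvas_rows=5, canvas_cols=5, gamma=0.5), 0.5
        )
        grid = IntensityGrid(np.full((15, 15), 0.5))
        seeds = viewfinder_seeds(15, 15)
        graph = build_lattice_graph(grid)
        ops = graph_operators(graph, seeds)
        field = place_prior(prior, (7, 7), grid)
        from apseg import attraction_factors

        field = attraction_factors(field, grid)
        a = field.factors.ravel()
        tau = {c: range_base(field, c) for c in ("f", "b")}
        reg = field.region.ravel().copy()
        reg[seeds.marked] = False
        prev = None
        for t in (0.0, 0.25, 0.5, 0.75, 1.0):
            bundle = assemble_system("l2", ops, t * a, tau, seeds)
            xf = solve_probabilities(bundle).x["f"][reg]
            if prev is not None:
                assert np.all(xf >= prev - 1e-10)
            prev = xf


class TestLabelsAndSegment:
    def test_tie_goes_to_foreground(self):
        prob = ProbabilityField(
            x={"f": np.array([0.6, 0.5, 0.2]), "b": np.array([0.4, 0.5, 0.8])},
            shape=(1, 3),
        )
        np.testing.assert_array_equal(assign_labels(prob), [[1, 1, 0]])

    def test_prior_none_and_empty_support_match_rw(self, rng):
        from apseg import generate_phantom, PhantomSpec, shape_probability

        spec = PhantomSpec(rows=48, cols=48, radii=(8.0, 8.0), rng_seed=5)
        grid, _ = generate_phantom(spec)
        seeds = viewfinder_seeds(48, 48)
        rw = segment(grid, seeds, variant="rw")
        plain = segment(grid, seeds, prior=None, variant="l2")
        np.testing.assert_array_equal(plain.mask, rw.mask)
        # a prior whose support empties at gamma=1 also reduces to RW
        m1 = np.zeros((9, 9), dtype=np.uint8)
        m1[:4] = 1
        m2 = np.zeros((9, 9), dtype=np.uint8)
        m2[5:] = 1  # disjoint from m1: no cell has SP = 1
        prior = threshold_prior(shape_probability([m1, m2]), 1.0)
        assert not np.any(prior.threshold_matrix)
        res = segment(grid, seeds, prior=prior, variant="l2")
        np.testing.assert_array_equal(res.mask, rw.mask)

    def test_multiple_foreground_seeds_with_prior_rejected(self, rng):
        grid = IntensityGrid(rng.uniform(size=(12, 12)))
        m = np.ones((3, 3), dtype=np.uint8)
        prior = threshold_prior(train_prior([m], gamma=0.5), 0.5)
        seeds = SeedSet(np.array([40, 41]), np.array([0, 11, 132]))
        with pytest.raises(InvalidSeedError):
            segment(grid, seeds, prior=prior, variant="l2")

    def test_determinism_bit_identical(self, rng):
        from apseg import generate_mask_corpus, generate_phantom, PhantomSpec

        prior = train_prior(generate_mask_corpus(10, rng_seed=2), gamma=0.8)
        grid, _ = generate_phantom(PhantomSpec(rng_seed=9))
        seeds = viewfinder_seeds(96, 96)
        r1 = segment(grid, seeds, prior=prior, variant="l2")
        r2 = segment(grid, seeds, prior=prior, variant="l2")
        np.testing.assert_array_equal(r1.mask, r2.mask)
        for c in ("f", "b"):
            np.testing.assert_array_equal(r1.probabilities.x[c], r2.probabilities.x[c])

    def test_l2_variational_optimality(self, rng):
        # the solved x^f attains a lower full objective than random
        # perturbations of its unmarked entries
        for _ in range(5):
            grid, graph, seeds, field, a, tau = random_instance(rng, 8, 8)
            if field is None:
                continue
            ops = graph_operators(graph, seeds)
            bundle = assemble_system("l2", ops, a, tau, seeds)
            prob = solve_probabilities(bundle)
            x = prob.x["f"]
            base = evaluate_objective("l2", x, field, graph, "f")
            unmarked = ops.unmarked
            for _ in range(50):
                pert = x.copy()
                pert[unmarked] += rng.normal(scale=0.05, size=unmarked.size)
                assert evaluate_objective("l2", pert, field, graph, "f") >= base - 1e-12
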