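"""Supra-modularity assembly: grids, coefficients, couplings, bookkeeping."""

import numpy as np
import pytest

from hiercomm import (
    MultiplexSpec,
    MultiScaleSpec,
    MultiSliceMultiScaleSpec,
    NullModel,
    build_multiplex,
    build_multiscale,
    build_multislice_multiscale,
    make_gamma_grid,
)
from hiercomm.multiscale import config_from_spec, spec_from_config

from conftest import random_graph

UNIF = NullModel("uniform", constant=0.5)


class TestGammaGrid:
    @pytest.mark.parametrize(
        "start, stop, step, n",
        [
            (0.0, 12.0, 0.05, 241),     # coarse-to-fine structural sweep
            (0.0133, 1.0, 0.0133, 75),  # fine sweep: multiples of 0.0133 <= 1
            (1.0, 1.0, 0.1, 1),         # degenerate single-layer grid
            (0.95, 1.7, 0.01, 76),      # inclusive endpoints
        ],
    )
    def test_layer_counts(self, start, stop, step, n):
        grid = make_gamma_grid(start, stop, step)
        assert grid.size == n
        assert np.all(np.diff(grid) > 0)
        assert grid[0] == start

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_gamma_grid(0, 1, 0)
        with pytest.raises(ValueError):
            make_gamma_grid(2, 1, 0.1)


class TestBuildMultiscale:
    def test_hand_enumerated_pair(self, pair_supra):
        """2-node graph, uniform null 0.5, grid {1,2}, τ=0.3: all 8 coefficients."""
        b = pair_supra
        # layer 0: A - 1*0.5 = 0.5 ; layer 1: A - 2*0.5 = 0.0
        assert b.coefficient(0, 1) == pytest.approx(0.5)
        assert b.coefficient(2, 3) == pytest.approx(0.0)
        # τ couplings between a node and itself in the adjacent layer
        for i in range(2):
            assert b.coefficient(i, i + 2) == pytest.approx(0.3)
        # no cross-node cross-layer terms, zero diagonal
        assert b.coefficient(0, 3) == 0.0
        assert b.coefficient(1, 2) == 0.0
        assert b.coefficient(0, 0) == 0.0
        # μ = (2 + 2 + 4·0.3)/2
        assert b.mu == pytest.approx(2.6)

    def test_single_layer_equals_modularity_coefficients(self):
        g = random_graph(5, 2)
        gamma = 1.3
        spec = MultiScaleSpec(graph=g, gamma_grid=[gamma], tau=0.0, null=UNIF)
        b = build_multiscale(spec)
        expect = g.weights - gamma * UNIF.expected_matrix(g)
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(b.dense(), expect)

    def test_tau_zero_is_block_diagonal(self):
        g = random_graph(4, 3)
        spec = MultiScaleSpec(graph=g, gamma_grid=[0.5, 1.0, 1.5], tau=0.0, null=UNIF)
        dense = build_multiscale(spec).dense()
        for x in range(3):
            for y in range(3):
                if x != y:
                    assert np.all(dense[4 * x:4 * x + 4, 4 * y:4 * y + 4] == 0)

    def test_adjacent_only_chain(self):
        g = random_graph(3, 4)
        spec = MultiScaleSpec(graph=g, gamma_grid=[1, 2, 3, 4], tau=0.7, null=UNIF)
        b = build_multiscale(spec)
        assert b.coefficient(b.flat_index(0, 0), b.flat_index(0, 1)) == 0.7
        assert b.coefficient(b.flat_index(0, 0), b.flat_index(0, 2)) == 0.0
        assert b.coefficient(b.flat_index(0, 0), b.flat_index(0, 3)) == 0.0

    def test_newman_girvan_layers(self):
        g = random_graph(5, 6)
        spec = MultiScaleSpec(
            graph=g, gamma_grid=[0.8, 1.1], tau=0.2, null=NullModel("newman_girvan")
        )
        b = build_multiscale(spec)
        p = NullModel("newman_girvan").expected_matrix(g)
        for gamma, x in zip((0.8, 1.1), range(2)):
            got = b.dense()[5 * x:5 * x + 5, 5 * x:5 * x + 5]
            expect = g.weights - gamma * p
            np.fill_diagonal(expect, 0.0)
            assert np.allclose(got, expect)

    def test_invalid_specs(self):
        g = random_graph(3, 0)
        with pytest.raises(ValueError, match="increasing"):
            MultiScaleSpec(graph=g, gamma_grid=[2.0, 1.0], tau=0.1, null=UNIF)
        with pytest.raises(ValueError, match="tau"):
            MultiScaleSpec(graph=g, gamma_grid=[1.0], tau=-0.1, null=UNIF)


class TestBuildMultiplex:
    def test_layout_and_kappa_pair_count(self):
        g = random_graph(3, 5)
        spec = MultiplexSpec(
            graph_a=g, graph_b=g, gamma_grid_a=[1, 2], gamma_grid_b=[1, 2],
            tau=0.0, kappa=0.7, null_a=UNIF, null_b=UNIF,
        )
        b = build_multiplex(spec)
        assert b.n_node_layers == 12
        coo = b.adj.tocoo()
        assert int((coo.data == 0.7).sum()) == 12  # 6 pairs, symmetric
        # κ sits between same node, same scale layer, across modalities
        assert b.coefficient(b.flat_index(1, 0, 0), b.flat_index(1, 0, 1)) == 0.7
        assert b.coefficient(b.flat_index(1, 0, 0), b.flat_index(2, 0, 1)) == 0.0

    def test_mismatched_nodes_error(self):
        with pytest.raises(ValueError, match="node set"):
            MultiplexSpec(
                graph_a=random_graph(3, 1), graph_b=random_graph(4, 1),
                gamma_grid_a=[1], gamma_grid_b=[1],
                tau=0.0, kappa=0.1, null_a=UNIF, null_b=UNIF,
            )


class TestBuildMultisliceMultiscale:
    def test_one_slice_reduces_to_multiscale(self):
        g = random_graph(4, 7)
        ms = MultiSliceMultiScaleSpec(
            slices=[g], gamma_grid=[0.5, 1.0], tau=0.2, omega=0.9, nulls=[UNIF]
        )
        plain = MultiScaleSpec(graph=g, gamma_grid=[0.5, 1.0], tau=0.2, null=UNIF)
        assert np.allclose(
            build_multislice_multiscale(ms).dense(), build_multiscale(plain).dense()
        )

    def test_omega_zero_block_diagonal_over_slices(self):
        g1, g2 = random_graph(3, 1), random_graph(3, 2)
        ms = MultiSliceMultiScaleSpec(
            slices=[g1, g2], gamma_grid=[1.0], tau=0.1, omega=0.0,
            nulls=[UNIF, UNIF],
        )
        b = build_multislice_multiscale(ms)
        for i in range(3):
            for j in range(3):
                assert b.coefficient(b.flat_index(i, 0, 0), b.flat_index(j, 0, 1)) == 0.0

    def test_hand_enumerated_2x2x2(self):
        """2 slices × 2 scales × 2 nodes: every coupling term by hand."""
        w1 = np.array([[0.0, 1.0], [1.0, 0.0]])
        w2 = np.array([[0.0, 2.0], [2.0, 0.0]])
        from hiercomm import WeightedGraph

        ms = MultiSliceMultiScaleSpec(
            slices=[WeightedGraph(w1), WeightedGraph(w2)],
            gamma_grid=[1.0, 3.0], tau=0.4, omega=0.6,
            nulls=[UNIF, UNIF],
        )
        b = build_multislice_multiscale(ms)
        # intra terms: A_l - γ_x · 0.5
        assert b.coefficient(b.flat_index(0, 0, 0), b.flat_index(1, 0, 0)) == pytest.approx(1 - 0.5)
        assert b.coefficient(b.flat_index(0, 0, 1), b.flat_index(1, 0, 1)) == pytest.approx(2 - 0.5)
        assert b.coefficient(b.flat_index(0, 1, 0), b.flat_index(1, 1, 0)) == pytest.approx(1 - 1.5)
        assert b.coefficient(b.flat_index(0, 1, 1), b.flat_index(1, 1, 1)) == pytest.approx(2 - 1.5)
        # ω: same node, adjacent slices, same scale; τ: same node, same slice, adjacent scales
        assert b.coefficient(b.flat_index(0, 0, 0), b.flat_index(0, 0, 1)) == 0.6
        assert b.coefficient(b.flat_index(0, 0, 0), b.flat_index(0, 1, 0)) == 0.4
        # no diagonal couplings across both axes at once
        assert b.coefficient(b.flat_index(0, 0, 0), b.flat_index(0, 1, 1)) == 0.0
        # μ: intra 2·(2+4)/2... sum per cell: slices contribute ΣA per scale copy
        # ΣA = 2 (slice 1) and 4 (slice 2) at each of 2 scales; couplings:
        # ω pairs 2 nodes × 2 scales, τ pairs 2 nodes × 2 slices, each ×2 directions
        expected_2mu = (2 + 4) * 2 + 2 * 2 * 0.6 * 2 + 2 * 2 * 0.4 * 2
        assert 2 * b.mu == pytest.approx(expected_2mu)


class TestStructureInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_total_coefficient_sum(self, seed):
        """Σ over all pairs of B equals ΣA - Σ γP per layer plus coupling mass."""
        g = random_graph(4, seed)
        grid = [0.5, 1.0, 2.0]
        tau = 0.3
        spec = MultiScaleSpec(graph=g, gamma_grid=grid, tau=tau, null=UNIF)
        b = build_multiscale(spec)
        dense = b.dense()
        p_sum = 0.5 * 4 * 3  # uniform null over off-diagonal pairs
        expect = sum(g.weights.sum() - gam * p_sum for gam in grid)
        expect += 2 * (4 * 2) * tau  # node × adjacent-pair couplings, both directions
        assert dense.sum() == pytest.approx(expect)

    def test_symmetry_and_positive_mu(self):
        g = random_graph(5, 9)
        b = build_multiscale(
            MultiScaleSpec(graph=g, gamma_grid=[1, 2], tau=0.1, null=UNIF)
        )
        dense = b.dense()
        assert np.abs(dense - dense.T).max() == 0.0
        assert b.mu > 0


class TestConfigRoundTrip:
    def test_multiscale_config(self):
        g = random_graph(4, 1)
        cfg = {
            "gamma": {"start": 0.0, "stop": 1.0, "step": 0.25},
            "tau": 0.1,
            "null": {"kind": "uniform", "mode": "mean_all"},
        }
        spec = spec_from_config(g, cfg)
        assert spec.n_layers == 5
        assert spec.null.kind == "uniform"
        back = config_from_spec(spec)
        assert back["gamma"]["step"] == pytest.approx(0.25)
        assert back["tau"] == 0.1

    def test_multiplex_config(self):
        g = random_graph(4, 2)
        cfg = {
            "gamma": {"start": 0.5, "stop": 1.0, "step": 0.5},
            "tau": 0.2, "kappa": 0.4,
            "null": {"kind": "newman_girvan"},
        }
        spec = spec_from_config(g, cfg, graph_b=g)
        assert spec.kappa == 0.4
        assert config_from_spec(spec)["kappa"] == 0.4
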