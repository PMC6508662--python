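"""Quality evaluation and the generalized Louvain optimizer.

The heuristic is certified against an exhaustive set-partition enumeration
on every problem small enough to enumerate (Bell-number oracle), and its
phase bookkeeping is asserted internally on every run.
"""

import numpy as np
import pytest

from hiercomm import (
    MultiplexSpec,
    MultiScalePartition,
    MultiScaleSpec,
    NullModel,
    build_multiplex,
    build_multiscale,
)
from hiercomm.louvain import (
    evaluate_quality,
    louvain_optimize,
    run_ensemble,
    single_scale_sweep,
)

from conftest import exhaustive_optimum, louvain_best, random_graph

UNIF = NullModel("uniform", constant=0.5)


class TestEvaluateQuality:
    def test_all_singletons_score_zero(self, pair_supra):
        labels = np.arange(pair_supra.n_node_layers)
        assert evaluate_quality(pair_supra, labels) == 0.0

    def test_one_community_sums_everything(self, pair_supra):
        labels = np.zeros(4, dtype=int)
        total = pair_supra.dense().sum()
        assert evaluate_quality(pair_supra, labels) == pytest.approx(
            total / (2 * pair_supra.mu)
        )

    def test_hand_computed_linked_pairs(self, pair_supra):
        """Nodes together per layer, linked across layers: Σ = 2·0.5 + 0 + 4·0.3."""
        labels = np.zeros(4, dtype=int)
        q = evaluate_quality(pair_supra, labels, normalized=False)
        assert q == pytest.approx(2 * 0.5 + 2 * 0.0 + 4 * 0.3)
        # splitting the layers keeps intra terms but drops the couplings
        split = np.array([0, 0, 1, 1])
        assert evaluate_quality(pair_supra, split, normalized=False) == pytest.approx(1.0)

    def test_dimension_mismatch_errors(self, pair_supra):
        with pytest.raises(ValueError, match="node-layers"):
            evaluate_quality(pair_supra, np.zeros(3, dtype=int))

    def test_matches_dense_quadratic_form(self):
        g = random_graph(4, 11)
        b = build_multiscale(
            MultiScaleSpec(graph=g, gamma_grid=[0.7, 1.4], tau=0.25, null=UNIF)
        )
        rng = np.random.default_rng(0)
        dense = b.dense()
        for _ in range(10):
            lab = rng.integers(0, 3, size=8)
            expect = dense[np.equal.outer(lab, lab)].sum() / (2 * b.mu)
            assert evaluate_quality(b, lab) == pytest.approx(expect)


class TestLouvainOptimize:
    def test_two_cliques_planted_optimum(self, two_clique_supra):
        part = louvain_optimize(two_clique_supra, seed=0)
        assert part.n_communities == 2
        assert np.array_equal(part.labels.ravel(), [0, 0, 0, 1, 1, 1])
        best_q, _ = exhaustive_optimum(two_clique_supra)
        assert part.quality == pytest.approx(best_q)

    def test_all_negative_coefficients_give_singletons(self):
        g = random_graph(5, 3)
        # γ·constant above every weight makes every merge unprofitable
        spec = MultiScaleSpec(graph=g, gamma_grid=[10.0], tau=0.0, null=UNIF)
        part = louvain_optimize(build_multiscale(spec), seed=1)
        assert part.n_communities == 5
        assert part.quality == 0.0

    def test_recorded_quality_is_recomputable(self, pair_supra):
        part = louvain_optimize(pair_supra, seed=5)
        assert part.quality == pytest.approx(evaluate_quality(pair_supra, part))

    def test_seed_determinism(self, two_clique_supra):
        a = louvain_optimize(two_clique_supra, seed=9)
        b = louvain_optimize(two_clique_supra, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_labels_canonical_first_appearance(self, two_clique_supra):
        part = louvain_optimize(two_clique_supra, seed=2)
        flat = part.flat_labels()
        seen = []
        for lab in flat:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    @pytest.mark.parametrize(
        "case",
        [
            "pair_two_layers",
            "random_uniform_2layer",
            "random_ng_single",
            "multiplex_2x2x2",
            "sparse_uniform_single",
        ],
    )
    def test_matches_exhaustive_optimum(self, case, pair_supra):
        """On every <= 8 node-layer problem, 20 restarts reach the global optimum."""
        if case == "pair_two_layers":
            supra = pair_supra
        elif case == "random_uniform_2layer":
            g = random_graph(4, 21)
            supra = build_multiscale(
                MultiScaleSpec(graph=g, gamma_grid=[0.8, 1.6], tau=0.15, null=UNIF)
            )
        elif case == "random_ng_single":
            g = random_graph(7, 22, density=0.6)
            supra = build_multiscale(
                MultiScaleSpec(
                    graph=g, gamma_grid=[1.0], tau=0.0,
                    null=NullModel("newman_girvan"),
                )
            )
        elif case == "multiplex_2x2x2":
            spec = MultiplexSpec(
                graph_a=random_graph(2, 23), graph_b=random_graph(2, 24),
                gamma_grid_a=[0.5, 1.0], gamma_grid_b=[0.5, 1.0],
                tau=0.2, kappa=0.3, null_a=UNIF, null_b=UNIF,
            )
            supra = build_multiplex(spec)
        else:
            g = random_graph(8, 25, density=0.4)
            supra = build_multiscale(
                MultiScaleSpec(
                    graph=g, gamma_grid=[1.0], tau=0.0,
                    null=NullModel("uniform", constant=0.2),
                )
            )
        best_q, _ = exhaustive_optimum(supra)
        heur = louvain_best(supra, restarts=20)
        assert heur.quality == pytest.approx(best_q, abs=1e-9)


class TestRunEnsemble:
    def test_single_run_matches_direct_call(self, two_clique_supra):
        e = run_ensemble(two_clique_supra, n_runs=1, base_seed=4)
        direct = louvain_optimize(two_clique_supra, seed=4)
        assert np.array_equal(e.runs[0].labels, direct.labels)

    def test_unique_optimum_makes_runs_agree(self, two_clique_supra):
        e = run_ensemble(two_clique_supra, n_runs=10, base_seed=0)
        for run in e.runs:
            assert np.array_equal(run.labels, e.runs[0].labels)

    def test_seed_bookkeeping_and_determinism(self, two_clique_supra):
        e1 = run_ensemble(two_clique_supra, n_runs=3, base_seed=7)
        e2 = run_ensemble(two_clique_supra, n_runs=3, base_seed=7)
        assert e1.seeds == (7, 8, 9)
        assert np.array_equal(e1.labels_array(), e2.labels_array())

    def test_invalid_run_count(self, two_clique_supra):
        with pytest.raises(ValueError):
            run_ensemble(two_clique_supra, n_runs=0)


class TestSingleScaleSweep:
    def test_all_positive_coefficients_one_community(self):
        g = random_graph(5, 31)
        parts = single_scale_sweep(
            g, [1e-6], NullModel("uniform", constant=0.01), n_runs=3, seed=0
        )
        assert parts[0].n_communities == 1

    def test_two_cliques_newman_girvan(self, two_cliques):
        parts = single_scale_sweep(
            two_cliques, [1.0], NullModel("newman_girvan"), n_runs=5, seed=0
        )
        assert parts[0].n_communities == 2

    def test_labels_not_linked_across_gammas(self, two_cliques):
        parts = single_scale_sweep(
            two_cliques, [0.5, 1.0, 2.0], NullModel("newman_girvan"), n_runs=2, seed=1
        )
        assert len(parts) == 3
        for p in parts:
            assert p.n_layers == 1


class TestPartitionContainer:
    def test_shapes_and_slices(self):
        lab = np.zeros((3, 2, 2), dtype=int)
        lab[:, :, 1] = 1
        p = MultiScalePartition(labels=lab, quality=0.1)
        assert p.n_slices == 2
        assert p.select_slice(1).labels.shape == (3, 2)
        with pytest.raises(ValueError):
            MultiScalePartition(labels=np.zeros(3, dtype=int), quality=0.0)
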