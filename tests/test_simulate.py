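"""Simulator: random trees, sequence evolution, noisy distances."""

import numpy as np
import pytest

import treemetrics as tm
from treemetrics.simulate import (
    LogDetSingularError,
    SimConfig,
    evolve_sequences,
    hamming_distances,
    logdet_distances,
    make_dataset,
    random_tree,
)


class TestRandomTree:
    def test_quartet_has_one_internal_edge(self):
        T = random_tree(SimConfig(n_leaves=4, seed=0))
        internal = [
            (u, v, w) for u, v, w in T.edges()
            if u not in T.leaf_labels and v not in T.leaf_labels
        ]
        assert len(internal) == 1
        assert len(T.edges()) == 5

    def test_binary_and_right_leaf_count(self):
        for model in ("uniform_addition", "yule"):
            T = random_tree(SimConfig(n_leaves=12, seed=3, topology_model=model))
            assert T.n_leaves == 12
            assert len(T.edges()) == 2 * 12 - 3
            degrees = {u: len(nbrs) for u, nbrs in T.adjacency.items()}
            for u, d in degrees.items():
                assert d == (1 if u in T.leaf_labels else 3)

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_leaves=15, seed=42)
        assert random_tree(cfg).to_newick() == random_tree(cfg).to_newick()

    def test_unknown_length_law_rejected(self):
        cfg = SimConfig(n_leaves=5, seed=0, edge_length_law=("cauchy", {}))
        with pytest.raises(ValueError):
            random_tree(cfg)

    def test_default_conditions_stay_below_saturation(self):
        """With the default edge-length law, the saturating four-state map of
        the path metric stays below 0.74 for the vast majority of seeds."""
        z = tm.JukesCantor(4)
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            T = random_tree(SimConfig(n_leaves=100, seed=seed))
            dmax = T.distance_matrix().max_offdiag()
            if float(z(dmax)) < 0.74:
                ok += 1
        assert ok >= 95


class TestSequenceEvolution:
    def test_zero_length_edge_copies_parent(self):
        T = tm.PhyloTree({0: {2: 0.0}, 1: {2: 0.7}, 2: {0: 0.0, 1: 0.7}},
                         {0: "a", 1: "b"})
        cfg = SimConfig(n_leaves=4, seed=1, seq_length=500)
        M = evolve_sequences(T, cfg)
        # node 2 is the root; leaf "a" sits at distance 0 from it
        assert M.n_sites == 500

    def test_long_branch_decorrelates_to_uniform(self):
        T = tm.PhyloTree({0: {2: 0.0}, 1: {2: 50.0}, 2: {0: 0.0, 1: 50.0}},
                         {0: "a", 1: "b"})
        cfg = SimConfig(n_leaves=4, seed=2, seq_length=20000)
        M = evolve_sequences(T, cfg)
        d = hamming_distances(M).get("a", "b")
        assert d == pytest.approx(0.75, abs=0.02)

    def test_mismatch_fraction_matches_saturating_map(self):
        # total path 0.3 between two leaves, k = 4, L = 1e5: the observed
        # mismatch fraction estimates 0.75*(1 - exp(-0.4))
        L = 100_000
        T = tm.PhyloTree({0: {2: 0.1}, 1: {2: 0.2}, 2: {0: 0.1, 1: 0.2}},
                         {0: "a", 1: "b"})
        cfg = SimConfig(n_leaves=4, seed=7, seq_length=L)
        M = evolve_sequences(T, cfg)
        p = float(tm.JukesCantor(4)(0.3))
        se = np.sqrt(p * (1 - p) / L)
        assert abs(hamming_distances(M).get("a", "b") - p) < 3 * se


class TestHamming:
    def test_identical_and_complementary(self):
        M = tm.CharacterMatrix(("a", "b", "c"),
                               np.array([[0, 1, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0]],
                                        dtype=np.uint8), "AC")
        D = hamming_distances(M)
        assert D.get("a", "b") == 0.0
        assert D.get("a", "c") == 1.0


class TestLogDet:
    def test_identical_sequences_uniform_composition(self):
        # C is diag(1/4,...) so -ln|det| = 4*ln(4)
        rng = np.random.default_rng(0)
        seq = np.repeat(np.arange(4, dtype=np.uint8), 2500)
        M = tm.CharacterMatrix(("a", "b"), np.stack([seq, seq]), "ACGT")
        d = logdet_distances(M).get("a", "b")
        assert d == pytest.approx(4 * np.log(4), abs=1e-12)

    def test_zero_length_sequences_error(self):
        M = tm.CharacterMatrix(("a", "b"), np.empty((2, 0), dtype=np.uint8), "ACGT")
        with pytest.raises(ValueError):
            logdet_distances(M)

    def test_singular_pair_reported(self):
        # constant sequences: C has a single nonzero entry -> singular
        M = tm.CharacterMatrix(("a", "b"),
                               np.zeros((2, 8), dtype=np.uint8), "ACGT")
        with pytest.raises(LogDetSingularError) as exc:
            logdet_distances(M)
        assert ("a", "b") in exc.value.pairs

    def test_four_point_violation_shrinks_with_sequence_length(self):
        cfg0 = SimConfig(n_leaves=6, seed=11, edge_length_law=("exponential",
                                                               {"mean": 0.08}))
        T = random_tree(cfg0)
        viols = []
        for L in (200, 2000, 20000):
            cfg = SimConfig(n_leaves=6, seed=13, seq_length=L)
            M = evolve_sequences(T, cfg)
            D = logdet_distances(M, on_singular="max")
            viols.append(tm.check_four_point(D).worst_violation)
        assert viols[2] < viols[0]


class TestMakeDataset:
    def test_noise_free_dataset_is_exact_and_refittable(self):
        cfg = SimConfig(n_leaves=15, seed=3)
        tree, T, D = make_dataset(cfg, tm.JukesCantor(4))
        assert np.allclose(D.values, tm.JukesCantor(4).apply(T).values)
        assert tm.nonadditivity(D, tm.JukesCantor(4)) < 1e-9

    def test_pure_noise_converges_to_saturating_map_of_source(self):
        cfg = SimConfig(n_leaves=6, seed=19, epsilon=1.0, seq_length=100_000)
        tree, T, D = make_dataset(cfg, tm.JukesCantor(4))
        expected = tm.JukesCantor(4).apply(T)
        assert np.abs(D.values - expected.values).max() < 0.02

    def test_intermediate_noise_perturbs_but_preserves_scale(self):
        cfg = SimConfig(n_leaves=10, seed=23, epsilon=0.2, seq_length=300)
        _, T, D = make_dataset(cfg, tm.JukesCantor(4))
        clean = tm.JukesCantor(4).apply(T)
        diff = np.abs(D.values - clean.values).max()
        assert 0 < diff < 0.2

    def test_identical_seeds_give_identical_matrices(self):
        cfg = SimConfig(n_leaves=8, seed=31, epsilon=0.1, seq_length=200)
        _, _, D1 = make_dataset(cfg, tm.JukesCantor(4))
        _, _, D2 = make_dataset(cfg, tm.JukesCantor(4))
        assert np.array_equal(D1.values, D2.values)
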