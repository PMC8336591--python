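import numpy as np
import pytest

from internof1 import (
    CountMatrix,
    SimulationConfig,
    assign_truth,
    build_null_pool,
    generate_dataset,
    generate_grid,
    grid_manifest,
    sample_deg_lfc,
    synth_baseline,
)


@pytest.fixture(scope="module")
def config():
    return SimulationConfig(n_genes=2000, cohort_size=3, seed=5)


class TestSynthBaseline:
    def test_seeded_reproducibility(self, config):
        a, _ = synth_baseline(config)
        b, _ = synth_baseline(config)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_nonnegative_integers(self, config):
        matrix, _ = synth_baseline(config)
        assert np.all(matrix.counts >= 0)
        np.testing.assert_array_equal(matrix.counts, np.rint(matrix.counts))

    def test_replicate_pair_log2fc_centred_at_zero(self, config):
        matrix, pairs = synth_baseline(config)
        lfcs = np.concatenate(
            [
                np.log2(matrix.column(a) + 1) - np.log2(matrix.column(b) + 1)
                for a, b in pairs
            ]
        )
        assert abs(np.median(lfcs)) < 0.05

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            synth_baseline(SimulationConfig(n_genes=500))


class TestNullPool:
    def test_positive_baselines_make_ten_bins(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 500, size=(1000, 4)).astype(float)
        matrix = CountMatrix(
            [f"g{i}" for i in range(1000)], ["a", "b", "c", "d"], counts
        )
        pool = build_null_pool(matrix, [("a", "b"), ("c", "d")])
        assert len(pool.pools) == 10

    def test_constant_replicates_give_zero_fold_changes(self):
        counts = np.tile(np.arange(10.0, 1010.0)[:, None], (1, 2))
        matrix = CountMatrix([f"g{i}" for i in range(1000)], ["a", "b"], counts)
        pool = build_null_pool(matrix, [("a", "b")])
        assert all(np.all(p == 0.0) for p in pool.pools.values())
        draws = pool.draw(np.random.default_rng(1))
        assert np.all(draws == 0.0)

    def test_draws_come_from_own_bin_pool(self, config):
        matrix, pairs = synth_baseline(config)
        pool = build_null_pool(matrix, pairs)
        draws = pool.draw(np.random.default_rng(3))
        for i in np.random.default_rng(4).choice(matrix.n_genes, 50, replace=False):
            assert draws[i] in pool.pools[int(pool.bin_of_gene[i])]

    def test_no_replicate_pairs_rejected(self, config):
        matrix, _ = synth_baseline(config)
        with pytest.raises(ValueError, match="replicate pair"):
            build_null_pool(matrix, [])


class TestDegLfc:
    def test_mean_matches_gamma_moments(self):
        draws = sample_deg_lfc(100_000, 0.55, 6.06, rng=0)
        assert np.mean(draws) == pytest.approx(0.55 * 6.06, rel=0.02)

    def test_all_positive(self):
        assert np.all(sample_deg_lfc(10_000, 0.55, 6.06, rng=1) > 0)

    def test_seeded_reproducibility(self):
        np.testing.assert_array_equal(
            sample_deg_lfc(100, rng=2), sample_deg_lfc(100, rng=2)
        )


class TestAssignTruth:
    def test_deg_count_is_round_half_up_of_proportion(self):
        config = SimulationConfig(n_genes=2000, cohort_size=4, seed=1)
        genes = [f"g{i}" for i in range(2000)]
        truth = assign_truth(config, genes)
        # sizes 200 and 40 at proportion 0.10 -> 20 and 4 DEGs per subject
        for set_id, expected in (("enriched_200", 20), ("enriched_40", 4)):
            members = set(truth.collection.get(set_id).genes)
            for degs in truth.subject_degs:
                assert len(degs & members) == expected

    def test_full_coordination_shares_selection(self):
        config = SimulationConfig(
            n_genes=2000, cohort_size=5, prop_coordinated=1.0, seed=2
        )
        truth = assign_truth(config, [f"g{i}" for i in range(2000)])
        assert truth.subject_coordinated.all()
        assert len(set(truth.subject_degs)) == 1

    def test_zero_coordination_draws_independently(self):
        config = SimulationConfig(
            n_genes=2000, cohort_size=5, prop_coordinated=0.0, seed=3
        )
        truth = assign_truth(config, [f"g{i}" for i in range(2000)])
        assert not truth.subject_coordinated.any()
        assert len(set(truth.subject_degs)) > 1

    def test_enriched_and_control_sets_disjoint(self):
        config = SimulationConfig(n_genes=2000, seed=4)
        truth = assign_truth(config, [f"g{i}" for i in range(2000)])
        all_genes = [g for s in truth.collection for g in s.genes]
        assert len(all_genes) == len(set(all_genes))

    def test_zero_rounded_deg_count_rejected(self):
        config = SimulationConfig(
            n_genes=2000, enriched_sets=((4, 0.05),), seed=5
        )
        with pytest.raises(ValueError, match="rounds to 0"):
            assign_truth(config, [f"g{i}" for i in range(2000)])


class TestGenerateDataset:
    def test_bitwise_reproducible(self, config):
        a = generate_dataset(config)
        b = generate_dataset(config)
        np.testing.assert_array_equal(a.counts.counts, b.counts.counts)
        assert a.truth_degs == b.truth_degs

    def test_counts_are_nonnegative_integers(self, small_dataset):
        counts = small_dataset.counts.counts
        assert np.all(counts >= 0)
        np.testing.assert_array_equal(counts, np.rint(counts))

    def test_cohort_b_carries_no_seeded_degs(self, small_dataset):
        for pair in small_dataset.cohort_b.subjects:
            assert small_dataset.truth_degs[pair.subject_id] == frozenset()

    def test_truth_labels_mark_only_enriched_sets(self, small_dataset):
        assert small_dataset.truth_positive_sets() == {"enriched_200", "enriched_40"}
        assert small_dataset.truth_sets["control_196"] is False

    def test_sample_layout_pairs_match_matrix(self, small_dataset):
        for pair in small_dataset.all_pairs():
            assert pair.baseline_sample in small_dataset.counts.samples
            assert pair.case_sample in small_dataset.counts.samples

    def test_global_null_config_has_no_positive_truth(self):
        config = SimulationConfig(n_genes=1500, cohort_size=2, enriched_sets=(),
                                  seed=9)
        dataset = generate_dataset(config)
        assert dataset.truth_positive_sets() == set()
        assert all(v == frozenset() for v in dataset.truth_degs.values())


class TestGrid:
    def test_default_manifest_has_450_entries(self):
        manifest = grid_manifest(SimulationConfig(seed=0))
        assert len(manifest) == 450

    def test_single_rep_manifest(self):
        manifest = grid_manifest(SimulationConfig(seed=0), reps=1)
        assert len(manifest) == 15

    def test_same_base_seed_same_manifest(self):
        a = grid_manifest(SimulationConfig(seed=7))
        b = grid_manifest(SimulationConfig(seed=7))
        assert a == b

    def test_reps_by_size_override(self):
        manifest = grid_manifest(
            SimulationConfig(seed=0), reps=30, reps_by_size={30: 10}
        )
        n30 = sum(1 for e in manifest if e["cohort_size"] == 30)
        assert n30 == 3 * 10
        assert len(manifest) == 4 * 3 * 30 + 30

    def test_grid_datasets_reproducible(self):
        base = SimulationConfig(n_genes=1500, seed=3)
        _, grid_a = generate_grid(base, cohort_sizes=[2], props=[0.5], reps=2)
        _, grid_b = generate_grid(base, cohort_sizes=[2], props=[0.5], reps=2)
        for (ea, da), (eb, db) in zip(grid_a, grid_b):
            assert ea == eb
            np.testing.assert_array_equal(da.counts.counts, db.counts.counts)

    def test_seeds_below_2_31(self):
        manifest = grid_manifest(SimulationConfig(seed=123), reps=2)
        assert all(0 <= e["seed"] < 2**31 for e in manifest)
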