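import numpy as np
import pytest

from mitophylo import synthgen
from mitophylo.alignment import load_partitioned_alignment
from mitophylo.substmodels import SubstModelParams
from mitophylo.synthgen import (BirthDeathParams, ExtinctLineageError,
                                GBMRateParams)
from mitophylo.treeio import annotate_ages_from_lengths, write_newick

from .conftest import random_tree, surviving_bd_tree


class TestBirthDeathTree:
    def test_yule_tip_count_matches_closed_form(self):
        """Crown Yule process: E[tips] = 2*exp(b*t)."""
        b, t_max, reps = 0.05, 100.0, 500
        counts = [len(synthgen.simulate_bd_tree(
            BirthDeathParams(b=b, t_max=t_max), seed).leaf_nodes())
            for seed in range(reps)]
        counts = np.asarray(counts, dtype=float)
        expected = 2 * np.exp(b * t_max)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expected) < 3 * se

    def test_ultrametric_with_tips_at_zero(self):
        tree = synthgen.simulate_bd_tree(BirthDeathParams(b=0.08, t_max=50.0), 4)
        for lf in tree.leaf_node_iter():
            assert lf.age == 0.0
        assert tree.seed_node.age <= 50.0
        annotate_ages_from_lengths(tree)  # raises if not ultrametric

    def test_same_seed_same_newick(self):
        p = BirthDeathParams(b=0.06, d=0.02, t_max=80.0)
        t1 = surviving_bd_tree(p, 9)
        t2 = surviving_bd_tree(p, 9)
        assert write_newick(t1) == write_newick(t2)

    def test_extinction_is_signalled_not_silent(self):
        p = BirthDeathParams(b=0.02, d=0.02, t_max=400.0)
        raised = 0
        for seed in range(15):
            try:
                synthgen.simulate_bd_tree(p, seed)
            except ExtinctLineageError:
                raised += 1
        assert raised > 0

    def test_n_target_stops_at_count(self):
        tree = surviving_bd_tree(BirthDeathParams(b=0.1, d=0.0, t_max=1e3,
                                                  n_target=12), 3)
        assert len(tree.leaf_nodes()) == 12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BirthDeathParams(b=0.0)
        with pytest.raises(ValueError):
            BirthDeathParams(b=0.1, d=0.2)


class TestGBMRates:
    def test_nu_zero_is_a_strict_clock(self):
        tree = random_tree(8, seed=2, depth=10.0)
        rates = synthgen.simulate_gbm_rates(
            tree, GBMRateParams(root_rate=1e-3, nu=0.0), 7)
        assert np.allclose(rates, 1e-3)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                dt = nd.parent_node.age - nd.age
                assert nd.edge.length == pytest.approx(1e-3 * dt)

    def test_log_rate_is_martingale_without_correction(self):
        tree = random_tree(4, seed=5, depth=20.0)
        params = GBMRateParams(root_rate=1e-3, nu=0.01)
        rep_means = []
        for seed in range(400):
            synthgen.simulate_gbm_rates(tree, params, seed, set_lengths=False)
            rep_means.append(np.mean([lf.log_rate for lf in tree.leaf_node_iter()]))
        rep_means = np.asarray(rep_means)
        se = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
        assert abs(rep_means.mean() - np.log(1e-3)) < 3 * se

    def test_same_seed_same_rates(self):
        tree = random_tree(6, seed=8, depth=5.0)
        r1 = synthgen.simulate_gbm_rates(tree, GBMRateParams(1e-3, 0.02), 13,
                                         set_lengths=False)
        r2 = synthgen.simulate_gbm_rates(tree, GBMRateParams(1e-3, 0.02), 13,
                                         set_lengths=False)
        assert np.array_equal(r1, r2)


class TestAlignmentSimulation:
    def test_zero_lengths_give_constant_columns(self):
        tree = random_tree(5, seed=1, depth=1.0)
        for nd in tree:
            if nd.edge.length is not None:
                nd.edge.length = 0.0
        aln = synthgen.simulate_alignment(
            tree, {"codon1": SubstModelParams()}, {"codon1": 50}, 3)
        assert all(len(set(aln.matrix[:, j])) == 1 for j in range(aln.n_sites))

    def test_stationary_frequencies_recovered(self):
        tree = random_tree(40, seed=6, depth=1.0)
        pi = np.array([0.4, 0.1, 0.2, 0.3])
        aln = synthgen.simulate_alignment(
            tree, {"rRNA": SubstModelParams(pi=pi, alpha=1.0)}, {"rRNA": 2000}, 11)
        freqs = aln.empirical_base_frequencies()
        assert np.abs(freqs - pi).max() < 0.03

    def test_smaller_alpha_gives_more_heterogeneous_sites(self):
        tree = random_tree(20, seed=9, depth=0.4)
        models = {"codon1": SubstModelParams(alpha=0.15),
                  "codon2": SubstModelParams(alpha=8.0)}
        aln = synthgen.simulate_alignment(tree, models,
                                          {"codon1": 1500, "codon2": 1500}, 21)

        def diversity_variance(label):
            sub = aln.matrix[:, aln.sites_where(label)]
            k = np.array([len(set(sub[:, j])) for j in range(sub.shape[1])])
            return k.var()

        assert diversity_variance("codon1") > diversity_variance("codon2")

    def test_zero_length_partition_rejected(self):
        tree = random_tree(4, seed=3, depth=1.0)
        with pytest.raises(ValueError):
            synthgen.simulate_alignment(tree, {"tRNA": SubstModelParams()},
                                        {"tRNA": 0}, 1)

    def test_missing_blocks_are_contiguous(self):
        tree = random_tree(10, seed=4, depth=0.5)
        aln = synthgen.simulate_alignment(
            tree, {"rRNA": SubstModelParams()}, {"rRNA": 400}, 2)
        blanked = synthgen.inject_missing_blocks(aln, taxa_fraction=0.3,
                                                 block_fraction=0.2, seed=5)
        affected = 0
        for row in blanked.matrix:
            idx = np.flatnonzero(row == "?")
            if len(idx):
                affected += 1
                assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
                assert len(idx) == 80
        assert affected == 3


class TestMkTraitSimulation:
    def test_rate_zero_shares_root_state(self):
        tree = random_tree(12, seed=7, depth=5.0)
        trait = synthgen.simulate_mk_trait(tree, k=4, q=0.0, seed=1)
        assert trait.nunique() == 1

    def test_saturation_approaches_uniform_states(self):
        counts = np.zeros(4)
        for seed in range(150):
            tree = random_tree(8, seed=30, depth=5.0)
            trait = synthgen.simulate_mk_trait(tree, k=4, q=50.0, seed=seed)
            counts += np.bincount(trait.values, minlength=4)
        freqs = counts / counts.sum()
        assert np.abs(freqs - 0.25).max() < 0.03


class TestDatasetRoundTrip:
    def test_written_dataset_reloads_exactly(self, small_dataset, tmp_path):
        synthgen.write_dataset(small_dataset, tmp_path)
        back = load_partitioned_alignment(tmp_path / "alignment.fasta",
                                          tmp_path / "partitions.tsv")
        assert back.taxa == small_dataset.alignment.taxa
        assert np.array_equal(back.matrix, small_dataset.alignment.matrix)
        assert list(back.partition_of_site) == list(
            small_dataset.alignment.partition_of_site)
        truth = (tmp_path / "truth.json").read_text()
        assert f'"seed": {small_dataset.seed}' in truth
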