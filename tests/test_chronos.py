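import numpy as np
import pytest

from mitophylo import chronos, synthgen
from mitophylo.chronos import (CalibrationConstraint, ChainSettings,
                               ChronosPriors, InfeasibleConstraintsError,
                               derive_root_rate_prior, run_dating_mcmc,
                               two_step_date)
from mitophylo.phylolik import BranchEstimates
from mitophylo.treeio import parse_newick

from .conftest import surviving_bd_tree


def balanced_chronogram(root_age=40.0):
    tree = parse_newick("(((a:10,b:10):15,(c:12,d:12):13):15,(e:20,f:20):20);")
    from mitophylo.treeio import annotate_ages_from_lengths
    annotate_ages_from_lengths(tree)
    scale = root_age / tree.seed_node.age
    for nd in tree:
        nd.age *= scale
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return tree


def diag_estimates(tree, rate=1e-3, rel_sd=0.05, seed=0, noise=True):
    """Observed branch lengths = clock expectation (+ optional MVN noise)."""
    rng = np.random.default_rng(seed)
    lengths, clades, var = [], [], []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        duration = nd.parent_node.age - nd.age
        mean = rate * duration
        sd = rel_sd * mean + 1e-5
        lengths.append(mean + (rng.normal(0, sd) if noise else 0.0))
        var.append(sd ** 2)
        clades.append(tuple(sorted(lf.taxon.label for lf in nd.leaf_iter())))
    return BranchEstimates(lengths=np.array(lengths), covariance=np.diag(var),
                           branch_clades=clades, log_likelihood=0.0)


def quick_settings(seed=0, burnin=600, n_samples=400, every=2):
    return ChainSettings(burnin=burnin, n_samples=n_samples,
                         sample_every=every, seed=seed)


class TestPackagedCalibrationTable:
    def test_thirty_one_bounds_all_consistent(self):
        from mitophylo.divrate import packaged_table

        table = packaged_table("calibration_constraints")
        n_bounds = table["lower_myr"].notna().sum() + table["upper_myr"].notna().sum()
        assert n_bounds == 31
        assert table["node"].nunique() == 25
        both = table.dropna(subset=["lower_myr", "upper_myr"])
        assert (both["lower_myr"] <= both["upper_myr"]).all()
        # the deepest calibration is the bony-fish root, capped at 472 Myr
        assert table["upper_myr"].max() == 472


class TestRootRatePrior:
    def test_equal_paths(self):
        tree = parse_newick("((a:0.21,b:0.21):0.21,(c:0.21,d:0.21):0.21);")
        rtrate, rtratesd = derive_root_rate_prior(tree, 4.2)
        assert rtrate == pytest.approx(0.1)
        assert rtratesd == pytest.approx(0.1)

    def test_mean_of_unequal_paths_and_linearity(self):
        tree = parse_newick("(a:0.40,b:0.44);")
        rtrate, _ = derive_root_rate_prior(tree, 4.2)
        assert rtrate == pytest.approx(0.1)
        for nd in tree:
            if nd.edge.length is not None:
                nd.edge.length *= 2
        doubled, _ = derive_root_rate_prior(tree, 4.2)
        assert doubled == pytest.approx(0.2)

    def test_unrooted_tree_rejected(self):
        tree = parse_newick("(a:1,b:1,c:1);", rooted=False)
        with pytest.raises(ValueError):
            derive_root_rate_prior(tree, 4.2)


class TestConstraints:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            CalibrationConstraint(taxa=("a", "b"))
        with pytest.raises(ValueError):
            CalibrationConstraint(taxa=("a", "b"), lower=10, upper=5)

    def test_infeasible_set_diagnosed(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree)
        cons = [CalibrationConstraint(taxa=("a", "b"), lower=50.0),
                CalibrationConstraint(taxa=("a", "b", "c", "d"), upper=30.0)]
        with pytest.raises(InfeasibleConstraintsError):
            run_dating_mcmc(tree, [est], cons, ChronosPriors(),
                            quick_settings())

    def test_fixed_age_is_exact_in_every_sample(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree)
        cons = [CalibrationConstraint(taxa=("a", "b"), lower=12.0, upper=12.0),
                CalibrationConstraint(taxa=tuple("abcdef"), lower=25, upper=60)]
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        post = run_dating_mcmc(tree, [est], cons, priors, quick_settings())
        col = [i for i, c in enumerate(post.internal_clades) if c == ("a", "b")][0]
        assert np.all(post.ages[:, col] == 12.0)
        assert post.all_samples_within_bounds()

    def test_every_sample_respects_bounds(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree, seed=3)
        cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=30, upper=55),
                CalibrationConstraint(taxa=("a", "b"), lower=5, upper=15)]
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        post = run_dating_mcmc(tree, [est], cons, priors, quick_settings(seed=5))
        assert post.all_samples_within_bounds()


class TestChainBehaviour:
    def test_deterministic_for_fixed_seed(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree, seed=1)
        cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=30, upper=55)]
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        p1 = run_dating_mcmc(tree, [est], cons, priors, quick_settings(seed=7))
        p2 = run_dating_mcmc(tree, [est], cons, priors, quick_settings(seed=7))
        assert np.array_equal(p1.ages, p2.ages)

    def test_fast_and_generic_paths_agree_exactly(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree, seed=2)
        cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=30, upper=55)]
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        fast = run_dating_mcmc(tree, [est], cons, priors, quick_settings(seed=9))
        slow = run_dating_mcmc(tree, [est], cons, priors, quick_settings(seed=9),
                               force_generic=True)
        assert np.allclose(fast.ages, slow.ages, rtol=1e-9)

    def test_prior_only_recovers_root_age_prior_mean(self):
        tree = balanced_chronogram()
        priors = ChronosPriors(rttm=50, rttmsd=10, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        post = run_dating_mcmc(tree, [diag_estimates(tree)], [], priors,
                               quick_settings(burnin=2000, n_samples=1500, every=3),
                               use_likelihood=False)
        root_col = int(np.argmax([len(c) for c in post.internal_clades]))
        assert post.ages[:, root_col].mean() == pytest.approx(50.0, rel=0.10)

    def test_posterior_age_monotone_in_lower_bound(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree, rel_sd=0.2, seed=4)
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        means = []
        for lower in (20.0, 45.0):
            cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=lower,
                                          upper=80.0)]
            post = run_dating_mcmc(tree, [est], cons, priors,
                                   quick_settings(seed=11))
            root_col = int(np.argmax([len(c) for c in post.internal_clades]))
            means.append(post.ages[:, root_col].mean())
        assert means[1] >= means[0]

    def test_strict_clock_recovery_within_ten_percent(self):
        """Near-clock data with generous bounds: posterior means of node
        ages land within 10% of the truth."""
        tree = balanced_chronogram(root_age=40.0)
        est = diag_estimates(tree, rate=1e-3, rel_sd=0.03, seed=6)
        cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=35, upper=45)]
        priors = ChronosPriors(rttm=40, rttmsd=20, rtrate=1e-3, rtratesd=5e-4,
                               brownmean=1e-5, brownsd=1e-5)
        post = run_dating_mcmc(tree, [est], cons, priors,
                               quick_settings(burnin=1500, n_samples=800))
        truth = {tuple(sorted(lf.taxon.label for lf in nd.leaf_iter())): nd.age
                 for nd in tree.postorder_internal_node_iter()}
        for clade, mean in zip(post.internal_clades, post.ages.mean(axis=0)):
            assert mean == pytest.approx(truth[clade], rel=0.10)


class TestTwoStepDating:
    def test_end_to_end_on_simulated_partitions(self):
        bd = synthgen.BirthDeathParams(b=0.06, d=0.0, t_max=300.0, n_target=6)
        tree = surviving_bd_tree(bd, 33)
        synthgen.simulate_gbm_rates(tree, synthgen.GBMRateParams(2e-3, 1e-5), 34)
        models = {k: v for k, v in synthgen.default_models().items()}
        aln = synthgen.simulate_alignment(
            tree, models,
            {"codon1": 300, "codon2": 300, "codon3": 300, "rRNA": 200, "tRNA": 100},
            35)
        root_age = tree.seed_node.age
        cons = [chronos.CalibrationConstraint(
            taxa=tuple(lf.taxon.label for lf in tree.leaf_node_iter()),
            lower=0.6 * root_age, upper=1.5 * root_age)]
        priors = ChronosPriors(rttm=root_age, rttmsd=root_age)
        post = two_step_date(aln, tree, cons, priors=priors,
                             settings=quick_settings(burnin=300, n_samples=200,
                                                     every=1))
        assert post.rhat_root_age is not None
        assert post.ages.shape[0] == 200
        assert post.all_samples_within_bounds()
        # third positions are excluded from the dating alignment
        from mitophylo.seqprep import DatasetVariant, ry_recode
        dating = ry_recode(aln, DatasetVariant("12nRTn"))
        assert dating.n_sites == aln.n_sites - 300

    def test_replicate_chains_agree_on_root_age(self):
        tree = balanced_chronogram()
        est = diag_estimates(tree, rel_sd=0.05, seed=8)
        cons = [CalibrationConstraint(taxa=tuple("abcdef"), lower=30, upper=55)]
        priors = ChronosPriors(rttm=40, rttmsd=40, rtrate=1e-3, rtratesd=1e-3,
                               brownmean=1e-4, brownsd=1e-4)
        root_means, root_ses = [], []
        for seed in (21, 22):
            post = run_dating_mcmc(tree, [est], cons, priors,
                                   quick_settings(seed=seed, burnin=1500,
                                                  n_samples=800))
            root_col = int(np.argmax([len(c) for c in post.internal_clades]))
            samples = post.ages[:, root_col]
            root_means.append(samples.mean())
            # effective-sample-size-deflated Monte-Carlo error (lag-1 AR)
            rho = np.corrcoef(samples[:-1], samples[1:])[0, 1]
            ess = len(samples) * max((1 - rho) / (1 + rho), 0.01)
            root_ses.append(samples.std(ddof=1) / np.sqrt(ess))
        diff = abs(root_means[0] - root_means[1])
        assert diff < 4 * np.hypot(*root_ses)
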