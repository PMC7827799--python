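import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from conservscape.conservation_core import (
    assign_grades,
    build_nj_tree,
    discretize_gamma,
    distance_matrix,
    estimate_alpha,
    kimura_protein_distance,
    nj_tree,
    normalize_scores,
    posterior_mean_rates,
    site_log_likelihood,
)
from conservscape.io_formats import Alignment, tree_from_newick
from conservscape.seqsim import SimulationConfig, simulate_alignment, simulate_tree

from oracles import enumeration_log_likelihood, random_additive_matrix


class TestDistancesAndNJ:
    def test_two_taxa_single_edge(self):
        aln = Alignment.from_pairs([("a", "MKVLW"), ("b", "MKALW")])
        tree = build_nj_tree(aln)
        d = kimura_protein_distance("MKVLW", "MKALW")
        assert math.isclose(sum(tree.branch_lengths()), d, rel_tol=1e-9)

    def test_identical_sequences_star_of_zeros(self):
        aln = Alignment.from_pairs([(f"s{i}", "MKVLW") for i in range(4)])
        tree = build_nj_tree(aln)
        assert all(t == 0.0 for t in tree.branch_lengths())

    def test_no_shared_columns_names_pair(self):
        aln = Alignment.from_pairs([("a", "MK--"), ("b", "--VL")])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            distance_matrix(aln)

    def test_saturated_distance_capped(self):
        with pytest.warns(UserWarning, match="capping"):
            d = kimura_protein_distance("MKVLWARNDC", "ARNDCMKVLW")
        assert d == 5.2

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        """NJ must return the generating tree metric for additive distances."""
        rng = np.random.default_rng(11)
        D, ids = random_additive_matrix(rng, n_taxa)
        tree = nj_tree(D, ids)
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert math.isclose(
                        pdm.distance(taxa[a], taxa[b]), D[i, j], abs_tol=1e-9
                    )


class TestDiscreteGamma:
    def test_single_category_is_one(self):
        assert discretize_gamma(0.7, 1).rates.tolist() == [1.0]

    @pytest.mark.parametrize("alpha,K", [(0.2, 4), (0.5, 16), (1.0, 4), (3.0, 8)])
    def test_mean_one(self, alpha, K):
        prior = discretize_gamma(alpha, K)
        assert abs(prior.rates.mean() - 1.0) < 1e-9
        assert np.all(np.diff(prior.rates) > 0)

    def test_category_means_match_quadrature(self):
        """alpha=1 quartile means vs direct numerical integration."""
        prior = discretize_gamma(1.0, 4)
        dist = gamma_dist(a=1.0, scale=1.0)
        edges = dist.ppf([0.0, 0.25, 0.5, 0.75, 1.0])
        edges[-1] = 60.0  # effective infinity for the integrand
        for k in range(4):
            mean_k, _ = integrate.quad(lambda x: x * dist.pdf(x), edges[k], edges[k + 1])
            assert abs(prior.rates[k] - 4 * mean_k) < 1e-6

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discretize_gamma(-1.0, 4)


class TestPruningLikelihood:
    def test_single_leaf_gives_log_pi(self, model):
        tree = tree_from_newick("(a:0.0,b:0.3);")
        # a two-leaf tree where b is missing data reduces to log pi over leaf a
        ll = site_log_likelihood("M-", tree, model, 1.0, leaf_order=("a", "b"))
        assert math.isclose(ll, math.log(model.pi[12]), abs_tol=1e-12)  # M index 12

    def test_matches_enumeration_on_random_instances(self, model):
        rng = np.random.default_rng(17)
        alphabet = "ARNDCQEGHILKMFPSTWYVX-"
        shapes = [
            "((a:{0},b:{1}):{2},(c:{3},d:{4}):{5});",
            "(a:{0},(b:{1},(c:{2},d:{3}):{4}):{5});",
            "((a:{0},b:{1}):{2},c:{3});",
            "(a:{0},b:{1});",
        ]
        for rep in range(20):
            shape = shapes[rep % len(shapes)]
            n_br = shape.count("{")
            tree = tree_from_newick(shape.format(*rng.uniform(0.02, 1.5, n_br)))
            n = tree.n_leaves
            col = "".join(rng.choice(list(alphabet), n))
            if all(ch in "X-" for ch in col):
                continue
            rate = float(rng.uniform(0.1, 4.0))
            ll = site_log_likelihood(col, tree, model, rate, leaf_order=tree.leaf_labels)
            oracle = enumeration_log_likelihood(tree, col, model, rate)
            assert abs(ll - oracle) < 1e-10

    def test_star_tree_zero_lengths_invariant_column(self, model):
        tree = tree_from_newick("(a:0,b:0,c:0,d:0);")
        for rate in (0.1, 1.0, 7.0):
            ll = site_log_likelihood("RRRR", tree, model, rate, leaf_order=tree.leaf_labels)
            assert math.isclose(ll, math.log(model.pi[1]), abs_tol=1e-12)  # R index 1

    def test_scale_consistency(self, model):
        """Multiplying branch lengths by c and dividing the rate by c is a no-op."""
        rng = np.random.default_rng(23)
        lengths = rng.uniform(0.05, 1.0, 6)
        col = "MKVL"
        for c in (0.25, 4.0):
            t1 = tree_from_newick(
                "((a:{},b:{}):{},(c:{},d:{}):{});".format(*lengths)
            )
            t2 = tree_from_newick(
                "((a:{},b:{}):{},(c:{},d:{}):{});".format(*(lengths * c))
            )
            l1 = site_log_likelihood(col, t1, model, 2.0, leaf_order=t1.leaf_labels)
            l2 = site_log_likelihood(col, t2, model, 2.0 / c, leaf_order=t2.leaf_labels)
            assert abs(l1 - l2) < 1e-10

    def test_duplicate_taxon_zero_branch_invariance(self, model):
        """Identical duplicates on zero-length branches leave rates unchanged."""
        config = SimulationConfig(n_taxa=8, site_blocks=((30, 1.0),), seed=9)
        tree = simulate_tree(8, seed=9)
        aln, _ = simulate_alignment(tree, config, model=model)
        prior = discretize_gamma(1.0, 4)
        r1, _ = posterior_mean_rates(aln, tree, model, prior)
        # replace leaf t1 with a zero-length polytomy of three identical copies
        import re

        m = re.search(r"t1:([0-9.]+)", tree.newick())
        newick = tree.newick().replace(
            f"t1:{m.group(1)}", f"(t1:0.0,dupA:0.0,dupB:0.0):{m.group(1)}"
        )
        tree2 = tree_from_newick(newick)
        seq = aln.sequence("t1")
        aln2 = Alignment(aln.records + (("dupA", seq), ("dupB", seq)))
        r2, _ = posterior_mean_rates(aln2, tree2, model, prior)
        assert np.abs(r1 - r2).max() < 1e-8


class TestAlphaEstimation:
    def test_recovers_simulation_shape(self, gamma_dataset, model):
        alignment, tree, _clades, _truth = gamma_dataset
        alpha_hat = estimate_alpha(alignment, tree, model, K=16)
        assert 0.3 <= alpha_hat <= 0.8

    def test_invariant_alignment_hits_lower_bound(self, model):
        aln = Alignment.from_pairs([(f"t{i+1}", "MKVLWARN") for i in range(4)])
        tree = tree_from_newick("((t1:0.1,t2:0.1):0.1,(t3:0.1,t4:0.1):0.1);")
        with pytest.warns(UserWarning, match="lower search bound"):
            alpha_hat = estimate_alpha(aln, tree, model, K=4)
        assert alpha_hat <= 0.06

    def test_optimum_beats_bracket_ends(self, model):
        config = SimulationConfig(
            n_taxa=10, site_blocks=None, alpha_true=0.8, n_sites=60, seed=13
        )
        tree = simulate_tree(10, seed=13)
        aln, _ = simulate_alignment(tree, config, model=model)
        from conservscape.conservation_core import _loglik_matrix
        from scipy.special import logsumexp

        def objective(alpha):
            prior = discretize_gamma(alpha, 4)
            ll = _loglik_matrix(aln, tree, model, prior.rates)
            return float(np.sum(logsumexp(ll, axis=1) - math.log(4)))

        alpha_hat = estimate_alpha(aln, tree, model, K=4)
        assert objective(alpha_hat) >= objective(0.05) - 1e-9
        assert objective(alpha_hat) >= objective(10.0) - 1e-9


class TestPosteriorRates:
    def test_single_category_returns_prior_rate(self, model):
        aln = Alignment.from_pairs([("t1", "MKV"), ("t2", "MAV")])
        tree = tree_from_newick("(t1:0.1,t2:0.1);")
        prior = discretize_gamma(0.5, 1)
        rates, _ = posterior_mean_rates(aln, tree, model, prior)
        assert np.allclose(rates, 1.0)

    def test_star_tree_no_information_returns_prior_mean(self, model):
        aln = Alignment.from_pairs([("a", "MKV"), ("b", "AWC"), ("c", "RND")])
        tree = tree_from_newick("(a:0,b:0,c:0);")
        prior = discretize_gamma(0.7, 8)
        rates, _ = posterior_mean_rates(aln, tree, model, prior)
        assert np.abs(rates - 1.0).max() < 1e-9

    def test_two_taxon_closed_form(self, model):
        """K=2 posterior mean equals the hand-written two-term Bayes quotient."""
        aln = Alignment.from_pairs([("a", "M"), ("b", "V")])
        t_total = 0.4
        tree = tree_from_newick("(a:0.2,b:0.2);")
        prior = discretize_gamma(0.8, 2)
        rates, _ = posterior_mean_rates(aln, tree, model, prior)
        i_m, i_v = 12, 19
        likes = [
            model.pi[i_m] * model.transition_matrix(t_total * r)[i_m, i_v]
            for r in prior.rates
        ]
        expected = sum(r * l for r, l in zip(prior.rates, likes)) / sum(likes)
        assert abs(rates[0] - expected) < 1e-10

    def test_all_gap_column_flagged_with_prior_mean(self, model):
        aln = Alignment.from_pairs([("a", "M-"), ("b", "V-")])
        tree = tree_from_newick("(a:0.2,b:0.2);")
        rates, all_gap = posterior_mean_rates(aln, tree, model, discretize_gamma(1.0, 4))
        assert all_gap.tolist() == [False, True]
        assert rates[1] == 1.0


class TestNormalizationAndGrades:
    def test_direct_arithmetic(self):
        s = normalize_scores(np.array([0.5, 1.0, 1.5]))
        assert np.allclose(s, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_scores(np.array([1.0, 1.0, 1.0]))

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([1.0]))

    def test_extremes_get_extreme_grades(self):
        s = np.linspace(-2, 2, 40)
        g = assign_grades(s)
        assert g[np.argmin(s)] == 9
        assert g[np.argmax(s)] == 1

    def test_nine_distinct_scores_are_a_permutation(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=9)
        assert sorted(assign_grades(s)) == list(range(1, 10))

    def test_ties_take_conserved_side(self):
        s = np.array([0.0] * 9 + [5.0] * 9)
        g = assign_grades(s)
        assert set(g[:9]) == {9}


class TestScoringPipeline:
    def test_normalization_contract_on_study_fixture(self, two_rate_scores):
        s = two_rate_scores.scores
        assert abs(s.mean()) < 1e-9
        assert abs(s.std() - 1.0) < 1e-9

    def test_low_rate_sites_more_conserved(self, two_rate_dataset, two_rate_scores):
        _aln, _tree, _clades, truth = two_rate_dataset
        cons = truth.rates < 1.0
        assert two_rate_scores.scores[cons].mean() < two_rate_scores.scores[~cons].mean()
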