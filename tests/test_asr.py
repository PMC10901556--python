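import numpy as np
import pytest

from p53evo.asr import (
    Alignment,
    AlignmentError,
    AncestralPosterior,
    _call_from_probs,
    aicc,
    akaike_weights,
    bic,
    call_sequences,
    fit_model_parameters,
    log_likelihood,
    marginal_posteriors,
)
from p53evo.evo_models import AMINO_ACIDS, jtt_model
from p53evo.phylo import TimeTree, TreeNode, parse_newick
from p53evo.synthetic_data import random_chronogram, simulate_alignment

from _oracles import enumeration_likelihood_and_posteriors


class TestLikelihood:
    def test_single_leaf_closed_form(self, jtt_gi):
        tree = TimeTree(TreeNode(label="A"))
        aln = Alignment(["A"], ["W"])
        total, per_site = log_likelihood(tree, aln, jtt_gi)
        expected = np.log(jtt_gi.frequencies[AMINO_ACIDS.index("W")])
        assert total == pytest.approx(expected, abs=1e-12)

    def test_all_gap_taxon_is_neutral(self, jtt_gi):
        t3 = parse_newick("((A:0.3,B:0.5):0.2,C:0.4);")
        aln3 = Alignment(["A", "B", "C"], ["AC", "CW", "AA"])
        ll3, _ = log_likelihood(t3, aln3, jtt_gi)
        t4 = parse_newick("(((A:0.3,B:0.5):0.2,C:0.4):0.1,GAPPY:0.9);")
        aln4 = Alignment(["A", "B", "C", "GAPPY"], ["AC", "CW", "AA", "--"])
        ll4, _ = log_likelihood(t4, aln4, jtt_gi)
        assert ll4 == pytest.approx(ll3, abs=1e-9)

    def test_matches_enumeration_oracle(
        self, quartet_tree, quartet_alignment, jtt_gi
    ):
        total, per_site = log_likelihood(quartet_tree, quartet_alignment, jtt_gi)
        oracle_liks, _, _ = enumeration_likelihood_and_posteriors(
            quartet_tree, quartet_alignment, jtt_gi
        )
        assert np.abs(np.log(oracle_liks) - per_site).max() < 1e-9

    def test_label_mismatch_rejected(self, quartet_tree, jtt_gi):
        aln = Alignment(["A", "B", "C", "Z"], ["A", "A", "A", "A"])
        with pytest.raises(AlignmentError):
            log_likelihood(quartet_tree, aln, jtt_gi)

    def test_invariant_to_root_placement(self, jtt_gi):
        # same unrooted tree (A-X = 1, B-X = 1, C-X = 2), three rootings
        aln = Alignment(["A", "B", "C"], ["AW", "AC", "GW"])
        rootings = [
            "(A:1,B:1,C:2);",
            "((B:1,C:2):0.3,A:0.7);",
            "((A:1,B:1):1.5,C:0.5);",
        ]
        lls = [log_likelihood(parse_newick(n), aln, jtt_gi)[0] for n in rootings]
        assert max(lls) - min(lls) < 1e-9


class TestMarginalPosteriors:
    def test_matches_enumeration_oracle(
        self, quartet_tree, quartet_alignment, jtt_gi
    ):
        post = marginal_posteriors(quartet_tree, quartet_alignment, jtt_gi)
        _, oracle_ids, oracle_post = enumeration_likelihood_and_posteriors(
            quartet_tree, quartet_alignment, jtt_gi
        )
        order = [post.node_ids.index(i) for i in oracle_ids]
        assert np.abs(post.probabilities[order] - oracle_post).max() < 1e-8

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_on_random_five_taxon_trees(self, seed, jtt_gi5):
        tree = random_chronogram(5, height=300.0, seed=seed)
        aln, _ = simulate_alignment(tree, jtt_gi5, 2, seed=seed, branch_scale=0.002)
        post = marginal_posteriors(tree, aln, jtt_gi5, branch_scale=0.002)
        _, oracle_ids, oracle_post = enumeration_likelihood_and_posteriors(
            tree, aln, jtt_gi5, branch_scale=0.002
        )
        order = [post.node_ids.index(i) for i in oracle_ids]
        assert np.abs(post.probabilities[order] - oracle_post).max() < 1e-8

    def test_posteriors_sum_to_one(self, quartet_tree, quartet_alignment, jtt_gi):
        post = marginal_posteriors(quartet_tree, quartet_alignment, jtt_gi)
        assert np.abs(post.probabilities.sum(axis=2) - 1.0).max() < 1e-10

    def test_zero_length_branch_pins_posterior(self, jtt_gi):
        tree = parse_newick("((A:0.0,B:0.7):0.3,C:0.9);")
        aln = Alignment(["A", "B", "C"], ["W", "C", "A"])
        post = marginal_posteriors(tree, aln, jtt_gi)
        # ids are assigned in postorder above the leaf count: the (A,B)
        # ancestor gets id 4; its zero-length branch to A pins the call
        vec = post.site_posterior(4, 1)
        assert vec[AMINO_ACIDS.index("W")] == pytest.approx(1.0, abs=1e-9)


class TestSequenceCalls:
    def _posterior(self, vectors):
        probs = np.array(vectors)[None, :, :]
        return AncestralPosterior(
            node_ids=[9], probabilities=probs, site_logliks=np.zeros(len(vectors))
        )

    def _vec(self, **mass):
        v = np.zeros(20)
        for aa, p in mass.items():
            v[AMINO_ACIDS.index(aa)] = p
        v[AMINO_ACIDS.index("G")] += 1.0 - v.sum()  # filler mass
        return v

    def test_confident_site_keeps_ml(self):
        post = self._posterior([self._vec(V=0.95, I=0.05)])
        ml, alt = call_sequences(post)[9]
        assert ml == alt == "V"

    def test_ambiguous_site_swaps_to_runner_up(self):
        post = self._posterior([self._vec(V=0.85, I=0.12)])
        ml, alt = call_sequences(post)[9]
        assert (ml, alt) == ("V", "I")

    def test_weak_runner_up_keeps_ml(self):
        post = self._posterior([self._vec(V=0.89, I=0.08)])
        ml, alt = call_sequences(post)[9]
        assert ml == "V" and alt == "V"

    def test_ties_break_alphabetically(self):
        v = np.zeros(20)
        v[AMINO_ACIDS.index("L")] = 0.5
        v[AMINO_ACIDS.index("A")] = 0.5
        ml, alt = _call_from_probs(v[None, :], 0.9, 0.1)
        assert ml == "A" and alt == "L"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_altall_differs_exactly_at_rule_sites(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.full(20, 0.15), size=60)
        post = AncestralPosterior(
            node_ids=[1],
            probabilities=probs[None, :, :],
            site_logliks=np.zeros(60),
        )
        ml, alt = call_sequences(post)[1]
        srt = np.sort(probs, axis=1)
        expected = set(np.where((srt[:, -1] < 0.90) & (srt[:, -2] >= 0.10))[0])
        observed = {i for i, (a, b) in enumerate(zip(ml, alt)) if a != b}
        assert observed == expected


@pytest.fixture(scope="module")
def small_sim():
    tree = random_chronogram(12, height=400.0, seed=9)
    model = jtt_model(gamma_shape=1.0, p_invariant=0.1, n_categories=3)
    aln, _ = simulate_alignment(tree, model, 300, seed=9, branch_scale=0.002)
    return tree, model, aln


class TestParameterFitting:
    def test_fit_beats_start_and_is_idempotent(self, small_sim):
        tree, model, aln = small_sim
        start_ll, _ = log_likelihood(tree, aln, model, branch_scale=0.002)
        fit = fit_model_parameters(tree, aln, model)
        assert fit.log_likelihood >= start_ll - 1e-9
        refit = fit_model_parameters(
            tree, aln, fit.model, branch_scale=fit.branch_scale
        )
        assert refit.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-4)

    def test_trace_monotone_nondecreasing(self, small_sim):
        tree, model, aln = small_sim
        fit = fit_model_parameters(tree, aln, model)
        assert all(b >= a for a, b in zip(fit.trace, fit.trace[1:]))

    def test_local_optimum_under_perturbation(self, small_sim):
        tree, model, aln = small_sim
        fit = fit_model_parameters(tree, aln, model)
        base = fit.log_likelihood
        for factor in (0.97, 1.03):
            perturbed = fit.model.with_params(gamma_shape=fit.model.gamma_shape * factor)
            ll, _ = log_likelihood(tree, aln, perturbed, branch_scale=fit.branch_scale)
            assert ll <= base + 1e-6

    def test_constant_alignment_warns(self):
        tree = parse_newick("((A:10,B:10):10,C:20);")
        aln = Alignment(["A", "B", "C"], ["AAA", "AAA", "AAA"])
        model = jtt_model(gamma_shape=1.0, p_invariant=0.1, n_categories=2)
        with pytest.warns(UserWarning, match="not.*identifiable|identifiable"):
            fit_model_parameters(tree, aln, model)

    def test_per_branch_mode_improves_or_matches(self):
        tree = random_chronogram(5, height=200.0, seed=4)
        model = jtt_model(gamma_shape=1.0, n_categories=2)
        aln, _ = simulate_alignment(tree, model, 120, seed=4, branch_scale=0.003)
        fit_scale = fit_model_parameters(tree, aln, model, optimize=("branch_scale",))
        fit_bl = fit_model_parameters(
            tree, aln, model, optimize=("branch_scale",), branch_mode="per_branch",
            n_branch_sweeps=1,
        )
        assert fit_bl.log_likelihood >= fit_scale.log_likelihood - 1e-6
        assert fit_bl.branch_lengths is not None


class TestModelSelectionArithmetic:
    def test_aicc_hand_value(self):
        # -2(-3000) + 2*10 + 2*10*11/489
        assert aicc(-3000.0, 10, 500) == pytest.approx(6020.449897750511, abs=1e-9)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_bic_value(self):
        assert bic(-3000.0, 10, 500) == pytest.approx(6000 + 10 * np.log(500))

    def test_single_candidate_weight_one(self):
        assert akaike_weights([123.4])[0] == pytest.approx(1.0)

    def test_equal_aicc_splits_evenly(self):
        w = akaike_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_weights_sum_to_one(self):
        w = akaike_weights([100.0, 101.0, 105.0, np.nan])
        assert np.nansum(w) == pytest.approx(1.0, abs=1e-10)
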