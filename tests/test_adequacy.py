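"""Posterior predictive machinery: tail areas, stochastic substitution
mappings (forward and endpoint-conditioned) and the homoplasy statistic."""

import numpy as np
import pytest
from scipy.integrate import quad

import phylopp as pp
from phylopp.adequacy import (SubstitutionMapping, _bridge_branch, mean_homoplasy,
                              tail_area)
from phylopp.mcmc import ChainConfig, PosteriorSample, run_chain
from phylopp.models import build_rate_matrix, load_matrix, poisson_matrix
from phylopp.tree import balanced_tree


def _samples_for(tree, model, n=25):
    return [PosteriorSample(generation=i, tree=tree, model=model, alpha=1.0,
                            log_likelihood=0.0, log_prior=0.0) for i in range(n)]


class TestTailArea:
    def test_observed_at_median_p_near_one(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=200)
        assert tail_area(float(np.median(pred)), pred) >= 0.9

    def test_observed_beyond_all_p_bounded(self):
        pred = np.arange(1000, dtype=float)
        assert tail_area(2000.0, pred) <= 0.002
        assert tail_area(-5.0, pred) <= 0.002

    def test_identical_distributions_self_test(self):
        pred = np.arange(100, dtype=float)
        assert tail_area(float(pred.mean()), pred) == pytest.approx(1.0, abs=0.02)


class TestPosteriorPredictive:
    def test_min_sample_floor_enforced(self, quartet, lg_model, sim_aln):
        samples = _samples_for(quartet, lg_model, n=5)
        with pytest.raises(ValueError, match="at least 20"):
            pp.posterior_predictive(samples, sim_aln, "composition_chisq")

    def test_unknown_statistic_rejected(self, quartet, lg_model, sim_aln):
        with pytest.raises(ValueError, match="composition_chisq"):
            pp.posterior_predictive(_samples_for(quartet, lg_model), sim_aln, "zeta")

    def test_matched_parameters_fit(self, lg_model):
        # predicted replicates generated from the very parameters that
        # produced the data: observed must sit inside the central mass
        tree = balanced_tree(8, 0.15)
        aln = pp.simulate_alignment(tree, lg_model, 200, seed=3)
        samples = _samples_for(tree, lg_model, n=40)
        res = pp.posterior_predictive(samples, aln, "composition_chisq", seed=9)
        assert res.verdict == "fit"
        assert res.predicted.shape == (40,)

    def test_deterministic_given_seed(self, quartet, lg_model, sim_aln):
        samples = _samples_for(quartet, lg_model)
        a = pp.posterior_predictive(samples, sim_aln, "site_diversity", seed=4)
        b = pp.posterior_predictive(samples, sim_aln, "site_diversity", seed=4)
        assert (a.predicted == b.predicted).all() and a.p_value == b.p_value


class TestUnconstrainedMapping:
    def test_zero_length_tree_no_events(self, poisson_model):
        tree = pp.PhyloTree.from_newick("((a:0,b:0):0,c:0,d:0);")
        m = pp.map_unconstrained(tree, poisson_model, 50, seed=1)
        assert not m.events
        m.validate()

    def test_same_seed_identical_histories(self, quartet, lg_model):
        a = pp.map_unconstrained(quartet, lg_model, 40, seed=6)
        b = pp.map_unconstrained(quartet, lg_model, 40, seed=6)
        assert a.events == b.events
        assert (a.node_states == b.node_states).all()

    def test_mean_events_match_tree_length(self, lg_model):
        # unit mean rate: expected events/site equals total branch length
        tree = balanced_tree(6, 0.2)
        m = pp.map_unconstrained(tree, lg_model, 3000, seed=2)
        counts = np.array([m.events_at_site(s) for s in range(3000)])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - tree.total_length()) < 3 * se
        m.validate()


class TestConditionalMapping:
    def test_constant_site_short_branches_no_events(self, poisson_model):
        tree = pp.PhyloTree.from_newick(
            "((a:1e-6,b:1e-6):1e-6,c:1e-6,d:1e-6);")
        aln = pp.Alignment.from_sequences(list("abcd"), ["A"] * 4)
        zero = 0
        for seed in range(100):
            m = pp.map_conditional(tree, poisson_model, aln, seed)
            zero += not m.events
        assert zero >= 99

    def test_endpoint_consistency_invariant(self, lg_model):
        tree = balanced_tree(6, 0.3)
        aln = pp.simulate_alignment(tree, lg_model, 40, seed=8)
        m = pp.map_conditional(tree, lg_model, aln, 5)
        m.validate()  # exact chain consistency, by construction

    def test_missing_leaves_marginalized(self, quartet, lg_model):
        aln = pp.Alignment.from_sequences(
            ["t1", "t2", "t3", "t4"], ["A-", "AX", "AC", "AD"])
        m = pp.map_conditional(quartet, lg_model, aln, 3)
        m.validate()
        assert m.observed_leaf.sum() == 6  # two cells were missing

    def test_bridge_expected_events_two_state_oracle(self):
        # E[N | X_0=a, X_t=b] for a 2-state chain, by numerical integration:
        # E = sum_{i!=j} Q_ij int_0^t P_ai(s) P_jb(t-s) ds / P_ab(t)
        pi = np.array([0.3, 0.7])
        R = np.array([[0.0, 1.0], [1.0, 0.0]])
        rm = build_rate_matrix(R, pi)
        t, a, b = 0.8, 0, 0
        P = pp.transition_probabilities(rm, t)

        def P_at(s):
            return pp.transition_probabilities(rm, s)

        expect = 0.0
        for i in range(2):
            for j in range(2):
                if i == j:
                    continue
                val = quad(lambda s: P_at(s)[a, i] * P_at(t - s)[j, b], 0, t)[0]
                expect += rm.Q[i, j] * val
        expect /= P[a, b]
        rng = np.random.default_rng(12)
        draws = np.array([len(_bridge_branch(rm, a, b, t, rng))
                          for _ in range(4000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expect) < 3 * se


class TestHomoplasy:
    def _mapping_with(self, tree, leaf_states, events):
        n_nodes = max(n.id for n in tree.nodes) + 1
        states = np.zeros((n_nodes, 1), dtype=np.int64)
        for name, st in leaf_states.items():
            states[tree.leaf_map[name].id, 0] = st
        return SubstitutionMapping(tree, states, events, conditional=False,
                                   observed_leaf=np.ones((len(leaf_states), 1), bool))

    def test_constant_site_zero(self, quartet):
        m = self._mapping_with(quartet, dict.fromkeys(["t1", "t2", "t3", "t4"], 0), {})
        assert pp.homoplasy_per_site(m, 0) == 0

    def test_minimal_explanation_zero(self, quartet):
        # three distinct leaf states reached by exactly two events
        leaf = {"t1": 0, "t2": 1, "t3": 2, "t4": 0}
        internal = next(c for c in quartet.root.children if not c.is_leaf)
        ev = {
            (quartet.leaf_map["t2"].id, 0): [(0.05, 0, 1)],
            (quartet.leaf_map["t3"].id, 0): [(0.05, 0, 2)],
        }
        m = self._mapping_with(quartet, leaf, ev)
        assert pp.homoplasy_per_site(m, 0) == 0

    def test_extra_events_counted(self, quartet):
        # three distinct leaf states, five events -> homoplasy 3
        leaf = {"t1": 0, "t2": 1, "t3": 2, "t4": 0}
        ev = {
            (quartet.leaf_map["t2"].id, 0): [(0.01, 0, 2), (0.05, 2, 1)],
            (quartet.leaf_map["t3"].id, 0): [(0.05, 0, 2)],
            (quartet.leaf_map["t4"].id, 0): [(0.01, 0, 3), (0.09, 3, 0)],
        }
        m = self._mapping_with(quartet, leaf, ev)
        assert pp.homoplasy_per_site(m, 0) == 3

    def test_event_floor_property(self, lg_model):
        # any conditional mapping: events >= distinct leaf states - 1
        tree = balanced_tree(6, 0.4)
        aln = pp.simulate_alignment(tree, lg_model, 50, seed=21)
        m = pp.map_conditional(tree, lg_model, aln, 7)
        enc = aln.encode()
        for site in range(50):
            distinct = len(set(enc[:, site]))
            assert m.events_at_site(site) >= distinct - 1
            assert pp.homoplasy_per_site(m, site) >= 0

    def test_self_distribution_p_near_one(self):
        draws = np.linspace(0.5, 1.5, 60)
        res = pp.adequacy.HomoplasyResult(draws, draws, tail_area(draws.mean(), draws))
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.verdict == "fit"

    def test_homoplasy_test_end_to_end(self, poisson_model):
        tree = balanced_tree(6, 0.2)
        aln = pp.simulate_alignment(tree, poisson_model, 80, seed=2)
        samples = _samples_for(tree, poisson_model, n=20)
        res = pp.homoplasy_test(samples, aln, seed=3)
        assert res.p_value > 0.05  # matched model anticipates its own homoplasy
        assert res.observed_draws.shape == (20,)
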