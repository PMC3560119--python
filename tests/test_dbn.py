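"""DBN scoring, search, CPT fitting, discretization and inference."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from relapsekit.containers import TimeCourseTensor, ValidationError
from relapsekit.dbn import (AnnealSchedule, DbnModel, DbnScorer, DbnStructure,
                            InconsistentEvidenceError, ScoreConfig,
                            anneal_search, apply_discretization,
                            brute_force_marginal, discretize, family_score,
                            fit_cpts, fit_discretization, greedy_search,
                            infer, predict_relapse)
from relapsekit.synthgen import (GroundTruthDbn, default_ground_truth,
                                 generate_timecourse)


class TestFamilyScore:
    def test_bic_closed_form_no_parents(self):
        """Binary variable, counts (5,5): BIC = 10 log(1/2) - 0.5 log 10."""
        child = np.array([0, 1] * 5)
        parents = np.empty((10, 0), dtype=int)
        got = family_score(child, parents, (), 2, ScoreConfig(score="bic"))
        assert got == pytest.approx(10 * math.log(0.5) - 0.5 * math.log(10))

    def test_bde_single_observation_uniform_prior(self):
        """One observation, r=2, ess=1: marginal likelihood = 1/2."""
        child = np.array([1])
        parents = np.empty((1, 0), dtype=int)
        got = family_score(child, parents, (), 2, ScoreConfig(score="bde"))
        assert got == pytest.approx(math.log(0.5))

    def test_bde_two_observations_dirichlet_multinomial(self):
        # P(x1=0, x2=0) = (1/2) * (3/2 / 2) under Dirichlet(1/2, 1/2)
        child = np.array([0, 0])
        parents = np.empty((2, 0), dtype=int)
        got = family_score(child, parents, (), 2, ScoreConfig(score="bde"))
        expected = (gammaln(1) - gammaln(3)
                    + gammaln(0.5 + 2) - gammaln(0.5))
        assert got == pytest.approx(float(expected))

    def test_independent_parent_never_helps_bic_on_null_data(self):
        rng = np.random.default_rng(0)
        child = rng.integers(0, 2, 600)
        parent = rng.integers(0, 2, 600)[:, None]
        cfg = ScoreConfig(score="bic")
        without = family_score(child, np.empty((600, 0), dtype=int), (), 2, cfg)
        with_parent = family_score(child, parent, (2,), 2, cfg)
        assert with_parent < without

    def test_parent_cap_enforced(self):
        cfg = ScoreConfig(max_parents=1)
        with pytest.raises(ValidationError, match="max_parents"):
            family_score(np.zeros(4, dtype=int), np.zeros((4, 2), dtype=int),
                         (2, 2), 2, cfg)


class TestDiscretize:
    def _tc(self, values):
        values = np.asarray(values, dtype=float)
        return TimeCourseTensor(values,
                                [f"P{i}" for i in range(values.shape[0])],
                                [f"g{i}" for i in range(values.shape[1])],
                                tuple(f"t{i}" for i in range(values.shape[2])))

    def test_equal_frequency_thirds(self):
        tc = self._tc(np.arange(1.0, 10.0).reshape(1, 1, 9))
        states, cuts = discretize(tc, 3)
        assert states.ravel().tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_held_out_values_clamp_to_end_bins(self):
        train = self._tc(np.arange(1.0, 10.0).reshape(1, 1, 9))
        cuts = fit_discretization(train, 3)
        held = self._tc(np.array([[[-5.0, 50.0, 5.0, 5.0, 5.0, 5.0, 5.0,
                                    5.0, 5.0]]]))
        states = apply_discretization(held, cuts)
        assert states[0, 0, 0] == 0 and states[0, 0, 1] == 2

    def test_boundaries_deterministic(self):
        tc = self._tc(np.random.default_rng(1).normal(8, 1, (5, 2, 3)))
        a = fit_discretization(tc, 3)
        b = fit_discretization(tc, 3)
        for g in a:
            assert np.array_equal(a[g], b[g])

    def test_constant_gene_warns_single_bin(self):
        tc = self._tc(np.full((3, 1, 3), 8.0))
        with pytest.warns(UserWarning, match="constant"):
            states, cuts = discretize(tc, 3)
        assert (states == 0).all()


class TestFitCpts:
    def _structure(self):
        return DbnStructure(("x",), frozenset(), frozenset({("x", "x")}))

    def test_smoothing_arithmetic(self):
        """Transition counts (3,1) with pseudocount 1 give row (4/6, 2/6)."""
        # trajectories: 0->0 three times, 0->1 once
        states = np.array([[[0, 0]], [[0, 0]], [[0, 0]], [[0, 1]]])
        model = fit_cpts(self._structure(), states, ["x"], {"x": 2},
                         pseudocount=1.0)
        assert model.transition_cpts["x"][0] == pytest.approx([4 / 6, 2 / 6])

    def test_mle_without_smoothing(self):
        states = np.array([[[0, 0]]] * 5)
        model = fit_cpts(self._structure(), states, ["x"], {"x": 2},
                         pseudocount=0.0)
        assert model.transition_cpts["x"][0] == pytest.approx([1.0, 0.0])

    def test_unseen_parent_configuration_falls_back_to_uniform(self):
        states = np.array([[[0, 0]]] * 5)       # state 1 never observed
        model = fit_cpts(self._structure(), states, ["x"], {"x": 2},
                         pseudocount=0.0)
        assert model.transition_cpts["x"][1] == pytest.approx([0.5, 0.5])

    def test_cpt_rows_always_normalized(self):
        res = generate_timecourse(default_ground_truth(), 40, seed=0)
        truth = default_ground_truth()
        model = fit_cpts(truth.model.structure, res.states,
                         list(truth.variables), truth.model.cardinalities)
        for cpts in (model.initial_cpts, model.transition_cpts):
            for v, table in cpts.items():
                assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)


class TestStructure:
    def test_intra_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            DbnStructure(("a", "b"),
                         frozenset({("a", "b"), ("b", "a")}), frozenset())

    def test_edge_list_round_trip(self):
        s = DbnStructure(("a", "b"), frozenset({("a", "b")}),
                         frozenset({("b", "a"), ("a", "a")}))
        assert DbnStructure.from_lines(("a", "b"), s.to_lines()) == s


def _random_states(rng, n, n_vars, n_slices=2):
    return rng.integers(0, 2, size=(n, n_vars, n_slices))


class TestSearch:
    def test_null_data_yields_sparse_structure(self):
        rng = np.random.default_rng(0)
        states = _random_states(rng, 400, 4)
        variables = [f"v{i}" for i in range(4)]
        struct = greedy_search(states, variables, {v: 2 for v in variables},
                               ScoreConfig(seed=0), n_restarts=2)
        assert len(struct.intra_edges) + len(struct.inter_edges) <= 2

    def test_known_interslice_chain_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        states = _random_states(rng, n, 2, 2)
        # y at t+1 copies x at t with 5% flips
        states[:, 1, 1] = states[:, 0, 0] ^ (rng.random(n) < 0.05)
        variables = ["x", "y"]
        struct = greedy_search(states, variables, {"x": 2, "y": 2},
                               ScoreConfig(seed=0), n_restarts=2)
        assert ("x", "y") in struct.inter_edges

    def test_search_never_scores_below_empty_structure(self):
        rng = np.random.default_rng(2)
        states = _random_states(rng, 60, 3)
        variables = ["a", "b", "c"]
        cards = {v: 2 for v in variables}
        cfg = ScoreConfig(seed=0)
        scorer = DbnScorer(states, variables, cards, cfg)
        empty_score = scorer.structure_score(DbnStructure(tuple(variables)))
        for result in (greedy_search(states, variables, cards, cfg,
                                     scorer=scorer),
                       anneal_search(states, variables, cards, cfg,
                                     scorer=scorer)):
            assert scorer.structure_score(result) >= empty_score - 1e-9

    def test_anneal_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        states = _random_states(rng, 50, 3)
        variables = ["a", "b", "c"]
        cards = {v: 2 for v in variables}
        cfg = ScoreConfig(seed=5)
        sched = AnnealSchedule(seed=5)
        a = anneal_search(states, variables, cards, cfg, sched)
        b = anneal_search(states, variables, cards, cfg, sched)
        assert a == b

    def test_cold_anneal_acts_as_hill_climb(self):
        rng = np.random.default_rng(4)
        states = _random_states(rng, 50, 3)
        variables = ["a", "b", "c"]
        cards = {v: 2 for v in variables}
        cfg = ScoreConfig(seed=0)
        scorer = DbnScorer(states, variables, cards, cfg)
        sched = AnnealSchedule(t_initial=1e-6, t_min=1e-6, moves_per_temp=30,
                               seed=0)
        result = anneal_search(states, variables, cards, cfg, sched,
                               scorer=scorer)
        empty = scorer.structure_score(DbnStructure(tuple(variables)))
        assert scorer.structure_score(result) >= empty


def _chain_model():
    """Two-variable chain with hand-set CPTs for read-off checks."""
    structure = DbnStructure(("x",), frozenset(), frozenset({("x", "x")}))
    return DbnModel(structure, {"x": 2},
                    {"x": np.array([[0.6, 0.4]])},
                    {"x": np.array([[0.9, 0.1], [0.2, 0.8]])})


class TestInference:
    def test_transition_read_off_by_d_separation(self):
        model = _chain_model()
        post = infer(model, {("x", 0): 1}, ("x", 1), n_slices=2)
        assert post[1] == pytest.approx(0.8)

    def test_observed_query_is_point_mass(self):
        model = _chain_model()
        post = infer(model, {("x", 1): 0}, ("x", 1), n_slices=2)
        assert post.tolist() == [1.0, 0.0]

    def test_no_evidence_matches_enumeration(self):
        truth = default_ground_truth(n_genes=3)
        for query in (("relapse", 2), ("g1", 1)):
            a = infer(truth.model, {}, query, 3)
            b = brute_force_marginal(truth.model, {}, query, 3)
            assert np.allclose(a, b, atol=1e-12)

    def test_impossible_evidence_raises(self):
        structure = DbnStructure(("x",), frozenset(), frozenset({("x", "x")}))
        model = DbnModel(structure, {"x": 2},
                         {"x": np.array([[1.0, 0.0]])},
                         {"x": np.array([[1.0, 0.0], [0.0, 1.0]])})
        with pytest.raises(InconsistentEvidenceError):
            infer(model, {("x", 0): 1}, ("x", 1), n_slices=2)


class TestPredictRelapse:
    def _absorbing_model(self, p_relapse=0.3):
        structure = DbnStructure(("relapse",), frozenset(),
                                 frozenset({("relapse", "relapse")}))
        return DbnModel(structure, {"relapse": 2},
                        {"relapse": np.array([[0.9, 0.1]])},
                        {"relapse": np.array([[1 - p_relapse, p_relapse],
                                              [0.0, 1.0]])})

    def test_gene_independent_relapse_returns_prior(self):
        """When relapse has no gene parents, gene evidence is irrelevant."""
        structure = DbnStructure(("g", "relapse"), frozenset(),
                                 frozenset({("relapse", "relapse")}))
        model = DbnModel(
            structure, {"g": 2, "relapse": 2},
            {"g": np.array([[0.5, 0.5]]),
             "relapse": np.array([[0.9, 0.1]])},
            {"g": np.array([[0.5, 0.5]]),
             "relapse": np.array([[0.7, 0.3], [0.0, 1.0]])})
        with_gene = predict_relapse(model, {("g", 0): 1}, 3)
        prior = infer(model, {}, ("relapse", 1), 3)
        assert with_gene[1][0] == pytest.approx(prior[1])

    def test_observed_relapse_is_absorbing(self):
        model = self._absorbing_model()
        horizons = predict_relapse(model, {("relapse", 0): 1}, 3)
        assert horizons[1][0] == pytest.approx(1.0)
        assert horizons[2][0] == pytest.approx(1.0)
        assert horizons[1][1] and horizons[2][1]

    def test_evidence_must_include_baseline(self):
        with pytest.raises(ValidationError, match="baseline"):
            predict_relapse(self._absorbing_model(), {("relapse", 1): 0}, 3)
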