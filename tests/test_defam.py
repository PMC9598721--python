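"""Differential evolution of FAM populations: codec, operators, fitness,
selection and the evolution loop."""

import numpy as np
import pytest

from avnlbp.defam import (
    DEParams,
    FitnessRecord,
    NetworkCodec,
    PENALTY,
    crossover,
    encode,
    evolve,
    fitness,
    fitness_raw,
    mutate_classic,
    mutate_neigh_to_best,
    select,
    train_diverse_population,
    DEFAMClassifier,
)
from avnlbp.fam import FuzzyARTMAP
from _oracles import overlapping_feature_set


@pytest.fixture
def trained_net(rng):
    X = rng.random((30, 3))
    y = rng.integers(0, 3, 30)
    return FuzzyARTMAP(rho=0.85).fit(X, y)


class TestCodec:
    def test_dimension_and_inactive_slots(self):
        net = FuzzyARTMAP().fit([[0.2, 0.8]], [0])
        vec, codec = encode(net, catmax=4)
        assert vec.size == 4 * (2 * 2 + 2)
        slots = vec.reshape(4, 6)
        assert slots[0, -1] == 1.0
        assert np.all(slots[1:] == 0.0)

    def test_round_trip_preserves_predictions(self, rng, trained_net):
        vec, codec = encode(trained_net, catmax=trained_net.n_categories_ + 3)
        probes = rng.random((50, 3))
        assert np.array_equal(codec.decode(vec).predict(probes),
                              trained_net.predict(probes))

    def test_decode_clips_perturbed_weights(self, trained_net):
        vec, codec = encode(trained_net, catmax=trained_net.n_categories_ + 1)
        vec[0] = 1.3
        assert codec.decode(vec).weights_[0, 0] == 1.0

    def test_capacity_error(self, trained_net):
        with pytest.raises(ValueError, match="capacity|exceeding"):
            encode(trained_net, catmax=trained_net.n_categories_ - 1)

    def test_label_genes_round_to_valid_class(self, trained_net):
        vec, codec = encode(trained_net, catmax=trained_net.n_categories_)
        slots = vec.reshape(codec.catmax, codec.slot_size)
        slots[0, -2] = 7.4  # beyond the 3 classes -> clipped to 2
        assert codec.decode(vec).category_classes_[0] == 2


class TestMutation:
    @pytest.fixture
    def toy(self):
        vectors = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                            [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        values = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        return vectors, values

    def test_rand1_with_equal_donors_reduces_to_base(self, toy):
        vectors = np.tile([2.0, 5.0], (6, 1))
        v = mutate_classic(vectors, np.arange(6.0), 0, "rand/1", F=0.7, rng=0)
        assert v == pytest.approx([2.0, 5.0])

    def test_best1_with_zero_scale_is_best(self, toy):
        vectors, values = toy
        v = mutate_classic(vectors, values, 3, "best/1", F=0.0, rng=1)
        assert v == pytest.approx(vectors[0])  # argmin fitness

    def test_rand_to_best_hand_arithmetic(self, toy):
        vectors, values = toy
        rng = np.random.default_rng(3)
        v = mutate_classic(vectors, values, 2, "rand-to-best/1", F=0.5, rng=3)
        pool = np.delete(np.arange(6), 2)
        r = np.random.default_rng(3).choice(pool, size=2, replace=False)
        expected = (vectors[2] + 0.5 * (vectors[0] - vectors[2])
                    + 0.5 * (vectors[r[0]] - vectors[r[1]]))
        assert v == pytest.approx(expected)

    def test_population_too_small(self, toy):
        vectors, values = toy
        with pytest.raises(ValueError, match="too small"):
            mutate_classic(vectors[:4], values[:4], 0, "rand/2", F=1.0, rng=0)

    def test_neigh_to_best_zero_factors_is_base(self, toy):
        vectors, values = toy
        params = DEParams(F1=0.0, F2=0.0, catmin=1, catmax=2, seed=0)
        v = mutate_neigh_to_best(vectors, values, params, rng=0)
        assert any(np.allclose(v, x) for x in vectors[:3])

    def test_neigh_to_best_midpoint(self):
        # with the difference term cancelled, F1=0.5 lands midway between
        # the base donor and the best member
        vectors = np.array([[0.0, 0.0], [4.0, 8.0], [4.0, 8.0],
                            [4.0, 8.0], [4.0, 8.0], [4.0, 8.0]])
        values = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        params = DEParams(F1=0.5, F2=0.0, catmin=1, catmax=2, seed=0)
        v = mutate_neigh_to_best(vectors, values, params, rng=0)
        # base donor is either the best itself or one of the equal others
        assert v == pytest.approx([2.0, 4.0]) or v == pytest.approx([0.0, 0.0])

    def test_neigh_to_best_matches_hand_evaluation(self):
        vectors = np.array([[1.0, 2.0], [3.0, 1.0], [0.0, 5.0],
                            [2.0, 2.0], [4.0, 0.0]])
        values = np.array([0.5, 0.1, 0.9, 0.3, 0.7])
        params = DEParams(F1=0.6, F2=0.4, neigh_frac=0.6, catmin=1, catmax=2)
        v = mutate_neigh_to_best(vectors, values, params, rng=11)
        order = np.argsort(values)          # [1, 3, 0, 4, 2]
        pool = order[:3]                    # top 60% of 5 -> 3 members
        r1, r2, r3 = np.random.default_rng(11).choice(pool, 3, replace=False)
        best = vectors[1]
        expected = (vectors[r3] + 0.6 * (best - vectors[r3])
                    + 0.4 * (vectors[r1] - vectors[r2]))
        assert v == pytest.approx(expected)


class TestCrossover:
    def test_cr_one_takes_entire_mutant(self):
        x, v = np.zeros(8), np.ones(8)
        assert crossover(x, v, CR=1.0, rng=0) == pytest.approx(v)

    def test_cr_zero_keeps_target_except_jrand(self):
        x, v = np.zeros(8), np.ones(8)
        u = crossover(x, v, CR=0.0, rng=5)
        assert u.sum() == 1.0  # exactly the forced jrand component

    def test_replay_with_same_generator_state(self):
        x = np.arange(6.0)
        v = -np.arange(6.0)
        u = crossover(x, v, CR=0.7, rng=9)
        draws = np.random.default_rng(9).random(6)
        take = draws <= 0.7
        take[np.random.default_rng(9).integers(6)] = True  # same stream? no:
        # recompute faithfully: one generator drives both draws
        g = np.random.default_rng(9)
        take = g.random(6) <= 0.7
        take[g.integers(6)] = True
        assert u == pytest.approx(np.where(take, v, x))

    def test_printed_dialect_inverts_inequality(self):
        x, v = np.zeros(50), np.ones(50)
        canonical = crossover(x, v, CR=0.9, rng=3)
        printed = crossover(x, v, CR=0.9, rng=3, dialect="printed")
        assert canonical.sum() > printed.sum()

    def test_invalid_cr(self):
        with pytest.raises(ValueError, match="CR"):
            crossover(np.zeros(3), np.ones(3), CR=1.5, rng=0)


class TestFitness:
    def _enc(self, n_active, pcc_pattern, rng):
        """Build an encoding whose decoded network has the given category
        count; accuracy is then controlled by the eval labels."""
        X = rng.random((n_active, 2)) * 0.001 + np.linspace(
            0.1, 0.9, n_active)[:, None]
        y = np.arange(n_active) % 2
        net = FuzzyARTMAP(rho=1.0).fit(X, y)
        assert net.n_categories_ == n_active
        return net

    def test_optimum_is_zero(self):
        # catmin=4, catmax=20, Na=4, pcc=100 -> |400 - 400| = 0
        params = DEParams(catmin=4, catmax=20)
        assert abs(100.0 * 4 - 100.0 * 4) / ((20 - 4) * 100.0 ** 2) == 0.0

    def test_direct_arithmetic_example(self, rng):
        # catmin=4, catmax=20, Na=5, pcc=90 -> 50 / 121500
        value = abs(100.0 * 4 - 90.0 * 5) / ((20 - 5) * 90.0 ** 2)
        assert value == pytest.approx(4.115e-4, rel=1e-3)

    def test_fitness_on_decoded_network(self, rng):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        y = np.array([0, 1])
        net = FuzzyARTMAP(rho=0.9).fit(X, y)
        vec, codec = encode(net, catmax=10)
        params = DEParams(catmin=2, catmax=10)
        rec = fitness(vec, codec, X, y, params)
        assert rec.pcc == 100.0 and rec.n_active == 2
        assert rec.value == pytest.approx(
            abs(100 * 2 - 100 * 2) / ((10 - 2) * 100.0 ** 2))

    def test_na_at_catmax_is_penalized_not_divided(self, rng):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        y = np.array([0, 1])
        net = FuzzyARTMAP(rho=0.9).fit(X, y)
        vec, codec = encode(net, catmax=2)
        params = DEParams(catmin=2, catmax=2)
        rec = fitness(vec, codec, X, y, params)
        assert rec.value >= PENALTY

    def test_zero_accuracy_is_penalized(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        net = FuzzyARTMAP(rho=0.9).fit(X, [0, 1])
        vec, codec = encode(net, catmax=10)
        params = DEParams(catmin=2, catmax=10)
        rec = fitness(vec, codec, X, [1, 0], params)  # everything wrong
        assert rec.pcc == 0.0
        assert rec.value >= PENALTY

    def test_raw_formula_exposes_sign_pathology(self):
        # high accuracy near catmax drives the unguarded value to large
        # negative numbers, the reason the guarded form exists
        assert fitness_raw(100.0, 19, catmin=4, catmax=20) < 0


class TestSelection:
    def test_smaller_value_survives_and_ties_keep_target(self):
        x, u = np.zeros(3), np.ones(3)
        fx = FitnessRecord(90.0, 5, 0.5)
        fu = FitnessRecord(95.0, 4, 0.2)
        survivor, record = select(x, u, fx, fu)
        assert survivor is u and record is fu
        survivor, record = select(x, u, fx, FitnessRecord(95.0, 4, 0.5))
        assert survivor is x and record is fx

    def test_matches_argmin_oracle(self, rng):
        for _ in range(10):
            fx = FitnessRecord(0, 0, rng.random())
            fu = FitnessRecord(0, 0, rng.random())
            survivor, _ = select(np.zeros(1), np.ones(1), fx, fu)
            expected = np.ones(1) if fu.value < fx.value else np.zeros(1)
            assert survivor == pytest.approx(expected)


class TestEvolve:
    def _population(self, rng, n=6):
        X, y = overlapping_feature_set(rng, n_per_class=15)
        nets = train_diverse_population(X, y, n, rng, rho=0.95)
        return nets, X, y

    def test_zero_generations_returns_best_initial(self, rng):
        nets, X, y = self._population(rng)
        params = DEParams(catmin=3, catmax=60, generations=0, seed=0)
        result = evolve(nets, X, y, params)
        codec_nas = [n.n_categories_ for n in nets]
        assert result.record.n_active in codec_nas
        assert len(result.trace) == 1

    def test_best_fitness_non_increasing(self, rng):
        nets, X, y = self._population(rng, n=8)
        params = DEParams(catmin=3, catmax=80, generations=15, seed=2)
        result = evolve(nets, X, y, params)
        values = result.trace_values()
        assert np.all(np.diff(values) <= 1e-15)

    def test_reproducible_given_seed(self, rng):
        nets, X, y = self._population(rng)
        params = DEParams(catmin=3, catmax=60, generations=10, seed=4)
        r1 = evolve(nets, X, y, params)
        r2 = evolve(nets, X, y, params)
        assert np.array_equal(r1.trace_values(), r2.trace_values())
        assert np.array_equal(r1.network.weights_, r2.network.weights_)

    def test_returned_network_is_feasible(self, rng):
        nets, X, y = self._population(rng, n=8)
        params = DEParams(catmin=3, catmax=80, generations=20, seed=5)
        result = evolve(nets, X, y, params)
        assert 3 <= result.record.n_active <= 80

    def test_too_few_networks_rejected(self, rng):
        nets, X, y = self._population(rng)
        with pytest.raises(ValueError, match="at least 6"):
            evolve(nets[:3], X, y, DEParams(catmin=3, catmax=60))

    def test_stagnation_stops_early(self, rng, caplog):
        nets, X, y = self._population(rng)
        params = DEParams(catmin=3, catmax=60, generations=200, seed=1,
                          max_stagnation=3)
        with caplog.at_level("WARNING", logger="avnlbp.defam"):
            result = evolve(nets, X, y, params)
        assert len(result.trace) < 201

    def test_invalid_params_rejected_before_compute(self, rng):
        nets, X, y = self._population(rng)
        with pytest.raises(ValueError, match="catmin"):
            evolve(nets, X, y, DEParams(catmin=50, catmax=10))
        with pytest.raises(ValueError, match="neigh_frac"):
            evolve(nets, X, y, DEParams(catmin=3, catmax=60, neigh_frac=0.9))


class TestDEFAMClassifier:
    def test_fit_predict_reduces_categories(self, rng):
        X, y = overlapping_feature_set(rng, n_per_class=20)
        clf = DEFAMClassifier(n_networks=6, catmax=70, generations=10,
                              rho=0.95, random_state=0)
        clf.fit(X, y)
        max_initial = max(n.n_categories_ for n in clf.initial_networks_)
        assert clf.n_categories_ <= max_initial
        assert (clf.predict(X) == y).mean() > 0.5

    def test_sklearn_params(self):
        from sklearn.base import clone

        clf = DEFAMClassifier(generations=3)
        assert clone(clf).get_params()["generations"] == 3
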