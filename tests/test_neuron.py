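import itertools

import numpy as np
import pytest

from airkerma.gmdh import QuadraticNeuron, build_layer, fit_neuron, neuron_predict


def _normal_equations_oracle(x_i, x_j, y):
    """Independent least-squares solve of the 6x6 normal equations."""
    A = np.column_stack([np.ones_like(x_i), x_i, x_j, x_i**2, x_j**2, x_i * x_j])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitNeuron:
    def test_constant_target(self, rng):
        x_i, x_j = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        coeffs = fit_neuron(x_i, x_j, np.full(10, 5.0))
        np.testing.assert_allclose(coeffs, [5, 0, 0, 0, 0, 0], atol=1e-9)

    def test_pure_cross_term(self, rng):
        x_i, x_j = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        coeffs = fit_neuron(x_i, x_j, x_i * x_j)
        np.testing.assert_allclose(coeffs, [0, 0, 0, 0, 0, 1], atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x_i, x_j = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        y = 1 + 2 * x_i + 3 * x_j + 0.5 * x_i**2
        coeffs = fit_neuron(x_i, x_j, y)
        np.testing.assert_allclose(coeffs, [1, 2, 3, 0.5, 0, 0], atol=1e-8)
        np.testing.assert_allclose(coeffs, _normal_equations_oracle(x_i, x_j, y), atol=1e-8)

    def test_local_optimality(self, rng):
        """Perturbing any fitted coefficient never decreases the SSR."""
        x_i, x_j = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        y = rng.normal(size=30)
        coeffs = fit_neuron(x_i, x_j, y)

        def ssr(c):
            neuron = QuadraticNeuron(0, 1, tuple(c))
            return np.sum((y - neuron_predict(neuron, x_i, x_j)) ** 2)

        base = ssr(coeffs)
        for k in range(6):
            for delta in (-1e-3, 1e-3):
                bumped = coeffs.copy()
                bumped[k] += delta
                assert ssr(bumped) >= base

    def test_rank_deficient_gives_min_norm(self):
        # x_j constant: columns 1/3 and x_j-terms are collinear
        x_i = np.linspace(0, 1, 10)
        x_j = np.full(10, 0.5)
        coeffs = fit_neuron(x_i, x_j, 2 * x_i)
        pred = neuron_predict(QuadraticNeuron(0, 1, tuple(coeffs)), x_i, x_j)
        np.testing.assert_allclose(pred, 2 * x_i, atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_neuron([1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="non-finite"):
            fit_neuron(
                [1, 2, 3, 4, 5, np.inf], [1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]
            )


class TestNeuronPredict:
    @pytest.mark.parametrize(
        "coefficients, x_i, x_j, expected",
        [
            ((1, 0, 0, 0, 0, 0), [0.3, 7.0], [2.0, -1.0], [1.0, 1.0]),
            ((0, 1, 1, 0, 0, 0), [0.2], [0.3], [0.5]),
            ((1, 2, 3, 0.5, 0, 0), [1.0], [1.0], [6.5]),
        ],
    )
    def test_examples(self, coefficients, x_i, x_j, expected):
        neuron = QuadraticNeuron(0, 1, coefficients)
        np.testing.assert_allclose(neuron.predict(np.array(x_i), np.array(x_j)), expected)

    def test_length_mismatch(self):
        neuron = QuadraticNeuron(0, 1, (1, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError, match="same length"):
            neuron_predict(neuron, np.zeros(3), np.zeros(4))


class TestQuadraticNeuronInvariants:
    def test_rejects_equal_inputs(self):
        with pytest.raises(ValueError):
            QuadraticNeuron(2, 2, (0, 0, 0, 0, 0, 0))

    def test_rejects_wrong_coefficient_count(self):
        with pytest.raises(ValueError):
            QuadraticNeuron(0, 1, (1, 2, 3))

    def test_rejects_negative_score(self):
        with pytest.raises(ValueError):
            QuadraticNeuron(0, 1, (0,) * 6, criterion_score=-1.0)


class TestBuildLayer:
    @pytest.fixture()
    def four_features(self, rng):
        features = rng.uniform(0, 1, size=(60, 4))
        y = rng.normal(size=60)
        return features, y, np.arange(40), np.arange(40, 60)

    def test_candidate_count_and_width(self, four_features):
        features, y, fit_idx, select_idx = four_features
        full = build_layer(features, y, fit_idx, select_idx, width=100)
        assert len(full) == 6  # C(4, 2) candidate pairs
        layer = build_layer(features, y, fit_idx, select_idx, width=4)
        assert len(layer) == 4

    def test_survivors_sorted_by_score_then_pair(self, four_features):
        features, y, fit_idx, select_idx = four_features
        layer = build_layer(features, y, fit_idx, select_idx, width=6)
        keys = [(n.criterion_score, n.input_i, n.input_j) for n in layer.neurons]
        assert keys == sorted(keys)

    def test_recovers_generating_pair(self, rng):
        """An exact quadratic of features (1, 2) must win with ~zero score,
        confirmed against exhaustive independent scoring of all 6 pairs."""
        features = rng.uniform(0, 1, size=(80, 4))
        coeffs_true = np.array([0.3, -1.0, 2.0, 0.7, -0.4, 1.5])
        A = np.column_stack(
            [
                np.ones(80),
                features[:, 1],
                features[:, 2],
                features[:, 1] ** 2,
                features[:, 2] ** 2,
                features[:, 1] * features[:, 2],
            ]
        )
        y = A @ coeffs_true
        fit_idx, select_idx = np.arange(56), np.arange(56, 80)
        layer = build_layer(features, y, fit_idx, select_idx, width=6)
        best = layer.neurons[0]
        assert (best.input_i, best.input_j) == (1, 2)
        assert best.criterion_score < 1e-9

        # independent oracle: score every pair with the normal equations
        for i, j in itertools.combinations(range(4), 2):
            c = _normal_equations_oracle(
                features[fit_idx, i], features[fit_idx, j], y[fit_idx]
            )
            resid = y[select_idx] - neuron_predict(
                QuadraticNeuron(i, j, tuple(c)),
                features[select_idx, i],
                features[select_idx, j],
            )
            oracle_score = np.sqrt(np.mean(resid**2))
            matching = [
                n for n in layer.neurons if (n.input_i, n.input_j) == (i, j)
            ]
            assert matching and matching[0].criterion_score == pytest.approx(
                oracle_score, abs=1e-10
            )

    def test_errors(self, four_features):
        features, y, fit_idx, select_idx = four_features
        with pytest.raises(ValueError, match="cannot pair"):
            build_layer(features[:, :1], y, fit_idx, select_idx, width=2)
        with pytest.raises(ValueError, match="width"):
            build_layer(features, y, fit_idx, select_idx, width=0)
        with pytest.raises(ValueError, match="disjoint"):
            build_layer(features, y, np.arange(40), np.arange(39, 60), width=2)
        with pytest.raises(ValueError, match="non-empty"):
            build_layer(features, y, np.arange(40), np.array([], dtype=int), width=2)
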