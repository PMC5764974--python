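"""BP-ANN training, gradient correctness and MIV screening."""

import numpy as np
import pytest

from hecm.bpann import (
    ANNModel,
    _loss_and_grads,
    miv,
    predict,
    rank_variables,
    train_bpann,
)

from hecm.datasets import reference_screening_scores

# Published MIVs of the ten common peaks (screening-rule fixture).
PRINTED_MIV = reference_screening_scores()["miv"].tolist()


def _identity_scaled_model(w1, b1, w2, b2, activation="linear"):
    w1 = np.asarray(w1, float)
    w2 = np.asarray(w2, float)
    p = w1.shape[0]
    m = w2.shape[1]
    return ANNModel(
        w1=w1,
        b1=np.asarray(b1, float),
        w2=w2,
        b2=np.asarray(b2, float),
        activation=activation,
        x_min=np.zeros(p),
        x_range=np.ones(p),
        y_min=np.zeros(m),
        y_range=np.ones(m),
    )


class TestTraining:
    def test_bit_reproducible_for_fixed_seed(self, rng):
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 1))
        m1 = train_bpann(X, Y, epochs=50, seed=42)
        m2 = train_bpann(X, Y, epochs=50, seed=42)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert np.array_equal(m1.mse_trace, m2.mse_trace)

    def test_constant_response_converges_to_constant(self, rng):
        X = rng.normal(size=(10, 2))
        Y = np.full((10, 1), 5.0)
        # constant output column min-max maps to 0; training keeps it there
        m = train_bpann(X, Y, epochs=500, seed=0)
        assert m.mse_trace[-1] < 1e-3
        assert predict(m, X) == pytest.approx(Y, abs=0.5)

    def test_mse_decreases_on_linear_problem(self, rng):
        X = rng.uniform(size=(12, 3))
        Y = X[:, [0]]
        m = train_bpann(X, Y, epochs=500, seed=1)
        trace = m.mse_trace
        # monotone trend: each 100-epoch window ends lower than it starts
        for start in range(0, 400, 100):
            assert trace[start + 100] < trace[start]
        assert trace[-1] < trace[0]

    def test_trace_lengths_match_epochs(self, rng):
        m = train_bpann(rng.normal(size=(6, 2)), rng.normal(size=(6, 1)),
                        epochs=37, seed=0)
        assert len(m.mse_trace) == len(m.grad_trace) == 37

    def test_analytic_gradient_matches_central_differences(self, rng):
        Xs = rng.uniform(size=(5, 3))
        Ys = rng.uniform(size=(5, 2))
        w1 = rng.normal(size=(3, 3)) * 0.5
        b1 = rng.normal(size=3) * 0.1
        w2 = rng.normal(size=(3, 2)) * 0.5
        b2 = rng.normal(size=2) * 0.1
        _, grads = _loss_and_grads(w1, b1, w2, b2, "sigmoid", Xs, Ys)
        eps = 1e-6
        params = [w1, b1, w2, b2]
        for k, P in enumerate(params):
            num = np.zeros_like(P)
            for idx in np.ndindex(P.shape):
                Pp, Pm = P.copy(), P.copy()
                Pp[idx] += eps
                Pm[idx] -= eps
                args_p = [Pp if i == k else q for i, q in enumerate(params)]
                args_m = [Pm if i == k else q for i, q in enumerate(params)]
                lp, _ = _loss_and_grads(*args_p, "sigmoid", Xs, Ys)
                lm, _ = _loss_and_grads(*args_m, "sigmoid", Xs, Ys)
                num[idx] = (lp - lm) / (2 * eps)
            assert np.allclose(grads[k], num, atol=1e-6)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            train_bpann(X, rng.normal(size=(3, 1)))  # n < 4
        X = rng.normal(size=(6, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            train_bpann(X, rng.normal(size=(6, 1)))


class TestMiv:
    def test_unused_variable_has_zero_miv(self, rng):
        w1 = np.array([[1.0, 0.5], [0.0, 0.0]])  # variable 2 has no pathway
        model = _identity_scaled_model(w1, [0.0, 0.0], [[1.0], [1.0]], [0.0])
        X = rng.uniform(1.0, 2.0, size=(7, 2))
        r = miv(model, X)
        assert r.miv[1] == 0.0

    def test_linear_identity_network_closed_form(self, rng):
        # y = x1 through unit path weights: impact = (1.1 - 0.9) x1
        model = _identity_scaled_model([[1.0], [0.0]], [0.0], [[1.0]], [0.0])
        X = rng.uniform(0.5, 3.0, size=(9, 2))
        r = miv(model, X, delta=0.10)
        assert r.miv[0] == pytest.approx(0.2 * X[:, 0].mean(), abs=1e-12)
        assert r.iv[0] == pytest.approx(r.miv[0] * 9)

    def test_linear_network_miv_proportional_to_path_weights(self, rng):
        w1 = np.array([[0.3, -0.2], [0.7, 0.4]])
        w2 = np.array([[1.1], [-0.6]])
        model = _identity_scaled_model(w1, [0.1, -0.2], w2, [0.05])
        X = rng.uniform(0.5, 2.0, size=(6, 2))
        r = miv(model, X, delta=0.1)
        path = (w1 @ w2).ravel()  # summed path-weight products per input
        expected = 0.2 * X.mean(axis=0) * path
        assert np.allclose(r.miv, expected, atol=1e-10)

    def test_delta_bounds(self, rng):
        model = _identity_scaled_model([[1.0]], [0.0], [[1.0]], [0.0])
        with pytest.raises(ValueError):
            miv(model, rng.uniform(size=(4, 1)), delta=1.5)

    def test_planted_markers_top_two(self, scenario_data):
        _, _, X, Y = scenario_data
        model = train_bpann(X, Y, seed=0)
        r = miv(model, X, peak_ids=list(range(1, 11)))
        assert set(rank_variables(r, 2)) == {9, 10}


class TestRankVariables:
    def _result(self, mivs):
        mivs = np.asarray(mivs, float)
        ids = list(range(1, len(mivs) + 1))
        order_signed = sorted(range(len(ids)), key=lambda j: (-mivs[j], ids[j]))
        order_abs = sorted(range(len(ids)), key=lambda j: (-abs(mivs[j]), ids[j]))
        from hecm.bpann import MIVResult

        return MIVResult(
            iv=mivs * 3,
            miv=mivs,
            n=3,
            peak_ids=ids,
            ranking_signed=[ids[j] for j in order_signed],
            ranking_abs=[ids[j] for j in order_abs],
        )

    def test_printed_mivs_top2_signed_selects_10_and_9(self):
        r = self._result(PRINTED_MIV)
        assert rank_variables(r, 2) == [10, 9]

    def test_printed_mivs_abs_ranking_differs(self):
        # |-0.256| outranks 0.255: the absolute ranking would pick peak 1,
        # which is why the signed ranking is the screening default
        r = self._result(PRINTED_MIV)
        assert rank_variables(r, 2, by="abs") == [10, 1]

    def test_ties_break_toward_lower_id(self):
        r = self._result([0.5, 0.5, 0.5, 0.5])
        assert rank_variables(r, 2) == [1, 2]

    def test_top_k_equal_p_returns_full_order(self):
        r = self._result([0.1, 0.4, -0.2])
        assert rank_variables(r, 3) == [2, 1, 3]

    def test_top_k_exceeding_p_rejected(self):
        with pytest.raises(ValueError):
            rank_variables(self._result([0.1]), 2)
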