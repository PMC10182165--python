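"""The multistream LSTM: initialization, the gate equations (pinned to an
independent scalar oracle), masking semantics, gradients, and training."""

import numpy as np
import pytest

from tsradiomics.cohort import PatientSeries, StreamSchema
from tsradiomics.errors import TrainingError, ValidationError
from tsradiomics.lstm import TSRHyperparams, TSRModelParams, TimeSeriesRadiomicsModel, \
    bce_gradients, bce_loss, compute_loss, forward, init_params, lstm_cell_step, \
    train, train_ensemble
from tsradiomics.preprocessing import pad_and_mask

from conftest import oracle_patient_probability, random_cohort, random_patient


@pytest.fixture(scope="module")
def micro_schema():
    return StreamSchema(("a", "b"), (2, 1))


def _zero_params(schema, hidden):
    return TSRModelParams(schema, hidden)


class TestInit:
    def test_defaults_are_the_tuned_operating_point(self):
        h = TSRHyperparams()
        assert h.hidden_units == 16
        assert h.dropout_rate == 0.2
        assert h.learning_rate == 0.002
        assert h.epochs == 130

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_recurrent_kernels_orthogonal(self, seed):
        schema = StreamSchema.default()
        params = init_params(schema, TSRHyperparams(), seed)
        for k in range(schema.n_streams):
            for gate in ("i", "f", "o", "c"):
                u = params.recurrent(k, gate)
                np.testing.assert_allclose(u.T @ u, np.eye(u.shape[0]), atol=1e-6)

    def test_biases_zero_and_glorot_bound(self):
        schema = StreamSchema.default()
        params = init_params(schema, TSRHyperparams(hidden_units=16), seed=5)
        for k, d_k in enumerate(schema.widths):
            assert np.all(params.biases[k] == 0.0)
            limit = np.sqrt(6.0 / (d_k + 16))
            for gate in ("i", "f", "o", "c"):
                assert np.abs(params.kernel(k, gate)).max() <= limit
        assert params.head_b == 0.0
        head_limit = np.sqrt(6.0 / (3 * 16 + 1))
        assert np.abs(params.head_w).max() <= head_limit

    def test_deterministic_per_seed(self):
        schema = StreamSchema.default()
        a = init_params(schema, TSRHyperparams(), 3)
        b = init_params(schema, TSRHyperparams(), 3)
        np.testing.assert_array_equal(a.flat, b.flat)
        c = init_params(schema, TSRHyperparams(), 4)
        assert not np.array_equal(a.flat, c.flat)


class TestCellStep:
    def test_zero_everything(self, micro_schema):
        params = _zero_params(micro_schema, (3, 3))
        h, c, gates = lstm_cell_step(np.zeros(2), np.zeros(3), np.zeros(3), params)
        np.testing.assert_allclose(gates["i"], 0.5)
        np.testing.assert_allclose(gates["f"], 0.5)
        np.testing.assert_allclose(gates["o"], 0.5)
        np.testing.assert_allclose(gates["candidate"], 0.0)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_zero_params_unit_cell(self, micro_schema):
        """c_prev = 1: c = f*1 + i*0 = 0.5; h = 0.5*tanh(0.5) = 0.2310586."""
        params = _zero_params(micro_schema, (3, 3))
        h, c, _ = lstm_cell_step(np.zeros(2), np.zeros(3), np.ones(3), params)
        np.testing.assert_allclose(c, 0.5)
        np.testing.assert_allclose(h, 0.23105857863000487, atol=1e-12)

    def test_matches_scalar_equations(self, micro_schema):
        rng = np.random.default_rng(9)
        params = init_params(micro_schema, TSRHyperparams(hidden_units=3), 1)
        x = rng.standard_normal(2)
        h_prev = rng.standard_normal(3) * 0.5
        c_prev = rng.standard_normal(3) * 0.5
        h, c, _ = lstm_cell_step(x, h_prev, c_prev, params, stream=0)
        # literal per-unit evaluation
        for u in range(3):
            zi = params.bias(0, "i")[u] + h_prev @ params.recurrent(0, "i")[:, u] \
                + x @ params.kernel(0, "i")[:, u]
            zf = params.bias(0, "f")[u] + h_prev @ params.recurrent(0, "f")[:, u] \
                + x @ params.kernel(0, "f")[:, u]
            zo = params.bias(0, "o")[u] + h_prev @ params.recurrent(0, "o")[:, u] \
                + x @ params.kernel(0, "o")[:, u]
            zc = params.bias(0, "c")[u] + h_prev @ params.recurrent(0, "c")[:, u] \
                + x @ params.kernel(0, "c")[:, u]
            sig = lambda v: 1 / (1 + np.exp(-v))
            cc = sig(zf) * c_prev[u] + sig(zi) * np.tanh(zc)
            assert c[u] == pytest.approx(cc, abs=1e-12)
            assert h[u] == pytest.approx(sig(zo) * np.tanh(cc), abs=1e-12)

    def test_shape_mismatch_rejected(self, micro_schema):
        params = _zero_params(micro_schema, (3, 3))
        from tsradiomics.errors import SchemaError

        with pytest.raises(SchemaError):
            lstm_cell_step(np.zeros(5), np.zeros(3), np.zeros(3), params)


class TestForward:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scalar_oracle(self, micro_schema, seed):
        """Vectorised masked forward equals the literal-equation scalar loop
        on random tiny instances (tol 1e-10)."""
        rng = np.random.default_rng(seed)
        hyper = TSRHyperparams(hidden_units=3, dropout_rate=0.0)
        params = init_params(micro_schema, hyper, seed + 50)
        cohort = random_cohort(rng, micro_schema, n=4, t_range=(1, 5))
        batch = pad_and_mask(cohort.patients, micro_schema)
        probs = forward(batch, params, hyper)
        for i, p in enumerate(cohort.patients):
            assert probs[i] == pytest.approx(
                oracle_patient_probability(p, params), abs=1e-10)

    def test_tied_recurrence_matches_tied_oracle(self, micro_schema):
        rng = np.random.default_rng(77)
        hyper = TSRHyperparams(hidden_units=3, dropout_rate=0.0,
                               tied_input_forget_recurrence=True)
        params = init_params(micro_schema, hyper, 13)
        cohort = random_cohort(rng, micro_schema, n=3, t_range=(2, 4))
        batch = pad_and_mask(cohort.patients, micro_schema)
        probs = forward(batch, params, hyper)
        for i, p in enumerate(cohort.patients):
            assert probs[i] == pytest.approx(
                oracle_patient_probability(p, params, tied=True), abs=1e-10)
        untied = forward(batch, params, TSRHyperparams(hidden_units=3, dropout_rate=0.0))
        assert not np.allclose(probs, untied)

    @pytest.mark.parametrize("t_pad", [5, 7, 9])
    def test_padding_invariance(self, micro_schema, t_pad):
        rng = np.random.default_rng(3)
        params = init_params(micro_schema, TSRHyperparams(hidden_units=4), 0)
        p = random_patient(rng, "p", 1, micro_schema, t_i=4)
        base = forward(pad_and_mask([p], micro_schema), params)
        padded = forward(pad_and_mask([p], micro_schema, t_max=t_pad), params)
        assert abs(base[0] - padded[0]) < 1e-12

    def test_zero_head_gives_half(self, micro_schema, tiny_cohort):
        params = init_params(micro_schema, TSRHyperparams(hidden_units=3), 0)
        params.head_w[:] = 0.0
        params.head_b = 0.0
        batch = pad_and_mask(tiny_cohort.patients, micro_schema)
        np.testing.assert_allclose(forward(batch, params), 0.5)

    def test_no_cross_patient_coupling(self, micro_schema):
        rng = np.random.default_rng(5)
        params = init_params(micro_schema, TSRHyperparams(hidden_units=3), 2)
        cohort = random_cohort(rng, micro_schema, n=20, t_range=(2, 5))
        batch_all = pad_and_mask(cohort.patients, micro_schema)
        probs_all = forward(batch_all, params)
        t_max = int(batch_all.mask.shape[1])
        solo = forward(pad_and_mask([cohort.patients[7]], micro_schema, t_max=t_max),
                       params)
        assert abs(probs_all[7] - solo[0]) < 1e-12

    def test_batch_permutation_equivariance(self, micro_schema):
        rng = np.random.default_rng(6)
        params = init_params(micro_schema, TSRHyperparams(hidden_units=3), 2)
        cohort = random_cohort(rng, micro_schema, n=8, t_range=(3, 5))
        perm = rng.permutation(8)
        probs = forward(pad_and_mask(cohort.patients, micro_schema), params)
        probs_perm = forward(
            pad_and_mask([cohort.patients[i] for i in perm], micro_schema), params)
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-12)

    def test_inference_deterministic_bitwise(self, micro_schema, tiny_cohort):
        params = init_params(micro_schema, TSRHyperparams(), 0)
        batch = pad_and_mask(tiny_cohort.patients, micro_schema)
        a = forward(batch, params)
        b = forward(batch, params)
        np.testing.assert_array_equal(a, b)

    def test_trace_bounds(self, micro_schema):
        rng = np.random.default_rng(8)
        params = init_params(micro_schema, TSRHyperparams(hidden_units=4), 3)
        cohort = random_cohort(rng, micro_schema, n=5, t_range=(2, 5))
        batch = pad_and_mask(cohort.patients, micro_schema)
        probs, trace = forward(batch, params, return_trace=True)
        assert np.all((probs > 0) & (probs < 1))
        for k, g in enumerate(trace.gates):
            for name in ("i", "f", "o"):
                assert np.all((g[name] > 0) & (g[name] < 1))
            assert np.all(np.abs(g["candidate"]) < 1)
            assert np.all(np.abs(trace.hidden[k]) < 1)


class TestGradients:
    def test_gradients_match_finite_differences(self, micro_schema):
        """Central finite differences over every parameter, rel err < 1e-5."""
        rng = np.random.default_rng(0)
        hyper = TSRHyperparams(hidden_units=3, dropout_rate=0.0)
        params = init_params(micro_schema, hyper, 0)
        cohort = random_cohort(rng, micro_schema, n=2, t_range=(2, 3))
        batch = pad_and_mask(cohort.patients, micro_schema)
        _, grads, _ = bce_gradients(params, batch, hyper)
        eps = 1e-6
        for idx in range(params.flat.size):
            orig = params.flat[idx]
            params.flat[idx] = orig + eps
            lp = compute_loss(params, batch, hyper)
            params.flat[idx] = orig - eps
            lm = compute_loss(params, batch, hyper)
            params.flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(grads.flat[idx]), 1e-8)
            assert abs(fd - grads.flat[idx]) / denom < 1e-5

    def test_dropout_mask_gradients(self, micro_schema):
        """With a fixed dropout mask the analytic gradient still matches the
        finite-difference gradient of the masked-head loss."""
        rng = np.random.default_rng(4)
        hyper = TSRHyperparams(hidden_units=3, dropout_rate=0.5)
        params = init_params(micro_schema, hyper, 1)
        cohort = random_cohort(rng, micro_schema, n=2, t_range=(2, 3))
        batch = pad_and_mask(cohort.patients, micro_schema)
        d_mask = (rng.random((2, 6)) < 0.5).astype(float)
        _, grads, _ = bce_gradients(params, batch, hyper, dropout_mask=d_mask)

        def loss_with_mask():
            from tsradiomics.lstm import _run_stream, _sigmoid

            finals = []
            for k, x in enumerate(batch.streams):
                h_fin, _, _, _ = _run_stream(x, batch.mask, params, k, False, False)
                finals.append(h_fin)
            h_cat = np.concatenate(finals, axis=1)
            h_drop = h_cat * d_mask / 0.5
            return bce_loss(_sigmoid(h_drop @ params.head_w + params.head_b),
                            batch.labels)

        eps = 1e-6
        rng_idx = np.random.default_rng(2).choice(params.flat.size, 25, replace=False)
        for idx in rng_idx:
            orig = params.flat[idx]
            params.flat[idx] = orig + eps
            lp = loss_with_mask()
            params.flat[idx] = orig - eps
            lm = loss_with_mask()
            params.flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            # floor guards against FD truncation noise on near-zero gradients
            denom = max(abs(fd), abs(grads.flat[idx]), 1e-5)
            assert abs(fd - grads.flat[idx]) / denom < 1e-5


class TestTrain:
    def test_loss_decreases_on_separable_toy(self):
        schema = StreamSchema(("s",), (1,))
        lo = PatientSeries("lo", 0, [0, 6, 12], [np.full((3, 1), -1.0)])
        hi = PatientSeries("hi", 1, [0, 6, 12], [np.full((3, 1), 1.0)])
        hyper = TSRHyperparams(hidden_units=4)
        _, losses = train([lo, hi], schema, hyper, seed=0)
        assert losses[-1] < losses[0]
        assert losses[-1] < np.log(2)  # better than chance

    def test_lr_zero_is_identity(self, micro_schema, tiny_cohort):
        hyper = TSRHyperparams(hidden_units=3, learning_rate=0.0, epochs=20)
        params, losses = train(tiny_cohort.patients, micro_schema, hyper, seed=1)
        fresh_seed = int(np.random.default_rng(1).integers(2 ** 31))
        init = init_params(micro_schema, hyper, fresh_seed)
        np.testing.assert_array_equal(params.flat, init.flat)
        np.testing.assert_allclose(losses, losses[0])

    def test_single_class_subset_refused(self, micro_schema):
        rng = np.random.default_rng(2)
        patients = [random_patient(rng, f"p{i}", 1, micro_schema, 3) for i in range(4)]
        with pytest.raises(TrainingError):
            train(patients, micro_schema, TSRHyperparams(), seed=0)

    def test_training_deterministic(self, micro_schema, tiny_cohort):
        hyper = TSRHyperparams(hidden_units=3, epochs=10)
        a, la = train(tiny_cohort.patients, micro_schema, hyper, seed=4)
        b, lb = train(tiny_cohort.patients, micro_schema, hyper, seed=4)
        np.testing.assert_array_equal(a.flat, b.flat)
        np.testing.assert_array_equal(la, lb)

    def test_in_sample_auc_on_strong_drift(self, small_drift_cohort):
        """Default training separates a strongly drifting cohort in-sample."""
        aucs = []
        for seed in range(3):
            model = TimeSeriesRadiomicsModel(small_drift_cohort)
            res = model.fit(seed=seed)
            probs = res.predict(small_drift_cohort)
            y = small_drift_cohort.labels
            pos, neg = probs[y == 1], probs[y == 0]
            aucs.append(np.mean(pos[:, None] > neg[None, :]))
        assert np.mean(aucs) > 0.95

    def test_ensemble_equals_sequential(self, micro_schema, tiny_cohort):
        """Batched multi-seed training must reproduce per-seed training."""
        hyper = TSRHyperparams(hidden_units=3, epochs=15)
        seeds = [3, 9]
        ens = train_ensemble(tiny_cohort.patients, micro_schema, hyper, seeds)
        for seed, pe in zip(seeds, ens):
            ps, _ = train(tiny_cohort.patients, micro_schema, hyper, seed)
            np.testing.assert_allclose(pe.flat, ps.flat, atol=1e-12)

    def test_results_summary_mentions_fit(self, small_drift_cohort):
        res = TimeSeriesRadiomicsModel(
            small_drift_cohort, TSRHyperparams(epochs=10)).fit(seed=0)
        text = res.summary()
        assert "AUC" in text and "dropout" in text


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(dropout_rate=1.0), dict(learning_rate=-1e-3), dict(epochs=0)],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TSRHyperparams(**kwargs)

    def test_per_stream_units(self):
        schema = StreamSchema.default()
        h = TSRHyperparams(hidden_units=(8, 16, 4))
        assert h.units_for(schema) == (8, 16, 4)
        with pytest.raises(ValidationError):
            TSRHyperparams(hidden_units=(8, 16)).units_for(schema)
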