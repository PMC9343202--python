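import math

import numpy as np
import pytest

from mirsite.model import (
    CNN1d,
    CNNConfig,
    ClassProbabilities,
    LSTMCellParams,
    LSTMState,
    ModelConfig,
    SequenceClassifier,
    StackedModelParams,
    bilstm_forward,
    cnn1d_forward,
    load_checkpoint,
    lstm_cell_step,
    make_variant,
    save_checkpoint,
    softmax,
    stacked_forward,
)
from mirsite.training import _batch_loss_and_dlogits


# --- independent scalar oracle: pure-python gate equations ----------------


def scalar_lstm_step(x, h_prev, c_prev, p: LSTMCellParams):
    """Element-by-element evaluation of the gate equations in pure python."""
    H, D = p.hidden_size, p.input_size
    z = [float(v) for v in h_prev] + [float(v) for v in x]

    def gate(W, b, squash):
        out = []
        for r in range(H):
            s = float(b[r]) + sum(float(W[r][k]) * z[k] for k in range(H + D))
            out.append(squash(s))
        return out

    sig = lambda s: 1.0 / (1.0 + math.exp(-s))
    f = gate(p.W_f, p.b_f, sig)
    i = gate(p.W_i, p.b_i, sig)
    c_temp = gate(p.W_c, p.b_c, math.tanh)
    o = gate(p.W_o, p.b_o, sig)
    c = [f[r] * float(c_prev[r]) + i[r] * c_temp[r] for r in range(H)]
    h = [o[r] * math.tanh(c[r]) for r in range(H)]
    return h, c


def random_cell(rng, hidden, inp) -> LSTMCellParams:
    mk = lambda: rng.normal(size=(hidden, hidden + inp))
    vk = lambda: rng.normal(size=hidden)
    return LSTMCellParams(W_f=mk(), W_i=mk(), W_c=mk(), W_o=mk(),
                          b_f=vk(), b_i=vk(), b_c=vk(), b_o=vk())


def zero_cell(hidden, inp) -> LSTMCellParams:
    z = lambda: np.zeros((hidden, hidden + inp))
    v = lambda: np.zeros(hidden)
    return LSTMCellParams(W_f=z(), W_i=z(), W_c=z(), W_o=z(),
                          b_f=v(), b_i=v(), b_c=v(), b_o=v())


class TestLSTMCell:
    def test_zero_parameters_zero_state(self):
        cell = zero_cell(3, 2)
        out = lstm_cell_step(np.ones(2), LSTMState.zeros(3), cell)
        assert np.all(out.c == 0.0)
        assert np.all(out.h == 0.0)

    def test_zero_parameters_carry_cell_state(self):
        # gates all sigma(0)=0.5, candidate tanh(0)=0: c = 0.5 v, h = 0.5 tanh(0.5 v)
        cell = zero_cell(3, 2)
        v = np.array([1.0, -2.0, 0.5])
        out = lstm_cell_step(np.zeros(2), LSTMState(h=np.zeros(3), c=v), cell)
        assert np.allclose(out.c, 0.5 * v, atol=1e-15)
        assert np.allclose(out.h, 0.5 * np.tanh(0.5 * v), atol=1e-15)

    def test_saturated_forget_gate(self):
        cell = zero_cell(1, 1)
        cell.b_f[0] = 10.0
        out = lstm_cell_step(np.zeros(1), LSTMState(h=np.zeros(1), c=np.ones(1)), cell)
        f = 1.0 / (1.0 + math.exp(-10.0))
        assert out.c[0] == pytest.approx(f, abs=1e-12)
        assert out.c[0] == pytest.approx(0.99995, abs=1e-4)

    @pytest.mark.parametrize("hidden,inp", [(1, 1), (3, 2)])
    def test_agrees_with_scalar_oracle(self, hidden, inp):
        rng = np.random.default_rng(17)
        for _ in range(200):
            cell = random_cell(rng, hidden, inp)
            h_prev = rng.normal(size=hidden)
            c_prev = rng.normal(size=hidden)
            x = rng.normal(size=inp)
            out = lstm_cell_step(x, LSTMState(h=h_prev, c=c_prev), cell)
            h_ref, c_ref = scalar_lstm_step(x, h_prev, c_prev, cell)
            assert np.allclose(out.h, h_ref, atol=1e-12, rtol=0)
            assert np.allclose(out.c, c_ref, atol=1e-12, rtol=0)

    def test_dimension_mismatch_rejected(self):
        cell = zero_cell(3, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(np.zeros(5), LSTMState.zeros(3), cell)


class TestBiLSTM:
    def test_palindrome_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        cell = random_cell(rng, 4, 3)
        row = rng.normal(size=3)
        seq = np.stack([row, rng.normal(size=3), row])
        seq[1] = seq[1]
        pal = np.stack([seq[0], seq[1], seq[0]])
        out = bilstm_forward(pal, cell, cell)
        L, H = 3, 4
        for t in range(L):
            assert np.allclose(out[t, :H], out[L - 1 - t, H:], atol=1e-12)

    def test_zero_parameters_zero_output(self):
        cell = zero_cell(2, 3)
        out = bilstm_forward(np.random.default_rng(0).normal(size=(5, 3)), cell, cell)
        assert np.all(out == 0.0)

    def test_length_one_directions_coincide(self):
        rng = np.random.default_rng(2)
        cell = random_cell(rng, 4, 3)
        out = bilstm_forward(rng.normal(size=(1, 3)), cell, cell)
        assert np.allclose(out[0, :4], out[0, 4:], atol=1e-15)

    def test_reversal_swaps_direction_roles(self):
        rng = np.random.default_rng(3)
        fwd = random_cell(rng, 3, 2)
        bwd = random_cell(rng, 3, 2)
        seq = rng.normal(size=(6, 2))
        out = bilstm_forward(seq, fwd, bwd)
        rev = bilstm_forward(seq[::-1], bwd, fwd)
        # forward half on reversed input equals reversed backward half
        assert np.allclose(rev[:, :3], out[::-1, 3:], atol=1e-14)
        assert np.allclose(rev[:, 3:], out[::-1, :3], atol=1e-14)

    def test_empty_sequence_rejected(self):
        cell = zero_cell(2, 3)
        with pytest.raises(ValueError):
            bilstm_forward(np.zeros((0, 3)), cell, cell)


def small_stack(seed=0, d=3, h1=4, h2=2, lin=3) -> SequenceClassifier:
    cfg = ModelConfig(input_dim=d, hidden1=h1, hidden2=h2, linear1_units=lin)
    return SequenceClassifier(cfg, seed=seed)


class TestStackedForward:
    def test_zero_parameters_uniform_probabilities(self):
        model = small_stack()
        for k in model.params:
            model.params[k][:] = 0.0
        params = StackedModelParams.from_classifier(model)
        logits, probs = stacked_forward(np.ones((30, 3)), np.ones((30, 3)), params)
        assert np.allclose(logits, 0.0)
        assert np.allclose(probs.p, [0.5, 0.5])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = small_stack(seed=5)
        params = StackedModelParams.from_classifier(model)
        _, probs = stacked_forward(rng.normal(size=(30, 3)), rng.normal(size=(30, 3)), params)
        assert probs.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_branch_swap_changes_logits(self):
        rng = np.random.default_rng(6)
        model = small_stack(seed=6)
        params = StackedModelParams.from_classifier(model)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3))
        l1, _ = stacked_forward(a, b, params)
        l2, _ = stacked_forward(b, a, params)
        assert not np.allclose(l1, l2)

    def test_batched_and_single_paths_agree(self):
        rng = np.random.default_rng(7)
        model = small_stack(seed=7)
        params = StackedModelParams.from_classifier(model)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3))
        logits_single, _ = stacked_forward(a, b, params)
        logits_batch, _ = model.forward(a[None], b[None])
        assert np.allclose(logits_single, logits_batch[0], atol=1e-15)


class TestVariants:
    def test_bilstm_variant_matches_reference_stack(self):
        rng = np.random.default_rng(8)
        ctor = make_variant(("BiLSTM", "BiLSTM"))
        model = ctor(3, seed=8, hidden1=4, hidden2=2, linear1_units=3)
        ref = small_stack(seed=8)
        a, b = rng.normal(size=(1, 30, 3)), rng.normal(size=(1, 30, 3))
        assert np.array_equal(model.forward(a, b)[0], ref.forward(a, b)[0])

    def test_unidirectional_layer_width(self):
        ctor = make_variant(("LSTM", "LSTM"))
        model = ctor(3, seed=0, hidden1=4, hidden2=2, linear1_units=3)
        assert model.config.layer1_width == 4  # not 8
        assert model.params["l2.fwd.W_f"].shape == (2, 2 + 4)
        assert "l2.bwd.W_f" not in model.params
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.normal(size=(2, 30, 3)), rng.normal(size=(2, 30, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_rnn_zero_parameters_uniform(self):
        ctor = make_variant(("RNN", "RNN"))
        model = ctor(3, seed=0, hidden1=4, hidden2=2, linear1_units=3)
        for k in model.params:
            model.params[k][:] = 0.0
        probs = model.predict_proba(np.ones((2, 30, 3)), np.ones((2, 30, 3)))
        assert np.allclose(probs, 0.5)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            make_variant(("Transformer", "BiLSTM"))

    @pytest.mark.parametrize("arch", [
        ("RNN", "RNN"), ("GRU", "GRU"), ("LSTM", "LSTM"),
        ("LSTM", "BiLSTM"), ("BiLSTM", "LSTM"), ("BiLSTM", "BiLSTM"),
    ])
    def test_all_grid_architectures_produce_probabilities(self, arch):
        model = make_variant(arch)(3, seed=1, hidden1=3, hidden2=2, linear1_units=3)
        rng = np.random.default_rng(1)
        probs = model.predict_proba(rng.normal(size=(2, 30, 3)), rng.normal(size=(2, 30, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestCNN1d:
    def test_zero_parameters_uniform(self):
        model = CNN1d(CNNConfig(input_dim=3), seed=0)
        for k in model.params:
            model.params[k][:] = 0.0
        probs = cnn1d_forward(np.ones((30, 3)), np.ones((30, 3)), model)
        assert np.allclose(probs.p, 0.5)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(9)
        model = CNN1d(CNNConfig(input_dim=3), seed=9)
        probs = model.predict_proba(rng.normal(size=(4, 30, 3)), rng.normal(size=(4, 30, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_pad_region_ignored_when_weights_zero_there(self):
        # conv1 weights zero -> features constant in the input, so changing
        # PAD-row values cannot alter the output
        model = CNN1d(CNNConfig(input_dim=3), seed=10)
        model.params["conv1.W"][:] = 0.0
        rng = np.random.default_rng(10)
        a = rng.normal(size=(1, 30, 3))
        b = rng.normal(size=(1, 30, 3))
        p1 = model.predict_proba(a, b)
        a2 = a.copy()
        a2[0, 25:] = 99.0
        p2 = model.predict_proba(a2, b)
        assert np.array_equal(p1, p2)


def relative_grad_errors(model, B=2, T=5, d=2, seed=0):
    rng = np.random.default_rng(seed)
    Xm = rng.normal(size=(B, T, d))
    Xc = rng.normal(size=(B, T, d))
    y = rng.integers(0, 2, B)
    w = (1.0, 1.4)
    logits, cache = model.forward(Xm, Xc)
    _, dl = _batch_loss_and_dlogits(logits, y, w)
    grads = model.backward(dl, cache)
    h = 1e-5  # balances O(h^2) truncation against O(eps/h) roundoff
    errs = []
    for k, p in model.params.items():
        flat_idx = np.random.default_rng(1).choice(p.size, size=min(6, p.size), replace=False)
        for i in flat_idx:
            idx = tuple(np.unravel_index(i, p.shape))
            orig = p[idx]
            p[idx] = orig + h
            up, _ = _batch_loss_and_dlogits(model.forward(Xm, Xc)[0], y, w)
            p[idx] = orig - h
            down, _ = _batch_loss_and_dlogits(model.forward(Xm, Xc)[0], y, w)
            p[idx] = orig
            num = (up - down) / (2 * h)
            ana = grads[k][idx]
            scale = max(abs(num), abs(ana))
            if scale > 1e-6:  # below this, FD noise dominates
                errs.append(abs(num - ana) / scale)
    return errs


class TestBackprop:
    def test_stacked_gradients_match_finite_differences(self):
        model = small_stack(seed=21, d=2, h1=3, h2=2, lin=3)
        errs = relative_grad_errors(model, seed=21)
        assert max(errs) < 1e-4

    @pytest.mark.parametrize("arch", [("GRU", "GRU"), ("RNN", "BiLSTM")])
    def test_variant_gradients_match_finite_differences(self, arch):
        model = make_variant(arch)(2, seed=22, hidden1=3, hidden2=2, linear1_units=3)
        errs = relative_grad_errors(model, seed=22)
        assert max(errs) < 1e-4

    def test_cnn_gradients_match_finite_differences(self):
        model = CNN1d(CNNConfig(input_dim=2, seq_len=24), seed=23)
        rng = np.random.default_rng(23)
        Xm = rng.normal(size=(2, 12, 2))
        Xc = rng.normal(size=(2, 12, 2))
        y = rng.integers(0, 2, 2)
        logits, cache = model.forward(Xm, Xc)
        _, dl = _batch_loss_and_dlogits(logits, y, (1.0, 1.0))
        grads = model.backward(dl, cache)
        h = 1e-6
        for k, p in model.params.items():
            for i in np.random.default_rng(1).choice(p.size, size=min(5, p.size), replace=False):
                idx = tuple(np.unravel_index(i, p.shape))
                orig = p[idx]
                p[idx] = orig + h
                up, _ = _batch_loss_and_dlogits(model.forward(Xm, Xc)[0], y, (1.0, 1.0))
                p[idx] = orig - h
                down, _ = _batch_loss_and_dlogits(model.forward(Xm, Xc)[0], y, (1.0, 1.0))
                p[idx] = orig
                num = (up - down) / (2 * h)
                scale = max(abs(num), abs(grads[k][idx]))
                if scale > 1e-6:
                    assert abs(num - grads[k][idx]) / scale < 1e-4


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path):
        model = small_stack(seed=31)
        path = tmp_path / "m.ckpt"
        save_checkpoint(model, path)
        again = load_checkpoint(path)
        assert again.config == model.config
        assert set(again.params) == set(model.params)
        for k in model.params:
            assert np.array_equal(again.params[k], model.params[k])
        # byte-identical file on re-save
        save_checkpoint(again, tmp_path / "m2.ckpt")
        assert (tmp_path / "m.ckpt").read_bytes() == (tmp_path / "m2.ckpt").read_bytes()

    def test_cnn_round_trip(self, tmp_path):
        model = CNN1d(CNNConfig(input_dim=3), seed=2)
        save_checkpoint(model, tmp_path / "c.ckpt")
        again = load_checkpoint(tmp_path / "c.ckpt")
        assert isinstance(again, CNN1d)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(1, 30, 3)), rng.normal(size=(1, 30, 3))
        assert np.array_equal(model.predict_proba(a, b), again.predict_proba(a, b))


class TestSoftmax:
    def test_extreme_logits_stable(self):
        p = softmax(np.array([1000.0, -1000.0]))
        assert p[0] == pytest.approx(1.0)
        assert np.isfinite(p).all()

    def test_class_probabilities_validated(self):
        with pytest.raises(ValueError):
            ClassProbabilities(p=np.array([0.7, 0.6]))
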