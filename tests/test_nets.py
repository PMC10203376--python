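"""Gate-level LSTM/RNN/conv checks against explicit loop oracles, masking
semantics, determinism, and the sparse-autoencoder loss."""

import numpy as np
import pytest

from longidistill import autodiff as ad
from longidistill.nets import (AutoencoderConfig, Conv1d, LSTMCell, RNNCell,
                               SequenceClassifier, SparseAutoencoder,
                               autoencoder_loss, conv_extract, lstm_forward,
                               lstm_step, load_model, rebuild_head, rnn_step,
                               save_model)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_oracle(params, xs, squash=np.tanh):
    """Gate-by-gate loop implementation of the LSTM recurrence."""
    h = np.zeros(params["W_f"].shape[0])
    c = np.zeros_like(h)
    for x in xs:
        f = _sigmoid(params["W_f"] @ x + params["U_f"] @ h + params["b_f"])
        i = _sigmoid(params["W_i"] @ x + params["U_i"] @ h + params["b_i"])
        o = _sigmoid(params["W_o"] @ x + params["U_o"] @ h + params["b_o"])
        g = np.tanh(params["W_c"] @ x + params["U_c"] @ h + params["b_c"])
        c = f * c + i * g
        h = o * squash(c)
    return h, c


def _zeroed_cell(n_in, n_hidden, seed=0, squash="tanh"):
    cell = LSTMCell(n_in, n_hidden, np.random.default_rng(seed), state_squash=squash)
    for g in ("f", "i", "o", "c"):
        getattr(cell, f"W_{g}").data[:] = 0.0
        getattr(cell, f"U_{g}").data[:] = 0.0
        getattr(cell, f"b_{g}").data[:] = 0.0
    return cell


def test_zero_weight_step_closed_form():
    # all gates sigmoid(0)=0.5, candidate tanh(0)=0 -> c=0;
    # printed sigmoid variant: h = 0.5 * sigmoid(0) = 0.25
    cell = _zeroed_cell(3, 2, squash="sigmoid")
    state = lstm_step(cell, np.array([1.0, -2.0, 0.5]))
    assert np.allclose(state.c.data, 0.0)
    assert np.allclose(state.h.data, 0.25)
    # tanh default: h = 0.5 * tanh(0) = 0
    cell2 = _zeroed_cell(3, 2, squash="tanh")
    state2 = lstm_step(cell2, np.array([1.0, -2.0, 0.5]))
    assert np.allclose(state2.h.data, 0.0)


def test_saturated_forget_gate_carries_cell_state():
    cell = _zeroed_cell(1, 1)
    cell.b_f.data[:] = 50.0    # forget gate ~ 1
    cell.b_i.data[:] = -50.0   # input gate ~ 0
    from longidistill.nets import LSTMState
    state = LSTMState(h=ad.Tensor(np.zeros((1, 1))), c=ad.Tensor(np.ones((1, 1))), t=0)
    new = cell.step(ad.Tensor(np.array([[0.7]])), state)
    assert np.isclose(new.c.data[0, 0], 1.0, atol=1e-10)


@pytest.mark.parametrize("squash_name,squash_fn", [("tanh", np.tanh),
                                                   ("sigmoid", _sigmoid)])
def test_multistep_matches_loop_oracle(squash_name, squash_fn, rng):
    cell = LSTMCell(2, 2, np.random.default_rng(42), state_squash=squash_name)
    params = {n: getattr(cell, n).data for n in
              [f"{p}_{g}" for p in ("W", "U", "b") for g in ("f", "i", "o", "c")]}
    xs = [np.array([0.3, 0.7]), np.array([-0.2, 0.1]), np.array([0.9, -0.5])]
    state = None
    for x in xs:
        state = lstm_step(cell, x, state)
    h_ref, c_ref = lstm_oracle(params, xs, squash=squash_fn)
    assert np.abs(state.h.data[0] - h_ref).max() < 1e-10
    assert np.abs(state.c.data[0] - c_ref).max() < 1e-10


def test_gate_ranges_on_random_inputs(rng):
    cell = LSTMCell(4, 3, np.random.default_rng(5))
    x = rng.normal(size=(20, 5, 4)) * 3
    hidden, last = lstm_forward(cell, x, np.ones((20, 5)), use_mask=True)
    assert np.all(np.abs(hidden.data) < 1.0)  # tanh squashing keeps h in (-1, 1)


def test_masked_forward_equals_compacted_run(rng):
    cell = LSTMCell(3, 4, np.random.default_rng(8))
    obs = rng.random(size=(1, 2, 3))
    padded = np.zeros((1, 4, 3))
    padded[0, 0], padded[0, 3] = obs[0, 0], obs[0, 1]
    mask = np.array([[1, 0, 0, 1]])
    _, last_masked = lstm_forward(cell, padded, mask, use_mask=True)
    _, last_compact = lstm_forward(cell, obs, np.ones((1, 2)), use_mask=True)
    assert np.abs(last_masked.data - last_compact.data).max() < 1e-12


def test_unmasked_run_differs_when_padding_hits_gates(rng):
    cell = LSTMCell(3, 4, np.random.default_rng(8))
    padded = np.zeros((1, 4, 3))
    padded[0, 0] = rng.random(3)
    padded[0, 3] = rng.random(3)
    mask = np.array([[1, 0, 0, 1]])
    _, masked = lstm_forward(cell, padded, mask, use_mask=True)
    _, unmasked = lstm_forward(cell, padded, mask, use_mask=False)
    # zero inputs still move the gates (biases), so the paths diverge
    assert np.abs(masked.data - unmasked.data).max() > 1e-8


def test_single_step_forward_equals_step():
    cell = LSTMCell(3, 2, np.random.default_rng(3))
    x = np.random.default_rng(0).random((4, 1, 3))
    _, last = lstm_forward(cell, x, np.ones((4, 1)), use_mask=True)
    step = lstm_step(cell, x[:, 0])
    assert np.abs(last.data - step.h.data).max() < 1e-14


def test_all_zero_mask_subject_is_an_error():
    cell = LSTMCell(2, 2, np.random.default_rng(0))
    with pytest.raises(ValueError, match="all-zero mask"):
        lstm_forward(cell, np.zeros((1, 3, 2)), np.zeros((1, 3)), use_mask=True)


def test_fused_step_equals_per_gate_step(rng):
    cell = LSTMCell(5, 4, np.random.default_rng(77))
    cat = cell.gate_cat()
    state = cell.initial_state(3)
    for t in range(4):
        x = ad.Tensor(rng.normal(size=(3, 5)))
        s1, s2 = cell.step(x, state), cell.step_fused(x, state, cat)
        assert np.abs(s1.h.data - s2.h.data).max() < 1e-14
        assert np.abs(s1.c.data - s2.c.data).max() < 1e-14
        state = s1


# ---------------------------------------------------------------------------
# conv
# ---------------------------------------------------------------------------

def test_conv_hand_sums():
    conv = Conv1d(1, 1, 3, 1, np.random.default_rng(0))
    conv.W.data[:] = 1.0
    conv.b.data[:] = 0.0
    out = conv_extract(conv, np.array([1.0, 2.0, 3.0, 4.0]))
    assert np.allclose(out.data, [[6.0, 9.0]])


def test_identity_kernel_passes_input_through():
    conv = Conv1d(1, 1, 1, 1, np.random.default_rng(0))
    conv.W.data[:] = 1.0
    conv.b.data[:] = 0.25
    x = np.array([0.1, -0.4, 2.0])
    assert np.allclose(conv_extract(conv, x).data, x + 0.25)


def test_conv_matches_double_loop_oracle(rng):
    conv = Conv1d(2, 3, 4, 2, np.random.default_rng(12))
    x = rng.normal(size=(2, 10))
    out = conv_extract(conv, x).data
    w, b = conv.W.data, conv.b.data
    L = (10 - 4) // 2 + 1
    for o in range(3):
        for l in range(L):
            ref = b[o]
            for c in range(2):
                for j in range(4):
                    ref += w[o, c, j] * x[c, 2 * l + j]
            assert abs(out[o, l] - ref) < 1e-12


def test_conv_linear_in_input(rng):
    conv = Conv1d(1, 2, 3, 1, np.random.default_rng(1))
    conv.b.data[:] = 0.0
    x, y = rng.normal(size=(1, 8)), rng.normal(size=(1, 8))
    fx = conv_extract(conv, x).data
    fy = conv_extract(conv, y).data
    fxy = conv_extract(conv, 2.0 * x + 3.0 * y).data
    assert np.abs(fxy - (2 * fx + 3 * fy)).max() < 1e-9


def test_input_shorter_than_kernel_is_an_error():
    conv = Conv1d(1, 1, 5, 1, np.random.default_rng(0))
    with pytest.raises(ValueError, match="shorter than kernel"):
        conv_extract(conv, np.ones(3))


# ---------------------------------------------------------------------------
# RNN
# ---------------------------------------------------------------------------

def test_rnn_closed_forms():
    cell = RNNCell(1, 1, np.random.default_rng(0))
    cell.W_x.data[:] = 1.0
    cell.W_h.data[:] = 0.0
    cell.b.data[:] = 0.0
    h = rnn_step(cell, np.array([0.5]))
    assert np.isclose(h.data[0, 0], np.tanh(0.5), atol=1e-12)
    cell.W_x.data[:] = 0.0
    cell.b.data[:] = 0.3
    h2 = rnn_step(cell, np.array([123.0]))
    assert np.isclose(h2.data[0, 0], np.tanh(0.3), atol=1e-12)


def test_rnn_multistep_matches_loop_oracle(rng):
    cell = RNNCell(3, 2, np.random.default_rng(21))
    xs = rng.normal(size=(5, 3))
    h = None
    for x in xs:
        h = rnn_step(cell, x, h)
    ref = np.zeros(2)
    for x in xs:
        ref = np.tanh(cell.W_x.data @ x + cell.W_h.data @ ref + cell.b.data)
    assert np.abs(h.data[0] - ref).max() < 1e-10


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def test_identity_conv_cnnlstm_reduces_to_lstm(rng):
    lstm = SequenceClassifier(6, 3, arch="lstm", hidden=8, seed=3)
    cnn = SequenceClassifier(6, 3, arch="cnnlstm", hidden=8,
                             conv_channels=(1,), kernel_size=1, stride=1, seed=3)
    # configure the conv as the identity and copy the recurrent/head weights
    cnn.convs[0].W.data[:] = 1.0
    cnn.convs[0].b.data[:] = 0.0
    state = lstm.state_dict()
    cnn_state = cnn.state_dict()
    for k, v in state.items():
        if not k.startswith("conv"):
            cnn_state[k] = v
    cnn.load_state_dict(cnn_state)
    x = rng.normal(size=(5, 4, 6))
    mask = np.ones((5, 4))
    p1 = lstm.predict_proba(x, mask)
    p2 = cnn.predict_proba(x, mask)
    assert np.abs(p1 - p2).max() < 1e-12


def test_forward_deterministic_and_probabilistic(rng):
    model = SequenceClassifier(10, 4, arch="cnnlstm", hidden=8,
                               conv_channels=(4,), seed=9)
    x, mask = rng.random(size=(6, 3, 10)), np.ones((6, 3))
    p1, p2 = model.predict_proba(x, mask), model.predict_proba(x, mask)
    assert np.array_equal(p1, p2)  # bitwise-stable
    assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((p1 > 0) & (p1 < 1))


def test_multilabel_head_outputs_independent_sigmoids(rng):
    model = SequenceClassifier(5, 3, arch="lstm", hidden=6,
                               multi_label=True, seed=2)
    p = model.predict_proba(rng.random(size=(4, 2, 5)), np.ones((4, 2)))
    assert p.shape == (4, 3)
    assert np.all((p > 0) & (p < 1))
    # rows need not sum to one in multi-label mode
    assert not np.allclose(p.sum(axis=1), 1.0)


def test_checkpoint_round_trip_and_head_rebuild(tmp_path, rng):
    model = SequenceClassifier(8, 4, arch="cnnlstm", hidden=6,
                               conv_channels=(3,), seed=1)
    x, mask = rng.random(size=(3, 2, 8)), np.ones((3, 2))
    p_ref = model.predict_proba(x, mask)
    save_model(model, tmp_path / "m.npz")
    back = load_model(tmp_path / "m.npz")
    assert np.array_equal(back.predict_proba(x, mask), p_ref)

    body_before = {k: v for k, v in back.state_dict().items()
                   if not k.startswith("head")}
    rebuild_head(back, 3, use_concat_pool=True, seed=5)
    assert back.n_outputs == 3
    assert back.predict_proba(x, mask).shape == (3, 3)
    body_after = {k: v for k, v in back.state_dict().items()
                  if not k.startswith("head")}
    for k in body_before:
        assert np.array_equal(body_before[k], body_after[k])


# ---------------------------------------------------------------------------
# sparse autoencoder loss
# ---------------------------------------------------------------------------

def test_autoencoder_loss_zero_for_perfect_reconstruction(rng):
    x = rng.random(size=(4, 6))
    cfg = AutoencoderConfig(lam=0.0, beta=0.0)
    loss = autoencoder_loss(cfg, x, ad.Tensor(x), [], ad.Tensor(np.full((4, 2), 0.5)))
    assert loss.item() == 0.0


def test_autoencoder_sparsity_term_vanishes_at_target():
    x = np.zeros((3, 4))
    cfg = AutoencoderConfig(lam=0.0, beta=2.0, p=0.3)
    latent = ad.Tensor(np.full((3, 5), 0.3))  # average activation == p
    loss = autoencoder_loss(cfg, x, ad.Tensor(x), [], latent)
    assert abs(loss.item()) < 1e-12


def test_autoencoder_loss_matches_hand_computation(rng):
    x = rng.random(size=(2, 3))
    x_hat = rng.random(size=(2, 3))
    w = rng.normal(size=(3, 2))
    latent = rng.random(size=(2, 2)) * 0.8 + 0.1
    lam, beta, p = 0.1, 0.5, 0.05
    cfg = AutoencoderConfig(lam=lam, beta=beta, p=p)
    got = autoencoder_loss(cfg, x, ad.Tensor(x_hat), [ad.Tensor(w)],
                           ad.Tensor(latent)).item()
    recon = ((x - x_hat) ** 2).sum() / 2
    reg = lam * (w ** 2).sum()
    p_hat = latent.mean(axis=0)
    kl = (p * np.log(p / p_hat) + (1 - p) * np.log((1 - p) / (1 - p_hat))).sum()
    assert abs(got - (recon + reg + beta * kl)) < 1e-10


def test_latent_size_must_be_smaller_than_input():
    with pytest.raises(ValueError, match="latent size"):
        SparseAutoencoder(5, 5)
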