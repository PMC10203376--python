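"""Distillation losses vs explicit loop oracles; schedule, cache, and
trainer-reduction equivalences."""

import numpy as np
import pytest

from longidistill import autodiff as ad
from longidistill.distill import (DistillSchedule, TeacherCache, TrainConfig,
                                  alpha_at, binary_cross_entropy,
                                  cross_entropy, encode_targets, feature_l2,
                                  first_distillation_loss, kl_divergence,
                                  psk_loss, train, train_autoencoder)
from longidistill.longio import pad_in_sequence
from longidistill.nets import SequenceClassifier, SparseAutoencoder
from longidistill.synthgen import SynthConfig, generate_cohort


def _rand_probs(rng, m, c):
    p = rng.random((m, c)) + 1e-3
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# loss oracles
# ---------------------------------------------------------------------------

def test_cross_entropy_closed_forms():
    y = np.array([[1.0, 0.0]])
    assert cross_entropy(y, ad.Tensor(np.array([[1.0, 0.0]]))).item() <= 1.2e-7
    assert np.isclose(cross_entropy(y, ad.Tensor(np.array([[0.5, 0.5]]))).item(),
                      np.log(2), atol=1e-9)


def test_cross_entropy_matches_loop_oracle(rng):
    for _ in range(20):
        m, c = int(rng.integers(1, 8)), int(rng.integers(2, 5))
        y = np.eye(c)[rng.integers(0, c, size=m)]
        p = _rand_probs(rng, m, c)
        got = cross_entropy(y, ad.Tensor(p)).item()
        ref = -sum(y[i, k] * np.log(np.clip(p[i, k], 1e-7, 1 - 1e-7))
                   for i in range(m) for k in range(c)) / m
        assert abs(got - ref) < 1e-10


def test_cross_entropy_rejects_empty_batch():
    with pytest.raises(ValueError):
        cross_entropy(np.zeros((0, 2)), ad.Tensor(np.zeros((0, 2))))


def test_kl_zero_iff_equal_and_closed_form(rng):
    p = _rand_probs(rng, 3, 4)
    assert abs(kl_divergence(p, p).item()) < 1e-12
    got = kl_divergence(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])).item()
    assert abs(got - np.log(2)) < 1e-5  # clamping at eps shifts it slightly


def test_kl_matches_loop_oracle_and_gibbs(rng):
    for _ in range(50):
        m, c = int(rng.integers(1, 6)), int(rng.integers(2, 5))
        p, q = _rand_probs(rng, m, c), _rand_probs(rng, m, c)
        got = kl_divergence(p, q).item()
        ref = sum((p[i] * np.log(p[i] / q[i])).sum() for i in range(m)) / m
        assert abs(got - ref) < 1e-8
        assert got >= -1e-12  # Gibbs' inequality


def test_feature_l2_oracle(rng):
    assert feature_l2(np.ones((2, 2)), np.ones((2, 2))).item() == 0.0
    assert feature_l2(np.ones((2, 2)), np.zeros((2, 2))).item() == 1.0
    a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    ref = ((a - b) ** 2).mean()
    assert abs(feature_l2(a, b).item() - ref) < 1e-12
    with pytest.raises(ValueError, match="shapes differ"):
        feature_l2(np.ones((2, 2)), np.ones((3, 2)))


def test_first_distillation_reduces_to_main_ce(rng):
    y = np.eye(3)[[0, 1, 2]]
    main = ad.Tensor(_rand_probs(rng, 3, 3))
    br = [ad.Tensor(_rand_probs(rng, 3, 3))]
    w_m, w_s = ad.Tensor(rng.normal(size=(4, 4))), ad.Tensor(rng.normal(size=(4, 4)))
    total, _ = first_distillation_loss(main, br, y, w_m, [w_s], weights=(0, 0, 0))
    assert abs(total.item() - cross_entropy(y, main).item()) < 1e-12


def test_first_distillation_composes_terms(rng):
    y = np.eye(2)[[0, 1, 0]]
    main = ad.Tensor(_rand_probs(rng, 3, 2))
    branches = [ad.Tensor(_rand_probs(rng, 3, 2)) for _ in range(2)]
    w_m = ad.Tensor(rng.normal(size=(3, 3)))
    w_s = [ad.Tensor(rng.normal(size=(3, 3))) for _ in range(2)]
    weights = (0.7, 0.3, 0.5)
    total, report = first_distillation_loss(main, branches, y, w_m, w_s, weights)
    ref = cross_entropy(y, main).item()
    for bp, wb in zip(branches, w_s):
        ref += 0.7 * cross_entropy(y, bp).item()
        ref += 0.3 * kl_divergence(bp, main).item()
        ref += 0.5 * feature_l2(w_m, wb).item()
    assert abs(total.item() - ref) < 1e-10
    assert "branch1_kl" in report


def test_branch_identical_to_main_zeroes_kl_and_feature_terms(rng):
    y = np.eye(2)[[0, 1]]
    main = ad.Tensor(_rand_probs(rng, 2, 2))
    w = ad.Tensor(rng.normal(size=(2, 2)))
    _, report = first_distillation_loss(main, [main], y, w, [w])
    assert abs(report["branch0_kl"]) < 1e-12
    assert report["branch0_feat_l2"] == 0.0


# ---------------------------------------------------------------------------
# schedule + progressive distillation
# ---------------------------------------------------------------------------

def test_alpha_schedule_exact_and_monotone():
    sched = DistillSchedule(alpha_T=0.8, total_epochs=100)
    assert alpha_at(sched, 0) == 0.0
    assert alpha_at(sched, 25) == pytest.approx(0.2)
    assert alpha_at(sched, 100) == 0.8
    vals = [alpha_at(sched, t) for t in range(101)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert all(0.0 <= v <= 0.8 for v in vals)
    with pytest.raises(ValueError):
        alpha_at(sched, 101)


def test_psk_loss_reductions(rng):
    y = np.eye(2)[[0, 1, 1]]
    p = ad.Tensor(_rand_probs(rng, 3, 2))
    teacher = _rand_probs(rng, 3, 2)
    # alpha = 0 -> plain hard-label cross-entropy
    assert abs(psk_loss(y, p, teacher, 0.0).item()
               - cross_entropy(y, p).item()) < 1e-12
    # alpha = 1, teacher == current prediction -> entropy of the prediction
    h = -(p.data * np.log(p.data)).sum(axis=1).mean()
    assert abs(psk_loss(y, p, p.data, 1.0).item() - h) < 1e-6


def test_psk_loss_hand_combination(rng):
    y = np.eye(2)[[0, 1]]
    p = ad.Tensor(_rand_probs(rng, 2, 2))
    teacher = _rand_probs(rng, 2, 2)
    got = psk_loss(y, p, teacher, 0.5).item()
    ref = 0.5 * cross_entropy(y, p).item() + 0.5 * cross_entropy(teacher, p).item()
    assert abs(got - ref) < 1e-10


def test_teacher_cache_missing_entry_errors(rng):
    cache = TeacherCache()
    cache.update(np.array([0, 1]), _rand_probs(rng, 2, 3), epoch=0)
    assert cache.get(np.array([1, 0])).shape == (2, 3)
    with pytest.raises(KeyError, match="index 5"):
        cache.get(np.array([5]))


# ---------------------------------------------------------------------------
# trainer
# ---------------------------------------------------------------------------

def _tiny_setup(scheme, seed=0, n_branches=0):
    cohort, _ = generate_cohort(SynthConfig(
        n_subjects=50, n_features=10, n_timepoints=3, effect_size=0.8,
        missing_rate=0.2, seed=21))
    batch = pad_in_sequence(cohort)
    model = SequenceClassifier(10, 2, arch="cnnlstm", hidden=8,
                               conv_channels=(4,), kernel_size=3,
                               n_branches=n_branches, seed=seed)
    return model, batch


def test_zero_lr_leaves_parameters_unchanged():
    model, batch = _tiny_setup("none")
    before = model.state_dict()
    train(model, batch, scheme="none",
          config=TrainConfig(epochs=1, lr=0.0, seed=0))
    after = model.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k])


def test_sd_with_zero_alpha_matches_baseline_trace():
    cfgs = dict(epochs=5, lr=1e-3, seed=3, batch_size=16)
    m1, batch = _tiny_setup("none", seed=5)
    r1 = train(m1, batch, scheme="none", config=TrainConfig(**cfgs))
    m2, _ = _tiny_setup("sd", seed=5)
    r2 = train(m2, batch, scheme="sd", config=TrainConfig(alpha_T=0.0, **cfgs))
    assert np.abs(r1.losses() - r2.losses()).max() < 1e-6


def test_fd_with_zero_aux_weights_matches_baseline_trace():
    cfgs = dict(epochs=5, lr=1e-3, seed=3, batch_size=16)
    m1, batch = _tiny_setup("none", seed=5)
    r1 = train(m1, batch, scheme="none", config=TrainConfig(**cfgs))
    m2, _ = _tiny_setup("fd", seed=5, n_branches=2)
    r2 = train(m2, batch, scheme="fd",
               config=TrainConfig(branch_weights=(0.0, 0.0, 0.0), **cfgs))
    assert np.abs(r1.losses() - r2.losses()).max() < 1e-6


def test_fd_training_reduces_loss_on_separable_cohort():
    cohort, _ = generate_cohort(SynthConfig(
        n_subjects=60, n_features=10, n_timepoints=3, effect_size=1.0,
        missing_rate=0.1, seed=7))
    batch = pad_in_sequence(cohort)
    model = SequenceClassifier(10, 2, arch="cnnlstm", hidden=8,
                               conv_channels=(4,), kernel_size=3,
                               n_branches=2, seed=7)
    res = train(model, batch, scheme="fd",
                config=TrainConfig(epochs=15, lr=2e-3, seed=7))
    assert res.losses()[-1] < res.losses()[0]


def test_sd_requires_no_branches_but_fd_does():
    model, batch = _tiny_setup("none")
    with pytest.raises(ValueError, match="branch"):
        train(model, batch, scheme="fd", config=TrainConfig(epochs=1))


def test_teacher_cache_tracks_previous_epoch_predictions():
    model, batch = _tiny_setup("none", seed=2)
    cfg = TrainConfig(epochs=3, lr=1e-3, seed=2, alpha_T=0.8)
    res = train(model, batch, scheme="sd", config=cfg)
    # after training, recompute final-epoch predictions from the final state
    probs = model.predict_proba(batch.values, batch.mask, use_mask=False)
    m2 = SequenceClassifier(**{**model.config})
    m2.load_state_dict(res.final_state)
    probs2 = m2.predict_proba(batch.values, batch.mask, use_mask=False)
    assert np.array_equal(probs, probs2)


def test_divergent_loss_aborts_with_epoch_report():
    model, batch = _tiny_setup("none")
    batch.values[0, 0, 0] = np.nan  # propagates to a non-finite loss
    with pytest.raises(FloatingPointError, match="epoch"):
        train(model, batch, scheme="none",
              config=TrainConfig(epochs=3, lr=1e-3, seed=0))


def test_validation_trace_and_best_checkpoint(small_cohort):
    batch = pad_in_sequence(small_cohort)
    model = SequenceClassifier(12, 2, arch="lstm", hidden=8, seed=0)
    res = train(model, batch, scheme="none",
                config=TrainConfig(epochs=4, validation_fraction=0.2, seed=1))
    val = res.losses("val")
    assert len(val) == 4
    assert res.best_epoch == int(np.argmin(val)) + 1


def test_encode_targets_one_hot_and_multilabel():
    y, classes = encode_targets(np.array(["b", "a", "b"]), multi_label=False)
    assert list(classes) == ["a", "b"]
    assert np.array_equal(y, [[0, 1], [1, 0], [0, 1]])
    y2, _ = encode_targets(np.array([[1, 0], [0, 1]]), multi_label=True)
    assert np.array_equal(y2, [[1, 0], [0, 1]])


def test_multilabel_bce_matches_loop(rng):
    y = rng.integers(0, 2, size=(4, 3)).astype(float)
    p = rng.random((4, 3)) * 0.8 + 0.1
    got = binary_cross_entropy(y, ad.Tensor(p)).item()
    ref = -sum(y[i, j] * np.log(p[i, j]) + (1 - y[i, j]) * np.log(1 - p[i, j])
               for i in range(4) for j in range(3)) / 4
    assert abs(got - ref) < 1e-10


def test_autoencoder_trainer_reduces_reconstruction_loss(rng):
    from longidistill.nets import AutoencoderConfig
    x = rng.random((40, 12))
    ae = SparseAutoencoder(12, 4, hidden=(8,), seed=0)
    losses = train_autoencoder(ae, x, AutoencoderConfig(), epochs=30,
                               batch_size=16, lr=3e-3, seed=0)
    assert losses[-1] < losses[0]
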