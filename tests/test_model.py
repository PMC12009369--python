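"""ODE-RNN mechanics: solver behaviour, GRU updates, encode/predict, training."""

import copy

import numpy as np
import pytest
from scipy.linalg import expm

from ttdml import ModelConfig
from ttdml.model import (GRUBaseline, LSTMBaseline, ODERNNClassifier,
                         RNNBaseline, make_model, train_ensemble)
from ttdml.nn import Tensor

H = 8


def _small_config(**kw):
    defaults = dict(n_channels=25, hidden_dim=H, phenotype_dim=4,
                    static_hidden=[4], ode_hidden=[8], longitudinal_hidden=[8],
                    fusion_hidden=[8], classifier_hidden=[4], seed=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


def _linear_field_model(A, solver="euler", max_step=15.0):
    """ODE-RNN whose vector field is exactly f(h) = A h (per hour)."""
    model = ODERNNClassifier(_small_config(ode_hidden=[], solver=solver,
                                           max_step=max_step))
    layer = model.f_ode.layers[0]
    layer.W.data = A.T.copy()
    layer.b.data[:] = 0.0
    return model


def test_zero_field_evolution_is_identity(rng):
    model = ODERNNClassifier(_small_config())
    for layer in model.f_ode.layers:
        layer.W.data[:] = 0.0
        layer.b.data[:] = 0.0
    h = rng.normal(size=H)
    out = model.ode_evolve(h, -100.0, -3.0)
    np.testing.assert_array_equal(out, h)


def test_zero_interval_evolution_is_identity(rng):
    model = ODERNNClassifier(_small_config())
    h = rng.normal(size=H)
    np.testing.assert_array_equal(model.ode_evolve(h, -5.0, -5.0), h)


def test_euler_single_step_matches_definition(rng):
    A = 0.1 * rng.normal(size=(H, H))
    model = _linear_field_model(A, solver="euler", max_step=60.0)
    h = rng.normal(size=H)
    out = model.ode_evolve(h, 0.0, 60.0)  # one step of one hour
    np.testing.assert_allclose(out, h + A @ h, atol=1e-12)


def test_solvers_match_matrix_exponential(rng):
    """Linear dynamics have the closed form exp(A dt) h; RK4 and a
    fine-step Euler must both approach it."""
    A = 0.2 * rng.normal(size=(H, H))
    h = rng.normal(size=H)
    dt_min = 90.0
    exact = expm(A * (dt_min / 60.0)) @ h
    rk4 = _linear_field_model(A, "rk4", max_step=15.0).ode_evolve(h, 0.0, dt_min)
    euler_fine = _linear_field_model(A, "euler", max_step=0.05).ode_evolve(
        h, 0.0, dt_min)
    np.testing.assert_allclose(rk4, exact, atol=1e-4)
    np.testing.assert_allclose(euler_fine, exact, atol=1e-3)
    np.testing.assert_allclose(rk4, euler_fine, atol=1e-3)


def test_solver_convergence_orders(rng):
    """Halving the step shrinks the error ~2x for Euler, ~16x for RK4."""
    A = 0.3 * rng.normal(size=(H, H))
    h = rng.normal(size=H)
    exact = expm(A * 2.0) @ h  # 120 minutes = 2 hours
    for solver, lo, hi in (("euler", 1.6, 2.4), ("rk4", 8.0, 24.0)):
        errs = []
        for step in (30.0, 15.0, 7.5):
            out = _linear_field_model(A, solver, step).ode_evolve(h, 0.0, 120.0)
            errs.append(np.abs(out - exact).max())
        for a, b in zip(errs[:-1], errs[1:]):
            assert lo < a / b < hi


def test_evolution_rejects_reversed_interval(rng):
    model = ODERNNClassifier(_small_config())
    with pytest.raises(ValueError):
        model.ode_evolve(rng.normal(size=H), 0.0, -1.0)


def test_gru_update_gate_forced_open_keeps_state(rng):
    model = GRUBaseline(_small_config())
    model.cell.bz.data[:] = 50.0  # update gate ~ 1 -> h' = h
    h = rng.normal(size=H)
    x = rng.normal(size=25)
    m = (rng.random(25) < 0.5).astype(float)
    out = model.gru_update(h, x, m, 10.0)
    np.testing.assert_allclose(out, h, atol=1e-9)


def test_gru_update_gate_forced_closed_gives_candidate(rng):
    model = GRUBaseline(_small_config())
    model.cell.bz.data[:] = -50.0  # update gate ~ 0 -> h' = candidate
    h = rng.normal(size=H)
    x = rng.normal(size=25)
    m = np.ones(25)
    out = model.gru_update(h, x, m, 10.0)
    # recompute the candidate state by hand
    u = np.concatenate([x, m, [10.0 / 60.0]])[None, :]
    r = 1 / (1 + np.exp(-(u @ model.cell.Wr.data + h @ model.cell.Ur.data
                          + model.cell.br.data)))
    cand = np.tanh(u @ model.cell.Wc.data + (r * h) @ model.cell.Uc.data
                   + model.cell.bc.data)
    np.testing.assert_allclose(out, cand[0], atol=1e-9)


def test_gru_update_deterministic_and_shape_checked(rng):
    model = GRUBaseline(_small_config())
    h = rng.normal(size=H)
    x = rng.normal(size=25)
    m = np.ones(25)
    np.testing.assert_array_equal(model.gru_update(h, x, m, 5.0),
                                  model.gru_update(h, x, m, 5.0))
    with pytest.raises(ValueError, match="channels"):
        model.gru_update(h, x[:10], m[:10], 5.0)


def test_single_observation_encode(small_split):
    model = ODERNNClassifier(_small_config())
    p = copy.deepcopy(small_split["train"][0])
    p.times = p.times[:1]
    p.delta_t = p.delta_t[:1]
    p.values = p.values[:1]
    p.mask = p.mask[:1]
    z = model.encode([p])
    assert z.shape == (1, 4)
    assert np.all(np.isfinite(z))


def test_time_shift_invariance(small_split):
    """Autonomous dynamics: only gaps matter, not absolute times."""
    model = ODERNNClassifier(_small_config())
    patients = small_split["train"][:6]
    shifted = [copy.deepcopy(p) for p in patients]
    for p in shifted:
        p.times = p.times - 777.0
    np.testing.assert_array_equal(model.predict_proba(patients),
                                  model.predict_proba(shifted))


def test_predictions_on_simplex(small_split):
    model = ODERNNClassifier(_small_config())
    probs = model.predict_proba(small_split["train"][:20])
    assert np.all(probs >= 0) and np.all(probs <= 1)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_zero_classifier_weights_give_uniform(small_split):
    model = ODERNNClassifier(_small_config())
    for layer in model.f_classifier.layers:
        layer.W.data[:] = 0.0
        layer.b.data[:] = 0.0
    probs = model.predict_proba(small_split["train"][:4])
    np.testing.assert_allclose(probs, 0.25, atol=1e-12)


def test_logit_shift_leaves_argmax_unchanged(small_split):
    model = ODERNNClassifier(_small_config())
    patients = small_split["train"][:10]
    before = model.predict(patients)
    model.f_classifier.layers[-1].b.data += 7.5  # same constant on all logits
    after = model.predict(patients)
    np.testing.assert_array_equal(before, after)


def test_unsorted_observation_times_rejected():
    """Out-of-order observations are a rejected input, not silently used."""
    from ttdml.cohort import LongitudinalSeries

    with pytest.raises(ValueError, match="strictly increasing"):
        LongitudinalSeries(np.array([-5.0, -20.0]), np.zeros((2, 25)),
                           np.zeros((2, 25)))


def test_gru_reduction_equality(small_split):
    """ODE-RNN with a zeroed vector field equals the plain GRU baseline
    bit-for-bit when all shared weights are identical."""
    cfg = _small_config(seed=11)
    ode = ODERNNClassifier(cfg)
    for layer in ode.f_ode.layers:
        layer.W.data[:] = 0.0
        layer.b.data[:] = 0.0
    gru = GRUBaseline(cfg)
    for name in ("cell", "f_static", "f_longitudinal", "f_fusion",
                 "f_classifier"):
        getattr(gru, name).set_weights(getattr(ode, name).get_weights())
    gru.h0.data = ode.h0.data.copy()
    patients = small_split["train"][:20]
    np.testing.assert_array_equal(ode.predict_proba(patients),
                                  gru.predict_proba(patients))


@pytest.mark.parametrize("kind,cls", [("rnn", RNNBaseline),
                                      ("lstm", LSTMBaseline),
                                      ("gru", GRUBaseline),
                                      ("ode_rnn", ODERNNClassifier)])
def test_make_model_and_save_load_round_trip(tmp_path, kind, cls, small_split):
    model = make_model(kind, _small_config())
    assert isinstance(model, cls)
    patients = small_split["train"][:5]
    before = model.predict_proba(patients)
    model.save(tmp_path / "m.npz")
    loaded = type(model).load(tmp_path / "m.npz")
    np.testing.assert_array_equal(loaded.predict_proba(patients), before)


def test_training_deterministic_under_seed(small_split):
    cfg = _small_config(epochs=3, lr=5e-3)
    h1 = make_model("ode_rnn", cfg).fit(small_split["train"])
    h2 = make_model("ode_rnn", cfg).fit(small_split["train"])
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_loss"] == h2["val_loss"]


def test_training_reduces_loss(small_split):
    cfg = _small_config(epochs=6, lr=5e-3, val_fraction=0.0)
    hist = make_model("ode_rnn", cfg).fit(small_split["train"])
    assert hist["train_loss"][-1] < hist["train_loss"][0]


def test_ensemble_identical_seeds_have_zero_sd(small_split):
    from ttdml import evaluate_model

    cfg = _small_config(epochs=2)
    m1 = make_model("ode_rnn", cfg)
    m1.fit(small_split["train"])
    m2 = make_model("ode_rnn", cfg)
    m2.fit(small_split["train"])
    report = evaluate_model([m1, m2], small_split["test"])
    assert report.sd["accuracy4"] == 0.0


def test_ensemble_requires_two_seeds(small_split):
    with pytest.raises(ValueError):
        train_ensemble(small_split["train"], _small_config(), n_seeds=1)
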