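"""Model construction, parameter-count oracles, and the NumPy engine."""

import numpy as np
import pytest

from rteeg.models import ModelSpec, build_model, count_parameters
from rteeg.nn import Adam, make_optimizer


def closed_form_lstm_layer(input_dim: int, units: int) -> int:
    """Independent hand formula: gates hold a kernel (in x 4u), a
    recurrent kernel (u x 4u) and bias (4u)."""
    return 4 * ((input_dim + units + 1) * units)


def test_first_layer_parameter_count_8_channels():
    assert closed_form_lstm_layer(8, 64) == 18688
    model = build_model(
        ModelSpec(architecture="lstm", layer_units=(64,), input_channels=8,
                  input_timesteps=10)
    )
    lstm_layer = model.layers[0]
    assert lstm_layer.n_parameters == 18688


def test_tiny_hand_enumeration():
    """units=(1,), one input channel, two classes:
    4*((1+1+1)*1) + (1+1)*2 = 16 weights."""
    spec = ModelSpec(architecture="lstm", layer_units=(1,), input_channels=1,
                     input_timesteps=4)
    assert count_parameters(spec) == 16
    assert build_model(spec).n_parameters == 16


@pytest.mark.parametrize("arch", ["lstm", "bilstm"])
@pytest.mark.parametrize("units", [(1,), (2,), (4, 2), (2, 4, 1)])
@pytest.mark.parametrize("channels", [1, 2])
def test_closed_form_matches_constructed(arch, units, channels):
    spec = ModelSpec(
        architecture=arch, layer_units=units, input_channels=channels,
        input_timesteps=5,
    )
    assert build_model(spec, rng=3).n_parameters == count_parameters(spec)


def test_bilstm_layer_doubles_lstm_layer():
    """Per layer, the bidirectional variant holds exactly twice the
    parameters of the unidirectional one at equal units, and its output
    width doubles what downstream layers see."""
    lstm = ModelSpec(architecture="lstm", layer_units=(4,), input_channels=3,
                     input_timesteps=5)
    bi = ModelSpec(architecture="bilstm", layer_units=(4,), input_channels=3,
                   input_timesteps=5)
    lstm_layer_params = closed_form_lstm_layer(3, 4)
    assert build_model(lstm).layers[0].n_parameters == lstm_layer_params
    assert build_model(bi).layers[0].n_parameters == 2 * lstm_layer_params
    assert count_parameters(bi) >= count_parameters(lstm)
    # downstream width: dense sees 4 vs 8 features
    assert build_model(lstm).layers[-1].W.shape[0] == 4
    assert build_model(bi).layers[-1].W.shape[0] == 8


def test_forward_pass_outputs_normalized_scores(rng):
    for arch in ("lstm", "bilstm"):
        spec = ModelSpec(architecture=arch, layer_units=(4, 3),
                         input_channels=2, input_timesteps=6)
        model = build_model(spec, rng=0)
        probs = model.forward(rng.standard_normal((5, 6, 2)).astype(np.float32))
        assert probs.shape == (5, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_inference_is_deterministic_despite_dropout(rng):
    spec = ModelSpec(architecture="lstm", layer_units=(4, 3), dropout_rate=0.5,
                     input_channels=2, input_timesteps=6)
    model = build_model(spec, rng=0)
    x = rng.standard_normal((3, 6, 2)).astype(np.float32)
    assert np.array_equal(model.forward(x), model.forward(x))


def test_identical_seed_builds_identical_weights():
    spec = ModelSpec(architecture="bilstm", layer_units=(3,), input_channels=2,
                     input_timesteps=4)
    a, b = build_model(spec, rng=5), build_model(spec, rng=5)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa, pb)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ModelSpec(architecture="gru")
    with pytest.raises(ValueError):
        ModelSpec(layer_units=())
    with pytest.raises(ValueError):
        ModelSpec(dropout_rate=1.0)
    with pytest.raises(ValueError):
        ModelSpec(n_classes=1)
    with pytest.raises(ValueError):
        make_optimizer("adamw", 0.001)


def test_backward_matches_finite_differences(rng):
    """BPTT gradients agree with central finite differences on a small
    bidirectional stack (float64, dropout off)."""
    spec = ModelSpec(architecture="bilstm", layer_units=(4, 3), dropout_rate=0.0,
                     input_channels=2, input_timesteps=6)
    model = build_model(spec, rng=1, dtype=np.float64)
    x = rng.standard_normal((3, 6, 2))
    y = np.eye(2)[rng.integers(2, size=3)]

    def loss():
        p = model.forward(x)
        return -np.mean(np.sum(y * np.log(p + 1e-12), axis=1))

    probs = model.forward(x)
    model._backward_from_probs(probs, y)
    grads = [g.copy() for g in model.grads()]
    for p, g in zip(model.params(), grads):
        for _ in range(3):
            idx = tuple(rng.integers(s) for s in p.shape)
            orig = p[idx]
            eps = 1e-6
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-9)


def test_training_reduces_loss_on_separable_toy(rng):
    """A few Adam epochs on a trivially separable amplitude task cut the
    training loss well below chance."""
    n, t = 60, 12
    y_idx = rng.integers(2, size=n)
    x = rng.standard_normal((n, t, 1)).astype(np.float32)
    x[y_idx == 1] *= 4.0
    y = np.eye(2, dtype=np.float32)[y_idx]
    spec = ModelSpec(architecture="lstm", layer_units=(6,), dropout_rate=0.0,
                     input_channels=1, input_timesteps=t)
    model = build_model(spec, rng=0)
    opt = Adam(0.01)
    train_rng = np.random.default_rng(0)
    first = model.evaluate(x, y)[0]
    for _ in range(15):
        model.train_epoch(x, y, 10, opt, train_rng)
    final_loss, final_acc = model.evaluate(x, y)
    assert final_loss < first
    assert final_acc > 0.9
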