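"""Synthesis optimizer: loss, schedule, step constraint, regularizers, loop."""

import numpy as np
import pytest

import metamerlab as ml
from metamerlab.signals import Signal, ValidationError
from metamerlab.synthesis import (_alpha_norm_grad, _match_loss_grad, _tv_grad,
                                  SynthesisConfig)


@pytest.mark.parametrize("a,b,expected", [
    (np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), 0.0),
    (np.array([3.0, 4.0]), np.array([0.0, 0.0]), 1.0),
    (np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.sqrt(2)),
])
def test_match_loss_values(a, b, expected):
    assert ml.match_loss(a, b) == pytest.approx(expected, abs=1e-12)


def test_match_loss_denominator_modes():
    a = np.array([2.0, 0.0])
    b = np.array([0.0, 1.0])
    assert ml.match_loss(a, b, "reference") == pytest.approx(np.sqrt(5) / 2)
    assert ml.match_loss(a, b, "synthetic") == pytest.approx(np.sqrt(5) / 1)
    assert ml.match_loss(a, b, squared=True) == pytest.approx(5 / 4)
    with pytest.raises(ZeroDivisionError):
        ml.match_loss(np.zeros(3), np.ones(3))


@pytest.mark.parametrize("step,expected", [
    (0, 1.0),
    (2999, 1.0),
    (3000, 0.5),
    (23999, 0.5 ** 7),
])
def test_eta_schedule(step, expected):
    assert ml.eta_schedule(step, SynthesisConfig()) == pytest.approx(expected)


def test_eta_schedule_range():
    with pytest.raises(IndexError):
        ml.eta_schedule(24_000, SynthesisConfig())
    with pytest.raises(IndexError):
        ml.eta_schedule(-1, SynthesisConfig())


@pytest.mark.parametrize("gnorm,rule,expected_norm", [
    (2.0, "rescale_always", 1.0),
    (2.0, "clamp_only", 1.0),
    (0.25, "rescale_always", 1.0),
    (0.25, "clamp_only", 0.25),
])
def test_constrained_step_norms(gnorm, rule, expected_norm):
    sig = Signal(np.full((4, 4, 1), 0.5), "image")
    g = np.zeros((4, 4, 1))
    g[0, 0, 0] = gnorm
    out = ml.constrained_step(sig, g, 1.0, rule)
    assert np.linalg.norm(out.values - sig.values) == pytest.approx(expected_norm)


def test_constrained_step_zero_and_nonfinite():
    sig = Signal(np.full((2, 2, 1), 0.5), "image")
    out = ml.constrained_step(sig, np.zeros((2, 2, 1)), 1.0)
    np.testing.assert_array_equal(out.values, sig.values)
    bad = np.full((2, 2, 1), np.nan)
    with pytest.raises(FloatingPointError):
        ml.constrained_step(sig, bad, 1.0)


def test_constrained_step_clip():
    sig = Signal(np.full((2, 2, 1), 0.9), "image")
    g = -np.ones((2, 2, 1))
    out = ml.constrained_step(sig, g, 10.0, "rescale_always", clip_to_range=True)
    assert out.values.max() <= 1.0


def test_init_signal_moments():
    big = (1000, 1000)
    img = ml.init_signal("image", big, seed=0).values
    assert abs(img.mean() - 0.5) < 1e-3
    assert abs(img.std() - 0.05) < 1e-3
    aud = ml.init_signal("audio", (10 ** 6,), seed=1).values
    assert abs(aud.mean()) < 1e-9
    assert abs(aud.std() - 1e-7) < 1e-9
    again = ml.init_signal("image", big, seed=0).values
    np.testing.assert_array_equal(img, again)


def test_tv_regularizer_values():
    assert ml.tv_regularizer(np.full((3, 3), 2.0)) == 0.0
    assert ml.tv_regularizer(np.array([[0.0, 1.0]])) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        ml.tv_regularizer(np.zeros(5))


def test_tv_regularizer_bruteforce_oracle():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(8, 8))
    z = x - x.mean()
    total = 0.0
    for i in range(8):
        for j in range(8):
            if j + 1 < 8:
                total += (z[i, j + 1] - z[i, j]) ** 2
            if i + 1 < 8:
                total += (z[i + 1, j] - z[i, j]) ** 2
    assert ml.tv_regularizer(x) == pytest.approx(total, abs=1e-10)


@pytest.mark.parametrize("x,alpha,expected", [
    (np.full(5, 3.0), 6.0, 0.0),
    (np.array([2.0, 0.0]), 6.0, 2.0 ** (1 / 6)),
    (np.array([3.0, -3.0]), 2.0, np.sqrt(18.0)),
])
def test_alpha_norm_values(x, alpha, expected):
    assert ml.alpha_norm_regularizer(x, alpha) == pytest.approx(expected, abs=1e-9)


def test_regularized_objective_degenerate_equals_match_loss():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=12), rng.normal(size=12)
    sig = rng.normal(size=(3, 4))
    cfg = SynthesisConfig(lambda_tv=0.0, lambda_alpha=0.0)
    assert ml.regularized_objective(a, b, sig, cfg) == ml.match_loss(a, b)


def test_regularized_preset_coefficients():
    c1 = SynthesisConfig.regularized(1)
    assert c1.lambda_alpha == 0.005
    assert c1.eta_init == 16.0
    assert c1.clip_to_range is True
    tiers = [SynthesisConfig.regularized(t).lambda_tv for t in (1, 2, 3)]
    assert tiers[1] == pytest.approx(10 * tiers[0])
    assert tiers[2] == pytest.approx(100 * tiers[0])


def _numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def test_regularizer_gradients_match_finite_differences():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(5, 5))
    np.testing.assert_allclose(_tv_grad(x), _numeric_grad(ml.tv_regularizer, x),
                               atol=1e-6)
    fn = lambda v: ml.alpha_norm_regularizer(v, 6.0)
    np.testing.assert_allclose(_alpha_norm_grad(x, 6.0), _numeric_grad(fn, x),
                               atol=1e-6)


def test_match_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(1, 7))
    Ap = rng.normal(size=(1, 7))
    for mode in ("reference", "synthetic"):
        for sq in (False, True):
            _, g = _match_loss_grad(A, Ap, mode, sq)
            fn = lambda v: ml.match_loss(A[0], v, mode, sq)
            np.testing.assert_allclose(g[0], _numeric_grad(fn, Ap[0].copy()),
                                       atol=1e-6)


def test_synthesize_fixed_point(image_model8):
    """Starting at the reference: zero loss at step 0, output stays put."""
    ref = ml.generate_stimuli("image", 1, seed=9).signals[0]
    cfg = SynthesisConfig(total_steps=40, decay_interval=10, seed=0)
    cand = ml.synthesize_metamer(image_model8, "relu0", ref, cfg, x0=ref.values)
    assert cand.trace.loss[0] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(cand.signal.values, ref.values, atol=1e-9)


def test_synthesize_early_stage_converges(image_model8):
    refs = ml.generate_stimuli("image", 1, seed=10)
    cfg = SynthesisConfig(seed=1).scaled(24)  # 1,000 steps
    cands = ml.synthesize_batch(image_model8, "relu0", refs.stack()[:4], cfg)
    for c in cands:
        assert c.trace.loss[-1] < 0.05


def test_schedule_exactness_and_step_norm_bound(image_model8):
    refs = ml.generate_stimuli("image", 1, seed=11)
    cfg = SynthesisConfig(total_steps=300, decay_interval=50, seed=2)
    cand = ml.synthesize_batch(image_model8, "relu1", refs.stack()[:1], cfg)[0]
    expected = np.array([ml.eta_schedule(t, cfg) for t in range(300)])
    np.testing.assert_array_equal(cand.trace.eta, expected)
    assert cand.trace.iterations == 300
    assert np.all(cand.trace.step_norms <= cand.trace.eta + 1e-9)


def test_loss_trend_downward(image_model8):
    refs = ml.generate_stimuli("image", 1, seed=12)
    cfg = SynthesisConfig(seed=3).scaled(12)  # 2,000 steps
    cand = ml.synthesize_batch(image_model8, "relu1", refs.stack()[:1], cfg)[0]
    lead = cand.trace.loss[:1000].mean()
    trail = cand.trace.loss[-1000:].mean()
    assert trail < lead


def test_final_stage_metamer_label_matches_but_signal_differs(image_model8):
    refs = ml.generate_stimuli("image", 1, seed=13)
    batch = refs.stack()
    cfg = SynthesisConfig(seed=4).scaled(12)
    cands = ml.synthesize_batch(image_model8, "final", batch, cfg)
    synth = np.stack([c.signal.values for c in cands])
    assert np.array_equal(image_model8.predict(synth), image_model8.predict(batch))
    cors = [np.corrcoef(s.ravel(), r.ravel())[0, 1] for s, r in zip(synth, batch)]
    assert np.mean(cors) < 0.5


def test_regularized_synthesis_runs(image_model8):
    refs = ml.generate_stimuli("image", 1, seed=14)
    cfg = SynthesisConfig.regularized(1, total_steps=150, decay_interval=25, seed=5)
    cand = ml.synthesize_batch(image_model8, "relu0", refs.stack()[:1], cfg)[0]
    assert np.all(np.isfinite(cand.trace.loss))
    assert cand.signal.values.min() >= 0.0 and cand.signal.values.max() <= 1.0


def test_config_validation():
    with pytest.raises(ValidationError):
        SynthesisConfig(total_steps=0)
    with pytest.raises(ValidationError):
        SynthesisConfig(decay_factor=1.5)
    with pytest.raises(ValidationError):
        SynthesisConfig(step_rule="newton")
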