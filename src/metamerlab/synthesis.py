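"""Metamer synthesis: gradient descent on the input signal.

The synthesized signal is optimized so that its activations A′ at a chosen
model stage match those of a natural reference A, by minimizing the
normalized Euclidean distance ‖A−A′‖/‖A‖ (optionally squared, optionally
normalized by ‖A′‖ instead).  Each descent step has a bounded L2 norm η that
follows a stair-step decay schedule; model weights stay frozen throughout.

An optional regularized mode adds an α-norm and a total-variation penalty on
the (model-normalized) image and uses a 16× larger initial step size — useful
for probing whether natural-signal priors change metamer appearance, at some
cost in activation-match fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import StagedModel, _acts
from .signals import Signal, ValidationError

__all__ = [
    "SynthesisConfig",
    "SynthesisTrace",
    "MetamerCandidate",
    "SynthesisError",
    "match_loss",
    "eta_schedule",
    "constrained_step",
    "init_signal",
    "tv_regularizer",
    "alpha_norm_regularizer",
    "regularized_objective",
    "synthesize_metamer",
    "synthesize_batch",
]

# Default initialization moments per modality: images start as faint gray
# noise around mid-range, audio as near-silence.
INIT_MOMENTS = {"image": (0.5, 0.05), "audio": (0.0, 1e-7)}

TV_LAMBDA_BASE = 5e-6  # base TV coefficient; tiers are 1x / 10x / 100x


@dataclass
class SynthesisConfig:
    """All knobs of the synthesis optimizer.

    ``total_steps`` iterations of constrained gradient descent; the step-norm
    bound starts at ``eta_init`` and is multiplied by ``decay_factor`` every
    ``decay_interval`` steps.
    """

    total_steps: int = 24_000
    eta_init: float = 1.0
    decay_factor: float = 0.5
    decay_interval: int = 3_000
    init_mean: float | None = None   # None -> per-modality default
    init_std: float | None = None
    step_rule: str = "rescale_always"  # or "clamp_only"
    relu_override: bool = True
    clip_to_range: bool = False
    squared_loss: bool = False
    lambda_tv: float = 0.0
    lambda_alpha: float = 0.0
    alpha: float = 6.0
    denominator_mode: str = "reference"  # or "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.total_steps <= 0:
            raise ValidationError("total_steps must be positive")
        if self.decay_interval <= 0:
            raise ValidationError("decay_interval must be positive")
        if not 0 < self.decay_factor <= 1:
            raise ValidationError("decay_factor must be in (0, 1]")
        if self.step_rule not in ("rescale_always", "clamp_only"):
            raise ValidationError(f"unknown step_rule {self.step_rule!r}")
        if self.denominator_mode not in ("reference", "synthetic"):
            raise ValidationError(f"unknown denominator_mode {self.denominator_mode!r}")

    @classmethod
    def regularized(cls, tv_tier: int = 1, **kw) -> "SynthesisConfig":
        """Regularized preset: λ_α = 0.005, λ_TV tier 1/2/3 = 1×/10×/100× of
        the base coefficient, ‖A′‖ denominator, 16× initial step size, and
        clipping to the image range."""
        if tv_tier not in (1, 2, 3):
            raise ValidationError("tv_tier must be 1, 2 or 3")
        defaults = dict(
            eta_init=16.0,
            clip_to_range=True,
            lambda_alpha=0.005,
            lambda_tv=TV_LAMBDA_BASE * 10 ** (tv_tier - 1),
            denominator_mode="synthetic",
        )
        defaults.update(kw)
        return cls(**defaults)

    def scaled(self, factor: int) -> "SynthesisConfig":
        """Schedule scaled down ``factor``×, preserving the η plateau ladder
        (e.g. factor 12: 24,000→2,000 steps, decay every 250)."""
        return replace(self, total_steps=self.total_steps // factor,
                       decay_interval=self.decay_interval // factor)


@dataclass
class SynthesisTrace:
    loss: np.ndarray          # objective value at each step (before update)
    eta: np.ndarray           # step-norm bound per step
    step_norms: np.ndarray    # realized ‖Δ‖₂ per step

    def __post_init__(self):
        self.loss = np.asarray(self.loss, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.step_norms = np.asarray(self.step_norms, dtype=np.float64)

    @property
    def iterations(self) -> int:
        return self.loss.size


@dataclass
class MetamerCandidate:
    signal: Signal
    reference: Signal
    stage: str
    trace: SynthesisTrace

    def __post_init__(self):
        if self.signal.shape != self.reference.shape:
            raise ValidationError("candidate and reference shape mismatch")


class SynthesisError(RuntimeError):
    """Optimization diverged to non-finite values; carries the partial trace."""

    def __init__(self, message: str, trace: SynthesisTrace | None = None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Loss, schedule, steps, init
# ---------------------------------------------------------------------------

def match_loss(reference_acts, synth_acts, denominator_mode: str = "reference",
               squared: bool = False) -> float:
    """Normalized activation distance ‖A−A′‖ / ‖denominator‖ (flattened)."""
    a = _acts(reference_acts).ravel()
    b = _acts(synth_acts).ravel()
    if a.shape != b.shape:
        raise ValidationError("activation shape mismatch")
    denom_arr = a if denominator_mode == "reference" else b
    d = np.linalg.norm(denom_arr)
    if d == 0:
        raise ZeroDivisionError("zero-norm denominator in match loss")
    ratio = np.linalg.norm(a - b) / d
    return float(ratio ** 2 if squared else ratio)


def _match_loss_grad(A: np.ndarray, Ap: np.ndarray, denominator_mode: str,
                     squared: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample loss values and gradient w.r.t. A′ for batched activations
    (leading axis = sample; each sample's loss uses its own flattened norm)."""
    n_samp = A.shape[0]
    Af = A.reshape(n_samp, -1)
    Apf = Ap.reshape(n_samp, -1)
    diff = Apf - Af
    n = np.linalg.norm(diff, axis=1)
    d = np.linalg.norm(Af if denominator_mode == "reference" else Apf, axis=1)
    d = np.where(d == 0, np.inf, d)
    loss = n / d
    safe_n = np.where(n == 0, 1.0, n)
    g = diff / (safe_n * d)[:, None]
    g[n == 0] = 0.0
    if denominator_mode == "synthetic":
        safe_d = np.where(np.isinf(d), 1.0, d)
        g = g - (n / safe_d ** 2)[:, None] * (Apf / safe_d[:, None])
    if squared:
        g = 2.0 * loss[:, None] * g
        loss = loss ** 2
    return loss, g.reshape(Ap.shape)


def eta_schedule(step: int, config: SynthesisConfig) -> float:
    """η(t) = η₀ · decay^⌊t / interval⌋."""
    if not 0 <= step < config.total_steps:
        raise IndexError(f"step {step} outside [0, {config.total_steps})")
    return config.eta_init * config.decay_factor ** (step // config.decay_interval)


def constrained_step(signal: Signal, gradient: np.ndarray, eta: float,
                     step_rule: str = "rescale_always",
                     clip_to_range: bool = False) -> Signal:
    """Apply one descent update Δ = −g with an L2 norm constraint.

    ``rescale_always`` forces ‖Δ‖ = η exactly (zero gradient leaves the
    signal unchanged); ``clamp_only`` caps ‖Δ‖ at η without boosting small
    gradients.
    """
    g = np.asarray(gradient, dtype=np.float64)
    if g.shape != signal.values.shape:
        raise ValidationError("gradient shape mismatch")
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient")
    norm = np.linalg.norm(g)
    if norm == 0:
        new = signal.values.copy()
    else:
        scale = eta / norm if step_rule == "rescale_always" else min(1.0, eta / norm)
        new = signal.values - scale * g
    if clip_to_range:
        new = np.clip(new, 0.0, 1.0)
    return Signal(new, signal.modality, signal.sample_rate)


def init_signal(modality: str, shape: tuple, config: SynthesisConfig | None = None,
                seed: int | None = None) -> Signal:
    """I.i.d. normal initialization with per-modality default moments."""
    config = config or SynthesisConfig()
    if modality not in INIT_MOMENTS:
        raise ValidationError(f"unknown modality {modality!r}")
    mean_d, std_d = INIT_MOMENTS[modality]
    mean = config.init_mean if config.init_mean is not None else mean_d
    std = config.init_std if config.init_std is not None else std_d
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return Signal(rng.normal(mean, std, size=shape), modality)


# ---------------------------------------------------------------------------
# Regularizers (inputs are model-normalized signals)
# ---------------------------------------------------------------------------

def tv_regularizer(signal_normalized: np.ndarray) -> float:
    """Σ over in-bounds neighbor pairs of squared horizontal and vertical
    differences of the mean-subtracted image (channels summed)."""
    z = _centered_2d(signal_normalized)
    dh = z[:, 1:, :] - z[:, :-1, :]
    dv = z[1:, :, :] - z[:-1, :, :]
    return float(np.sum(dh ** 2) + np.sum(dv ** 2))


def _centered_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValidationError("TV regularizer needs a 2-D (or H×W×C) array")
    return x - x.mean()


def _tv_grad(signal_normalized: np.ndarray) -> np.ndarray:
    z = _centered_2d(signal_normalized)
    g = np.zeros_like(z)
    dh = z[:, 1:, :] - z[:, :-1, :]
    dv = z[1:, :, :] - z[:-1, :, :]
    g[:, 1:, :] += 2 * dh
    g[:, :-1, :] -= 2 * dh
    g[1:, :, :] += 2 * dv
    g[:-1, :, :] -= 2 * dv
    # gradient sums to zero, so centering contributes nothing extra
    return g.reshape(np.shape(signal_normalized))


def alpha_norm_regularizer(signal_normalized: np.ndarray, alpha: float = 6.0) -> float:
    """α-norm of the mean-subtracted flattened signal."""
    if alpha < 1:
        raise ValidationError("alpha must be >= 1")
    z = np.asarray(signal_normalized, dtype=np.float64).ravel()
    z = z - z.mean()
    return float(np.sum(np.abs(z) ** alpha) ** (1.0 / alpha))


def _alpha_norm_grad(signal_normalized: np.ndarray, alpha: float) -> np.ndarray:
    x = np.asarray(signal_normalized, dtype=np.float64)
    z = x.ravel() - x.mean()
    s = np.sum(np.abs(z) ** alpha)
    if s == 0:
        return np.zeros_like(x)
    g = np.sign(z) * np.abs(z) ** (alpha - 1) * s ** (1.0 / alpha - 1.0)
    g = g - g.mean()  # chain through the mean subtraction
    return g.reshape(x.shape)


def regularized_objective(reference_acts, synth_acts, signal_normalized,
                          config: SynthesisConfig) -> float:
    """match_loss + λ_α·R_α + λ_TV·R_TV; equals match_loss when both λ = 0."""
    if config.lambda_alpha < 0 or config.lambda_tv < 0:
        raise ValidationError("regularizer coefficients must be >= 0")
    total = match_loss(reference_acts, synth_acts, config.denominator_mode,
                       config.squared_loss)
    if config.lambda_alpha > 0:
        total += config.lambda_alpha * alpha_norm_regularizer(signal_normalized,
                                                              config.alpha)
    if config.lambda_tv > 0:
        total += config.lambda_tv * tv_regularizer(signal_normalized)
    return float(total)


# ---------------------------------------------------------------------------
# The synthesis loop
# ---------------------------------------------------------------------------

def synthesize_batch(model: StagedModel, stage: str, references: np.ndarray,
                     config: SynthesisConfig, x0: np.ndarray | None = None,
                     ) -> list[MetamerCandidate]:
    """Synthesize metamers for a batch of references in lockstep.

    Every sample follows its own constrained descent (per-sample step norms);
    batching only amortizes the forward/backward passes.  ``x0`` overrides
    the random initialization (e.g. to start at the references themselves).
    """
    refs = np.asarray(references, dtype=np.float64)
    n = refs.shape[0]
    sig_shape = refs.shape[1:]
    ref_acts = model.stage_activations(refs, stage)
    use_reg = config.lambda_alpha > 0 or config.lambda_tv > 0
    if use_reg and model.modality != "image" and config.lambda_tv > 0:
        raise ValidationError("TV regularization requires image signals")
    norm_mean, norm_std = model.normalization()

    if x0 is None:
        x = np.stack([
            init_signal(model.modality, sig_shape, config, seed=config.seed + i).values
            for i in range(n)])
    else:
        x = np.asarray(x0, dtype=np.float64).copy()
        if x.shape != refs.shape:
            raise ValidationError("x0 shape mismatch")

    steps = config.total_steps
    losses = np.empty((n, steps))
    etas = np.empty(steps)
    step_norms = np.empty((n, steps))

    def loss_and_grad(acts):
        return _match_loss_grad(ref_acts, acts, config.denominator_mode,
                                config.squared_loss)

    grad_holder = {}

    def grad_fn(acts):
        lv, g = loss_and_grad(acts)
        grad_holder["loss"] = lv
        return g

    flat = lambda a: a.reshape(n, -1)
    for t in range(steps):
        eta = eta_schedule(t, config)
        _, gx = model.stage_forward_backward(x, stage, grad_fn,
                                             relu_override=config.relu_override)
        loss_t = grad_holder["loss"].copy()
        if use_reg:
            for i in range(n):
                xi_norm = (x[i] - _chan(norm_mean, x[i])) / _chan(norm_std, x[i])
                jac = 1.0 / _chan(norm_std, x[i])
                if config.lambda_alpha > 0:
                    loss_t[i] += config.lambda_alpha * alpha_norm_regularizer(
                        xi_norm, config.alpha)
                    gx[i] += config.lambda_alpha * _alpha_norm_grad(
                        xi_norm, config.alpha) * jac
                if config.lambda_tv > 0:
                    loss_t[i] += config.lambda_tv * tv_regularizer(xi_norm)
                    gx[i] += config.lambda_tv * _tv_grad(xi_norm) * jac
        if not np.all(np.isfinite(loss_t)) or not np.all(np.isfinite(gx)):
            trace = SynthesisTrace(losses[0, :t], etas[:t], step_norms[0, :t])
            raise SynthesisError(f"synthesis diverged at step {t}", trace)
        losses[:, t] = loss_t
        etas[t] = eta
        gnorm = np.linalg.norm(flat(gx), axis=1)
        if config.step_rule == "rescale_always":
            scale = np.where(gnorm > 0, eta / np.where(gnorm == 0, 1, gnorm), 0.0)
        else:
            scale = np.minimum(1.0, eta / np.where(gnorm == 0, np.inf, gnorm))
        delta = -gx * scale.reshape((n,) + (1,) * (gx.ndim - 1))
        step_norms[:, t] = np.linalg.norm(flat(delta), axis=1)
        x = x + delta
        if config.clip_to_range and model.modality == "image":
            x = np.clip(x, 0.0, 1.0)

    out = []
    for i in range(n):
        trace = SynthesisTrace(losses[i], etas, step_norms[i])
        out.append(MetamerCandidate(
            Signal(x[i], model.modality, model.sample_rate),
            Signal(refs[i], model.modality, model.sample_rate),
            stage, trace))
    return out


def _chan(arr: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Broadcast per-channel stats over an H×W×C (or flat audio) signal."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 0 or a.size == 1:
        return a.reshape(())
    return a.reshape((1,) * (like.ndim - 1) + (a.size,))


def synthesize_metamer(model: StagedModel, stage: str, reference: Signal,
                       config: SynthesisConfig | None = None,
                       x0: np.ndarray | None = None) -> MetamerCandidate:
    """Synthesize a single metamer (see :func:`synthesize_batch`)."""
    config = config or SynthesisConfig()
    if reference.modality != model.modality:
        raise ValidationError("reference modality does not match model")
    x0b = None if x0 is None else np.asarray(x0)[None]
    return synthesize_batch(model, stage, reference.values[None], config, x0=x0b)[0]
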