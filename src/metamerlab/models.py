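"""Staged differentiable models and synthetic stimulus sets.

A :class:`StagedModel` is an ordered sequence of named layers with a declared
subset of *stages*: cut points where the model's output depends on the input
only through that stage's activations.  Metamers are only meaningful at such
cut points — matching the activations there pins down everything downstream.

The toy zoo provides small convolutional image and audio models (random or
briefly trained) plus parametric stimulus generators, so the full synthesis /
certification / transfer / encoding pipeline can run end to end on a laptop
with no external checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin

from . import nn
from .signals import DEFAULT_SAMPLE_RATE, Signal, StimulusSet, ValidationError

IMAGE_CLASS_VOCAB = ["disk", "square", "cross", "stripes", "ring", "checker",
                     "triangle", "corners"]
AUDIO_CLASS_VOCAB = ["tone", "chirp", "am_noise", "harmonic", "noise", "click_train"]

IMAGE_SIZE = 16
AUDIO_LENGTH = 1600

# Auditory front-end configuration: a fixed bandpass filterbank with envelope
# extraction and compressive nonlinearity.  Free choices (the exact biological
# cochleagram is not reproduced): 32 channels, power-law exponent 0.3.
FRONTEND_N_CHANNELS = 32
FRONTEND_KERNEL = 101
FRONTEND_LOWPASS_KERNEL = 33
FRONTEND_LOWPASS_CUTOFF = 400.0
FRONTEND_DOWNSAMPLE = 8
FRONTEND_COMPRESSION = 0.3
FRONTEND_FMIN, FRONTEND_FMAX = 200.0, 8000.0


class StageNotFoundError(KeyError):
    pass


@dataclass
class ActivationArray:
    """Activations of one model stage for one or more inputs."""

    values: np.ndarray
    stage_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite activations at stage {self.stage_name!r}")


def _acts(a) -> np.ndarray:
    return a.values if isinstance(a, ActivationArray) else np.asarray(a, dtype=np.float64)


class StagedModel:
    """Sequence of named layers with designated stage cut points.

    Parameters
    ----------
    layers : list of (name, Layer)
    stage_names : ordered list of layer names that are valid metamer stages
    modality : "image" or "audio"
    classifier_labels : class vocabulary of the final stage, or None
    """

    def __init__(self, layers, stage_names, modality, input_shape,
                 classifier_labels=None, sample_rate=DEFAULT_SAMPLE_RATE, name="toy"):
        self.layers = list(layers)
        names = [n for n, _ in self.layers]
        for s in stage_names:
            if s not in names:
                raise StageNotFoundError(s)
        self.stage_names = list(stage_names)
        self.modality = modality
        self.input_shape = tuple(input_shape)
        self.classifier_labels = list(classifier_labels) if classifier_labels else None
        self.sample_rate = sample_rate
        self.name = name

    # -- batch layout conversion -------------------------------------------
    def _to_internal(self, batch: np.ndarray) -> np.ndarray:
        if self.modality == "image":  # (N,H,W,C) -> (N,C,H,W)
            return np.transpose(batch, (0, 3, 1, 2))
        return batch[:, None, :]  # (N,T) -> (N,1,T)

    def _grad_to_user(self, grad: np.ndarray) -> np.ndarray:
        if self.modality == "image":
            return np.transpose(grad, (0, 2, 3, 1))
        return grad[:, 0, :]

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.shape[1:] != self.input_shape:
            raise ValidationError(
                f"input shape {batch.shape[1:]} != model input {self.input_shape}")
        if not np.all(np.isfinite(batch)):
            raise ValidationError("non-finite model input")
        return batch

    def _layer(self, name: str) -> nn.Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise StageNotFoundError(name)

    # -- forward / backward -------------------------------------------------
    def forward_to(self, batch: np.ndarray, stage: str | None = None) -> np.ndarray:
        """Run layers up to and including ``stage`` (or all layers)."""
        if stage is not None and stage not in (n for n, _ in self.layers):
            raise StageNotFoundError(stage)
        x = self._to_internal(self._check_batch(batch))
        for name, layer in self.layers:
            x = layer.forward(x)
            if name == stage:
                return x
        return x

    def stage_activations(self, batch: np.ndarray, stage: str) -> np.ndarray:
        if stage not in self.stage_names:
            raise StageNotFoundError(stage)
        return self.forward_to(batch, stage)

    def all_stage_activations(self, batch: np.ndarray) -> dict[str, np.ndarray]:
        x = self._to_internal(self._check_batch(batch))
        out = {}
        for name, layer in self.layers:
            x = layer.forward(x)
            if name in self.stage_names:
                out[name] = x
        return out

    def logits(self, batch: np.ndarray) -> np.ndarray:
        return self.forward_to(batch, None)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(batch), axis=-1)

    def predict_names(self, batch: np.ndarray) -> list[str]:
        if self.classifier_labels is None:
            raise ValidationError("model has no classifier head")
        return [self.classifier_labels[i] for i in self.predict(batch)]

    def input_gradient(self, batch: np.ndarray, stage: str,
                       grad_at_stage: np.ndarray, relu_override: bool = False
                       ) -> np.ndarray:
        """Backpropagate ``grad_at_stage`` from a stage to the input.

        With ``relu_override``, a rectifier *at the matched stage* passes
        gradients as identity; all earlier rectifiers behave normally.
        """
        if stage not in self.stage_names:
            raise StageNotFoundError(stage)
        x = self._to_internal(self._check_batch(batch))
        prefix = []
        for name, layer in self.layers:
            x = layer.forward(x)
            prefix.append((name, layer))
            if name == stage:
                break
        g = np.asarray(grad_at_stage, dtype=np.float64)
        stage_layer = prefix[-1][1]
        is_relu = isinstance(stage_layer, nn.ReLU)
        if is_relu and relu_override:
            stage_layer.override = True
        try:
            for _, layer in reversed(prefix):
                g = layer.backward(g)
        finally:
            if is_relu:
                stage_layer.override = False
        return self._grad_to_user(g)

    def stage_forward_backward(self, batch: np.ndarray, stage: str, grad_fn,
                               relu_override: bool = False):
        """One forward pass to ``stage``; ``grad_fn(acts) -> grad_at_stage``;
        one backward pass.  Returns (stage activations, input gradient).

        Avoids the double forward of calling ``stage_activations`` and
        ``input_gradient`` separately — synthesis calls this every step.
        """
        if stage not in self.stage_names:
            raise StageNotFoundError(stage)
        x = self._to_internal(self._check_batch(batch))
        prefix = []
        for name, layer in self.layers:
            x = layer.forward(x)
            prefix.append(layer)
            if name == stage:
                break
        acts = x
        g = np.asarray(grad_fn(acts), dtype=np.float64)
        stage_layer = prefix[-1]
        is_relu = isinstance(stage_layer, nn.ReLU)
        if is_relu and relu_override:
            stage_layer.override = True
        try:
            for layer in reversed(prefix):
                g = layer.backward(g)
        finally:
            if is_relu:
                stage_layer.override = False
        return acts, self._grad_to_user(g)

    def normalization(self):
        """(mean, std) of the model's Normalize layer, or (0, 1) if absent."""
        for _, layer in self.layers:
            if isinstance(layer, nn.Normalize):
                return layer.mean, layer.std
        return np.zeros(1), np.ones(1)

    # -- training support ---------------------------------------------------
    def trainable_layers(self):
        return [l for _, l in self.layers if l.trainable]

    def descriptor(self) -> dict:
        return {
            "name": self.name,
            "modality": self.modality,
            "input_shape": list(self.input_shape),
            "stage_names": self.stage_names,
            "classifier_labels": self.classifier_labels,
            "sample_rate": self.sample_rate,
        }


def forward_activations(model: StagedModel, signal: Signal, stage: str) -> ActivationArray:
    """Activations of ``stage`` for a single signal (batch axis squeezed)."""
    if signal.modality != model.modality:
        raise ValidationError("signal modality does not match model")
    acts = model.stage_activations(signal.values[None], stage)
    return ActivationArray(acts[0], stage_name=stage)


# ---------------------------------------------------------------------------
# Auditory front end
# ---------------------------------------------------------------------------

def _frontend_filters(sample_rate: int = DEFAULT_SAMPLE_RATE):
    """Fixed FIR bandpass bank (log-spaced centers) and envelope lowpass."""
    centers = np.geomspace(FRONTEND_FMIN, FRONTEND_FMAX, FRONTEND_N_CHANNELS)
    nyq = sample_rate / 2.0
    bank = np.zeros((FRONTEND_N_CHANNELS, 1, FRONTEND_KERNEL))
    for i, fc in enumerate(centers):
        lo = max(fc / 2 ** 0.25, 10.0)
        hi = min(fc * 2 ** 0.25, nyq * 0.99)
        bank[i, 0] = firwin(FRONTEND_KERNEL, [lo / nyq, hi / nyq], pass_zero=False)
    lp = firwin(FRONTEND_LOWPASS_KERNEL, FRONTEND_LOWPASS_CUTOFF / nyq)
    return bank, lp, centers


def frontend_layers(sample_rate: int = DEFAULT_SAMPLE_RATE):
    """Differentiable cochlea-inspired front end as a list of named layers:
    bandpass filterbank -> half-wave rectification -> lowpass -> downsample
    -> power-law compression."""
    bank, lowpass, _ = _frontend_filters(sample_rate)
    return [
        ("fb_bandpass", nn.Conv1d(1, FRONTEND_N_CHANNELS, FRONTEND_KERNEL,
                                  weight=bank, frozen=True)),
        ("fb_rectify", nn.ReLU()),
        ("fb_lowpass", nn.SharedKernelConv1d(lowpass)),
        ("fb_downsample", nn.Downsample1d(FRONTEND_DOWNSAMPLE)),
        ("cochleagram", nn.PowerCompress(FRONTEND_COMPRESSION)),
    ]


def filterbank_frontend(waveform: Signal,
                        sample_rate: int = DEFAULT_SAMPLE_RATE) -> ActivationArray:
    """Time×frequency representation of a waveform through the front end."""
    if waveform.modality != "audio":
        raise ValidationError("filterbank_frontend expects audio")
    if waveform.sample_rate != sample_rate:
        raise ValidationError(
            f"sample rate {waveform.sample_rate} != configured {sample_rate}")
    x = waveform.values[None, None, :]
    for _, layer in frontend_layers(sample_rate):
        x = layer.forward(x)
    return ActivationArray(x[0].T, stage_name="cochleagram")  # (time, freq)


# ---------------------------------------------------------------------------
# Stimulus generators
# ---------------------------------------------------------------------------

def _image_proto(cls: str, size: int, cx: float, cy: float, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    s = size / 4.0
    if cls == "disk":
        img = (r < s).astype(float)
    elif cls == "square":
        img = ((np.abs(xx - cx) < s) & (np.abs(yy - cy) < s)).astype(float)
    elif cls == "cross":
        img = ((np.abs(xx - cx) < s / 2.5) | (np.abs(yy - cy) < s / 2.5)).astype(float)
        img *= ((np.abs(xx - cx) < s * 1.4) & (np.abs(yy - cy) < s * 1.4))
    elif cls == "stripes":
        phase = rng.uniform(0, np.pi)
        img = 0.5 + 0.5 * np.sin(2 * np.pi * yy / 4.0 + phase)
    elif cls == "ring":
        img = ((r < s) & (r > s / 2.0)).astype(float)
    elif cls == "checker":
        img = (((xx // 2) + (yy // 2)) % 2).astype(float)
    elif cls == "triangle":
        img = ((yy - cy > -s) & (np.abs(xx - cx) < (yy - cy + s) / 2.0)
               & (yy - cy < s)).astype(float)
    elif cls == "corners":
        img = (((np.abs(xx - cx) > size / 2 - s / 1.5)
                & (np.abs(yy - cy) > size / 2 - s / 1.5))).astype(float)
    else:
        raise ValidationError(f"unknown image class {cls!r}")
    return img


def _audio_proto(cls: str, t: np.ndarray, rng) -> np.ndarray:
    if cls == "tone":
        f = 500.0 * 2 ** rng.uniform(-0.2, 0.2)
        return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if cls == "chirp":
        f0 = 300.0 * 2 ** rng.uniform(-0.2, 0.2)
        return np.sin(2 * np.pi * f0 * t * (1 + 8.0 * t / t[-1] / 2))
    if cls == "am_noise":
        fm = 30.0 * 2 ** rng.uniform(-0.3, 0.3)
        carrier = rng.normal(size=t.size)
        return carrier * (0.5 + 0.5 * np.sin(2 * np.pi * fm * t))
    if cls == "harmonic":
        f0 = 200.0 * 2 ** rng.uniform(-0.15, 0.15)
        sig = sum(np.sin(2 * np.pi * f0 * k * t + rng.uniform(0, 2 * np.pi)) / k
                  for k in range(1, 6))
        return np.asarray(sig)
    if cls == "noise":
        return rng.normal(size=t.size)
    if cls == "click_train":
        sig = np.zeros(t.size)
        period = int(t.size / 8 * 2 ** rng.uniform(-0.2, 0.2))
        sig[rng.integers(0, period)::period] = 1.0
        return sig
    raise ValidationError(f"unknown audio class {cls!r}")


def generate_stimuli(modality: str, n_per_class: int, classes: list[str] | None = None,
                     seed: int = 0, noise_std: float = 0.05) -> StimulusSet:
    """Class-balanced parametric stimulus set with jitter and additive noise.

    Images are shape silhouettes with positional jitter on a gray background;
    audio are tone/chirp/noise-like tokens with frequency jitter.  Identical
    (arguments, seed) give identical sets.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if classes is None:
        classes = (IMAGE_CLASS_VOCAB[:4] if modality == "image"
                   else AUDIO_CLASS_VOCAB[:4])
    if len(classes) == 0:
        raise ValidationError("empty class list")
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    if modality == "image":
        size = IMAGE_SIZE
        for ci, cls in enumerate(classes):
            for _ in range(n_per_class):
                cx = size / 2 + rng.uniform(-2, 2)
                cy = size / 2 + rng.uniform(-2, 2)
                img = _image_proto(cls, size, cx, cy, rng)
                img = 0.2 + 0.6 * img + rng.normal(0, noise_std, img.shape)
                signals.append(Signal(np.clip(img, 0, 1)[:, :, None], "image"))
                labels.append(ci)
    elif modality == "audio":
        t = np.arange(AUDIO_LENGTH) / DEFAULT_SAMPLE_RATE
        for ci, cls in enumerate(classes):
            for _ in range(n_per_class):
                sig = _audio_proto(cls, t, rng)
                sig = sig / (np.sqrt(np.mean(sig ** 2)) + 1e-9) * 0.1
                sig = sig + rng.normal(0, noise_std * 0.1, sig.shape)
                signals.append(Signal(sig, "audio"))
                labels.append(ci)
    else:
        raise ValidationError(f"unsupported modality {modality!r}")
    order = rng.permutation(len(signals))
    return StimulusSet([signals[i] for i in order], np.asarray(labels)[order],
                       list(classes), seed=seed)


# ---------------------------------------------------------------------------
# Toy model zoo
# ---------------------------------------------------------------------------

def _image_architecture(n_classes: int, rng) -> tuple[list, list[str]]:
    layers = [
        ("norm", nn.Normalize([0.5], [0.25])),
        ("conv0", nn.Conv2d(1, 8, 3, rng=rng)),
        ("relu0", nn.ReLU()),
        ("pool0", nn.AvgPool2d(2)),
        ("conv1", nn.Conv2d(8, 16, 3, rng=rng)),
        ("relu1", nn.ReLU()),
        ("flatten", nn.Flatten()),
        ("fc0", nn.Linear(16 * 5 * 5, 32, rng=rng)),
        ("fc0_relu", nn.ReLU()),
        ("final", nn.Linear(32, n_classes, rng=rng)),
    ]
    stages = ["relu0", "pool0", "relu1", "fc0_relu", "final"]
    return layers, stages


def _audio_architecture(n_classes: int, rng) -> tuple[list, list[str]]:
    layers = frontend_layers() + [
        ("conv0", nn.Conv1d(FRONTEND_N_CHANNELS, 16, 5, rng=rng)),
        ("relu0", nn.ReLU()),
        ("pool0", nn.AvgPool1d(2)),
        ("conv1", nn.Conv1d(16, 16, 5, rng=rng)),
        ("relu1", nn.ReLU()),
        ("gap", nn.GlobalAvgPool()),
        ("fc0", nn.Linear(16, 32, rng=rng)),
        ("fc0_relu", nn.ReLU()),
        ("final", nn.Linear(32, n_classes, rng=rng)),
    ]
    stages = ["cochleagram", "relu0", "relu1", "fc0_relu", "final"]
    return layers, stages


def _sgd_step(model: StagedModel, lr: float) -> None:
    for layer in model.trainable_layers():
        for p, g in zip(layer.params(), layer.grads()):
            p -= lr * g
        layer.zero_grad()


def _train_suffix(model: StagedModel, cached: np.ndarray, labels: np.ndarray,
                  start_layer: str, epochs: int, lr: float, rng) -> None:
    """SGD on the trainable suffix using cached activations at ``start_layer``
    (the frozen front end is evaluated once instead of every batch)."""
    names = [n for n, _ in model.layers]
    i0 = names.index(start_layer) + 1
    suffix = model.layers[i0:]
    n = cached.shape[0]
    batch = 32
    for _ in range(epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, batch):
            idx = order[b0:b0 + batch]
            x = cached[idx]
            stack = []
            for _, layer in suffix:
                x = layer.forward(x)
                stack.append(layer)
            _, g = nn.cross_entropy_grad(x, labels[idx])
            for layer in reversed(stack):
                g = layer.backward(g)
            _sgd_step(model, lr)


def make_toy_model(modality: str, n_classes: int = 4,
                   variant: str = "random_weights", seed: int = 0,
                   n_train_per_class: int = 30) -> StagedModel:
    """Build a small staged convolutional model (5 stages incl. classifier).

    ``briefly_trained`` runs a short SGD pass on the matching synthetic
    stimulus set; ``random_weights`` leaves the initialization untouched.
    """
    if modality not in ("image", "audio"):
        raise ValidationError(f"unsupported modality {modality!r}")
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    vocab = IMAGE_CLASS_VOCAB if modality == "image" else AUDIO_CLASS_VOCAB
    if n_classes > len(vocab):
        raise ValidationError(f"at most {len(vocab)} classes for {modality}")
    rng = np.random.default_rng(seed)
    if modality == "image":
        layers, stages = _image_architecture(n_classes, rng)
        input_shape = (IMAGE_SIZE, IMAGE_SIZE, 1)
    else:
        layers, stages = _audio_architecture(n_classes, rng)
        input_shape = (AUDIO_LENGTH,)
    model = StagedModel(layers, stages, modality, input_shape,
                        classifier_labels=vocab[:n_classes],
                        name=f"{modality}_{variant}_s{seed}")
    if variant == "briefly_trained":
        train = generate_stimuli(modality, n_train_per_class, vocab[:n_classes],
                                 seed=seed + 10_000)
        batchx = train.stack()
        if modality == "audio":
            cached = model.forward_to(batchx, "cochleagram")
            _train_suffix(model, cached, train.labels, "cochleagram",
                          epochs=60, lr=0.08, rng=rng)
        else:
            cached = model.forward_to(batchx, "norm")
            _train_suffix(model, cached, train.labels, "norm",
                          epochs=60, lr=0.05, rng=rng)
    elif variant != "random_weights":
        raise ValidationError(f"unknown variant {variant!r}")
    return model


def stage_feature_matrix(model: StagedModel, batch: np.ndarray, stage: str
                         ) -> np.ndarray:
    """(stimuli, features) matrix of stage activations for encoding analyses.

    Units with a temporal axis (audio conv stages) are averaged over time;
    everything else is flattened.
    """
    acts = model.stage_activations(batch, stage)
    if model.modality == "audio" and acts.ndim == 3:
        acts = acts.mean(axis=2)
    return acts.reshape(acts.shape[0], -1)


def train_linear_readout(model: StagedModel, stage: str, stimuli: StimulusSet,
                         seed: int = 0, epochs: int = 80, lr: float = 0.1) -> StagedModel:
    """Attach a linear classifier head to frozen stage activations.

    Gives label decisions to models without a classifier so the label-match
    criterion can always be applied.
    """
    acts = model.stage_activations(stimuli.stack(), stage)
    feats = acts.reshape(acts.shape[0], -1)
    rng = np.random.default_rng(seed)
    head = nn.Linear(feats.shape[1], len(stimuli.classes), rng=rng)
    for _ in range(epochs):
        order = rng.permutation(feats.shape[0])
        for b0 in range(0, feats.shape[0], 32):
            idx = order[b0:b0 + 32]
            logits = head.forward(feats[idx])
            _, g = nn.cross_entropy_grad(logits, stimuli.labels[idx])
            head.backward(g)
            for p, gr in zip(head.params(), head.grads()):
                p -= lr * gr
            head.zero_grad()
    names = [n for n, _ in model.layers]
    i0 = names.index(stage) + 1
    layers = model.layers[:i0] + [("readout_flatten", nn.Flatten()),
                                  ("final", head)]
    return StagedModel(layers, model.stage_names[:model.stage_names.index(stage) + 1]
                       + ["final"], model.modality, model.input_shape,
                       classifier_labels=list(stimuli.classes),
                       sample_rate=model.sample_rate,
                       name=model.name + f"+readout[{stage}]")
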