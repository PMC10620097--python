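"""Signal containers and file I/O (PNG images, WAV audio).

Images live as H×W×C float arrays in [0, 1]; audio as 1-D float waveforms at a
configurable sample rate (default 20,000 Hz, the rate the auditory pipeline
assumes its inputs were resampled to).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 20_000


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class Signal:
    """A sensory input: an image (H, W, C) in [0, 1] or a mono waveform (T,)."""

    values: np.ndarray
    modality: str  # "image" | "audio"
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.modality not in ("image", "audio"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite values")
        if self.modality == "image":
            if self.values.ndim == 2:
                self.values = self.values[:, :, None]
            if self.values.ndim != 3:
                raise ValidationError("image must be H×W×C")
        else:
            if self.values.ndim != 1 or self.values.size == 0:
                raise ValidationError("audio must be a non-empty 1-D waveform")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "Signal":
        return Signal(self.values.copy(), self.modality, self.sample_rate)


@dataclass
class StimulusSet:
    """Class-labeled signals, reproducible from a seed."""

    signals: list
    labels: np.ndarray
    classes: list
    seed: int = 0
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.signals) != len(self.labels):
            raise ValidationError("signals and labels length mismatch")
        if not self.label_names:
            self.label_names = [self.classes[i] for i in self.labels]

    def __len__(self) -> int:
        return len(self.signals)

    def stack(self) -> np.ndarray:
        return np.stack([s.values for s in self.signals])


def read_image(path: str | Path) -> Signal:
    arr = np.asarray(Image.open(path)).astype(np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return Signal(arr / 255.0, "image")


def write_image(signal: Signal, path: str | Path) -> None:
    if signal.modality != "image":
        raise ValidationError("write_image expects an image signal")
    arr = np.clip(signal.values, 0.0, 1.0)
    arr = (arr * 255.0 + 0.5).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray(arr).save(path)


def read_wav(path: str | Path, expected_rate: int | None = None) -> Signal:
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:  # mono contract: average channels
        data = data.mean(axis=1)
    if expected_rate is not None and rate != expected_rate:
        raise ValidationError(f"sample rate {rate} != expected {expected_rate}")
    return Signal(data, "audio", sample_rate=rate)


def write_wav(signal: Signal, path: str | Path, pcm16: bool = False) -> None:
    if signal.modality != "audio":
        raise ValidationError("write_wav expects an audio signal")
    if pcm16:
        data = np.clip(signal.values, -1.0, 1.0)
        wavfile.write(path, signal.sample_rate, (data * 32767.0).astype(np.int16))
    else:
        wavfile.write(path, signal.sample_rate, signal.values.astype(np.float32))
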