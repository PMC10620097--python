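"""Ground-truth generators for behavioral and neural fixtures.

These emulate the *structure* of the real datasets — trial-level response
tables with controllable per-condition accuracy, confusion kernels and item
difficulty; voxel responses as a noisy sparse linear readout of a known model
stage across repeated scans — so that every analysis has a parameter-recovery
test.  They do not model realistic lapse behavior or fMRI noise spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import RESPONSE_COLUMNS
from .models import StagedModel, stage_feature_matrix
from .signals import StimulusSet, ValidationError

__all__ = ["ObserverSpec", "VoxelSimSpec", "VoxelResponses",
           "simulate_observers", "simulate_voxel_responses"]


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ObserverSpec:
    """Observer population with per-condition accuracy and error structure.

    ``accuracy``: condition -> probability correct (before item effects).
    ``confusion_kernel``: (K, K) row-stochastic error distribution over wrong
    classes (zero diagonal); None = uniform over wrong classes.
    ``sigma_item``: s.d. of Gaussian item effects on the logit scale — the
    knob for per-stimulus reliability.
    """

    accuracy: dict
    n_participants: int = 20
    trials_per_participant: int | None = None  # None = every stimulus once
    sigma_item: float = 0.0
    confusion_kernel: np.ndarray | None = None
    observer_type: str = "human"

    def __post_init__(self):
        for c, p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"accuracy for {c!r} outside [0, 1]")
        if self.sigma_item < 0:
            raise ValidationError("sigma_item must be >= 0")
        if self.confusion_kernel is not None:
            k = np.asarray(self.confusion_kernel, dtype=np.float64)
            if np.any(k < 0) or np.any(np.abs(np.diagonal(k)) > 1e-12):
                raise ValidationError("kernel needs non-negative off-diagonal rows")
            if not np.allclose(k.sum(axis=1), 1.0):
                raise ValidationError("kernel rows must sum to 1 over wrong classes")
            self.confusion_kernel = k


def simulate_observers(spec: ObserverSpec, stimuli: StimulusSet,
                       conditions: list | None = None, seed: int = 0
                       ) -> pd.DataFrame:
    """Trial-level response table for a simulated observer population.

    Each trial is correct with probability sigmoid(logit(p_c) + item effect);
    errors are drawn from the confusion kernel row of the true class.  Item
    effects are per-stimulus, shared across participants and conditions.
    """
    conditions = list(spec.accuracy) if conditions is None else list(conditions)
    for c in conditions:
        if c not in spec.accuracy:
            raise ValidationError(f"no accuracy specified for condition {c!r}")
    rng = np.random.default_rng(seed)
    classes = list(stimuli.classes)
    k = len(classes)
    kernel = spec.confusion_kernel
    if kernel is None:
        kernel = (np.ones((k, k)) - np.eye(k)) / max(k - 1, 1)
    n_stim = len(stimuli)
    item_fx = rng.normal(0.0, spec.sigma_item, size=n_stim)
    stim_ids = [f"s{i:04d}" for i in range(n_stim)]
    rows = []
    for part in range(spec.n_participants):
        pid = f"{spec.observer_type[0]}{part:03d}"
        for cond in conditions:
            base = _logit(spec.accuracy[cond])
            if spec.trials_per_participant is None:
                chosen = np.arange(n_stim)
            else:
                t = spec.trials_per_participant
                chosen = (rng.choice(n_stim, size=t, replace=False) if t <= n_stim
                          else rng.integers(0, n_stim, size=t))
            p_corr = _sigmoid(base + item_fx[chosen])
            is_corr = rng.random(chosen.size) < p_corr
            for s_local, ok in zip(chosen, is_corr):
                true_i = int(stimuli.labels[s_local])
                if ok:
                    resp_i = true_i
                else:
                    resp_i = int(rng.choice(k, p=kernel[true_i]))
                rows.append((pid, spec.observer_type, cond, stim_ids[s_local],
                             classes[true_i], classes[resp_i], bool(ok)))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass
class VoxelSimSpec:
    """Voxels as a sparse non-negative linear readout of one model stage."""

    stage: str
    n_voxels: int = 30
    sparsity: float = 0.25       # fraction of features with nonzero weight
    noise_std: float = 0.4       # per-scan i.i.d. noise (signal has unit s.d.)
    n_scans: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")
        if not 0 < self.sparsity <= 1:
            raise ValidationError("sparsity must be in (0, 1]")
        if self.n_scans < 1:
            raise ValidationError("n_scans must be >= 1")


@dataclass
class VoxelResponses:
    responses: np.ndarray        # (stimuli, voxels, scans)
    weights: np.ndarray          # (features, voxels) ground truth
    stage: str
    noise_std: float


def simulate_voxel_responses(model: StagedModel, stimuli: StimulusSet,
                             spec: VoxelSimSpec) -> VoxelResponses:
    """Per-scan voxel responses from a known generating stage.

    Each voxel's noiseless response (a non-negative sparse combination of the
    stage's time-averaged features) is standardized to zero mean / unit s.d.
    across stimuli, then i.i.d. Gaussian scan noise of ``spec.noise_std`` is
    added, so the expected inter-scan correlation is 1/(1 + noise_std²).
    """
    if spec.stage not in model.stage_names:
        raise ValidationError(f"stage {spec.stage!r} not in model")
    rng = np.random.default_rng(spec.seed)
    F = stage_feature_matrix(model, stimuli.stack(), spec.stage)
    n_stim, n_feat = F.shape
    n_on = max(1, int(round(spec.sparsity * n_feat)))
    W = np.zeros((n_feat, spec.n_voxels))
    for v in range(spec.n_voxels):
        on = rng.choice(n_feat, size=n_on, replace=False)
        W[on, v] = rng.uniform(0.2, 1.0, size=n_on)
    signal = F @ W
    sd = signal.std(axis=0)
    sd[sd == 0] = 1.0
    signal = (signal - signal.mean(axis=0)) / sd
    noise = rng.normal(0.0, spec.noise_std,
                       size=(n_stim, spec.n_voxels, spec.n_scans))
    resp = signal[:, :, None] + noise
    return VoxelResponses(resp, W, spec.stage, spec.noise_std)
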