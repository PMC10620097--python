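"""Convergence criteria: does a synthesized candidate qualify as a metamer?

Two requirements, mirroring how experimental stimuli are vetted:

1. The activation match at the generation stage must be better than expected
   between *random* stimulus pairs — for each of Spearman ρ, Pearson R² and
   SNR(dB), the candidate's value must fall outside (above) a null
   distribution built from random natural-stimulus pairs.
2. The model must assign the candidate the same class label as its reference.

Candidates failing either are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import ActivationArray, StagedModel, _acts
from .signals import StimulusSet, ValidationError
from .synthesis import MetamerCandidate

__all__ = [
    "MatchMetrics",
    "NullDistribution",
    "CriterionVerdict",
    "MetamerRecord",
    "snr_db",
    "match_metrics",
    "build_null_distribution",
    "evaluate_metamer",
]

METRIC_NAMES = ("spearman_rho", "pearson_r2", "snr_db")
DEFAULT_NULL_PAIRS = 1_000_000
TEST_NULL_PAIRS = 10_000  # fast preset for fixtures and CI-scale runs


def snr_db(x, y) -> float:
    """10·log₁₀(Σx² / Σ(x−y)²); +∞ for an exact match."""
    xv = _acts(x).ravel()
    yv = _acts(y).ravel()
    if xv.shape != yv.shape:
        raise ValidationError("shape mismatch in snr_db")
    sig = np.sum(xv ** 2)
    if sig == 0:
        raise ValidationError("undefined SNR: reference activations are all zero")
    err = np.sum((xv - yv) ** 2)
    if err == 0:
        return np.inf
    return float(10.0 * np.log10(sig / err))


@dataclass
class MatchMetrics:
    spearman_rho: float
    pearson_r2: float
    snr_db: float
    flags: dict = field(default_factory=dict)  # metric -> reason when undefined

    def as_dict(self) -> dict:
        return {"rho": self.spearman_rho, "r2": self.pearson_r2, "snr_db": self.snr_db}


def match_metrics(reference_acts, synth_acts) -> MatchMetrics:
    """All three fidelity metrics on flattened activations.

    Spearman uses average ranks for ties; R² is the square of Pearson r.
    Zero-variance inputs flag the correlation metrics as undefined (NaN)
    rather than raising, so null construction can log and resample.
    """
    a = _acts(reference_acts).ravel()
    b = _acts(synth_acts).ravel()
    if a.shape != b.shape:
        raise ValidationError("activation shape mismatch")
    if a.size < 3:
        raise ValidationError("need at least 3 elements for match metrics")
    flags = {}
    if np.std(a) == 0 or np.std(b) == 0:
        rho, r2 = np.nan, np.nan
        flags["spearman_rho"] = flags["pearson_r2"] = "zero variance"
    else:
        rho = float(stats.spearmanr(a, b).statistic)
        r = float(stats.pearsonr(a, b).statistic)
        r2 = r * r
    return MatchMetrics(rho, r2, snr_db(a, b), flags)


@dataclass
class NullDistribution:
    """Per-stage null samples of the match metrics over random stimulus pairs.

    ``thresholds`` default to the sample maximum per metric (the most
    conservative reading of "outside the null"); a quantile rule is
    available via ``threshold_quantile``.
    """

    stage: str
    samples: dict                      # metric -> np.ndarray of n_pairs values
    seed: int
    threshold_quantile: float | None = None   # None -> max rule
    n_resampled: int = 0

    def __post_init__(self):
        lens = {len(v) for v in self.samples.values()}
        if len(lens) != 1:
            raise ValidationError("metric sample lists must have equal length")

    @property
    def n_pairs(self) -> int:
        return len(next(iter(self.samples.values())))

    def threshold(self, metric: str) -> float:
        s = self.samples[metric]
        if self.threshold_quantile is None:
            return float(np.max(s))
        return float(np.quantile(s, self.threshold_quantile))

    def thresholds(self) -> dict:
        return {m: self.threshold(m) for m in self.samples}


def _pairwise_metrics(acts: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray
                      ) -> dict[str, np.ndarray]:
    """Vectorized metrics for many (x, y) activation pairs."""
    flat = acts.reshape(acts.shape[0], -1)
    X = flat[idx_x]
    Y = flat[idx_y]
    # SNR
    sig = np.sum(X ** 2, axis=1)
    err = np.sum((X - Y) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 10.0 * np.log10(sig / err)
    snr[err == 0] = np.inf
    snr[sig == 0] = np.nan
    # Pearson R^2
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.linalg.norm(Xc, axis=1)
    sy = np.linalg.norm(Yc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sum(Xc * Yc, axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    # Spearman: Pearson on average ranks
    rX = stats.rankdata(X, axis=1)
    rY = stats.rankdata(Y, axis=1)
    rXc = rX - rX.mean(axis=1, keepdims=True)
    rYc = rY - rY.mean(axis=1, keepdims=True)
    srx = np.linalg.norm(rXc, axis=1)
    sry = np.linalg.norm(rYc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.sum(rXc * rYc, axis=1) / (srx * sry)
    rho[(srx == 0) | (sry == 0)] = np.nan
    return {"spearman_rho": rho, "pearson_r2": r ** 2, "snr_db": snr}


def build_null_distribution(model: StagedModel, stage: str,
                            training_set: StimulusSet,
                            n_pairs: int = DEFAULT_NULL_PAIRS,
                            seed: int = 0,
                            threshold_quantile: float | None = None,
                            batch: int = 200_000) -> NullDistribution:
    """Null metric distribution over random distinct-index stimulus pairs.

    Pairs are drawn with replacement across pairs; an item is never paired
    with itself.  Degenerate pairs (undefined metrics) are resampled and
    counted in ``n_resampled``.
    """
    if len(training_set) < 2:
        raise ValidationError("need at least 2 training stimuli")
    rng = np.random.default_rng(seed)
    acts = model.stage_activations(training_set.stack(), stage)
    n = acts.shape[0]
    out = {m: np.empty(n_pairs) for m in METRIC_NAMES}
    filled = 0
    n_resampled = 0
    while filled < n_pairs:
        take = min(batch, n_pairs - filled)
        ix = rng.integers(0, n, size=take)
        off = rng.integers(1, n, size=take)
        iy = (ix + off) % n  # distinct by construction, uniform over j != i
        vals = _pairwise_metrics(acts, ix, iy)
        ok = np.ones(take, dtype=bool)
        for m in METRIC_NAMES:
            ok &= ~np.isnan(vals[m])
        n_ok = int(ok.sum())
        n_resampled += take - n_ok
        for m in METRIC_NAMES:
            out[m][filled:filled + n_ok] = vals[m][ok]
        filled += n_ok
    return NullDistribution(stage, out, seed, threshold_quantile, n_resampled)


@dataclass
class CriterionVerdict:
    stage: str
    metrics: MatchMetrics
    thresholds: dict
    passes: dict          # metric -> bool, for the required subset
    label_match: bool
    overall: bool

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "metrics": self.metrics.as_dict(),
            "thresholds": self.thresholds,
            "passes": dict(self.passes),
            "label_match": bool(self.label_match),
            "overall": bool(self.overall),
        }


# Exact-perfect metric values that always satisfy their criterion.  A perfect
# rank agreement (ρ = 1) or an exact activation match (SNR = +∞) cannot be
# strictly exceeded, yet denotes the best possible match; on low-dimensional
# stages (e.g. a small logit vector) the null itself can saturate at ρ = 1.
_PERFECT = {"spearman_rho": 1.0, "snr_db": np.inf}


def evaluate_metamer(model: StagedModel, candidate: MetamerCandidate,
                     null: NullDistribution,
                     metric_subset: tuple = METRIC_NAMES) -> CriterionVerdict:
    """Apply both success criteria to a synthesized candidate.

    Each required metric must strictly exceed its null threshold (or hit its
    exact-perfect value); the model's argmax decision for the candidate must
    equal that for the reference.  ``metric_subset`` restricts the metric
    criterion (e.g. SNR only) for models whose stages make rank-based
    metrics unreliable.
    """
    if null.stage != candidate.stage:
        raise ValidationError(
            f"null built for stage {null.stage!r}, candidate is {candidate.stage!r}")
    ref_acts = model.stage_activations(candidate.reference.values[None],
                                       candidate.stage)[0]
    syn_acts = model.stage_activations(candidate.signal.values[None],
                                       candidate.stage)[0]
    metrics = match_metrics(ref_acts, syn_acts)
    thresholds = null.thresholds()
    passes = {}
    for m in metric_subset:
        v = getattr(metrics, m)
        perfect = _PERFECT.get(m)
        passes[m] = bool(np.isfinite(v) and v > thresholds[m]) or \
            (perfect is not None and v == perfect)
    if model.classifier_labels is None:
        raise ValidationError(
            "label criterion requires a classifier head (attach a linear readout)")
    pair = np.stack([candidate.reference.values, candidate.signal.values])
    lab_ref, lab_syn = model.predict(pair)
    label_match = bool(lab_ref == lab_syn)
    overall = all(passes.values()) and label_match
    return CriterionVerdict(candidate.stage, metrics, thresholds, passes,
                            label_match, overall)


@dataclass
class MetamerRecord:
    """A certified (or rejected) metamer with its full provenance."""

    candidate: MetamerCandidate
    verdict: CriterionVerdict
    reference_label: str
    generation_model: str
    stage: str
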