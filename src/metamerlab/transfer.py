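"""Cross-model transfer: how well do other models recognize a model's metamers?

A metamer synthesized from a *generation* model is shown to a *recognition*
model; recognition accuracy per generation stage, aggregated across
recognition models (always excluding the generation model itself), measures
how idiosyncratic the generation model's invariances are.  Group differences
(e.g. standard vs adversarially trained generation models) are tested with a
permutation test that shuffles generation-model labels independently within
each recognition model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _nanmean(a, axis=None):
    """nanmean without the all-NaN-slice warning (NaN result is meaningful
    here: a stage with no contributing models is absent, not zero)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)

from .criteria import MetamerRecord
from .models import StagedModel
from .signals import ValidationError

__all__ = [
    "TransferMatrix",
    "TransferCurve",
    "cross_model_recognition",
    "aggregate_transfer",
    "transfer_permutation_test",
    "perm_pvalue",
]

TIDY_COLUMNS = ["generation_model", "stage", "recognition_model", "n_trials", "n_correct"]


def perm_pvalue(observed: float, null: np.ndarray, convention: str = "add_one") -> float:
    """Permutation p-value.

    ``add_one`` (default): (1 + #{null ≥ observed}) / (1 + n_perm), which can
    never be 0.  ``rank`` replicates the 1 − rank/n_perm formula (rank =
    #{null < observed}), floored at 1/n_perm to keep p in (0, 1].
    """
    null = np.asarray(null, dtype=np.float64)
    n = null.size
    if n < 1:
        raise ValidationError("need at least one permutation")
    n_ge = int(np.sum(null >= observed))
    if convention == "add_one":
        return (1 + n_ge) / (1 + n)
    if convention == "rank":
        return max(n_ge / n, 1.0 / n)
    raise ValidationError(f"unknown p-value convention {convention!r}")


@dataclass
class TransferMatrix:
    """Tidy accuracy table indexed by (generation model, stage, recognition
    model).  Self-cells (recognition = generation) are missing, never zero."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(TIDY_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"transfer table missing columns {sorted(missing)}")
        t = self.table
        if ((t.n_correct > t.n_trials) | (t.n_trials < 0)).any():
            raise ValidationError("invalid trial counts")
        if (t.generation_model == t.recognition_model).any():
            raise ValidationError("self-cells must be absent, not recorded")

    @property
    def generation_models(self) -> list:
        return sorted(self.table.generation_model.unique())

    @property
    def recognition_models(self) -> list:
        return sorted(self.table.recognition_model.unique())

    @property
    def stages(self) -> list:
        return sorted(self.table.stage.unique())

    def accuracy_array(self) -> tuple[np.ndarray, list, list, list]:
        """(gen × stage × rec) accuracy array with NaN for missing cells."""
        gens, stages, recs = self.generation_models, self.stages, self.recognition_models
        arr = np.full((len(gens), len(stages), len(recs)), np.nan)
        gi = {g: i for i, g in enumerate(gens)}
        si = {s: i for i, s in enumerate(stages)}
        ri = {r: i for i, r in enumerate(recs)}
        for row in self.table.itertuples():
            if row.n_trials > 0:  # zero-trial cells stay missing
                arr[gi[row.generation_model], si[row.stage],
                    ri[row.recognition_model]] = row.n_correct / row.n_trials
        return arr, gens, stages, recs

    def to_csv(self, path) -> None:
        self.table[TIDY_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransferMatrix":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: list[dict]) -> "TransferMatrix":
        return cls(pd.DataFrame.from_records(records, columns=TIDY_COLUMNS))


@dataclass
class TransferCurve:
    stages: list
    mean: np.ndarray       # per-stage accuracy averaged across recognition models
    sem: np.ndarray        # s.e.m. across recognition models
    n_models: np.ndarray   # recognition models contributing per stage


def cross_model_recognition(metamers: list[MetamerRecord],
                            recognition_model: StagedModel,
                            class_mapping: dict | None = None) -> dict[str, tuple]:
    """Per-stage (n_correct, n_trials) of a recognition model on metamers.

    Reference classes are matched to the recognition model's vocabulary by
    name, or through ``class_mapping`` (generation label -> recognition
    label) when the vocabularies differ.
    """
    if recognition_model.classifier_labels is None:
        raise ValidationError("recognition model needs a classifier head")
    vocab = recognition_model.classifier_labels
    out: dict[str, list] = {}
    by_stage: dict[str, list] = {}
    for rec in metamers:
        by_stage.setdefault(rec.stage, []).append(rec)
    for stage, recs in by_stage.items():
        batch = np.stack([r.candidate.signal.values for r in recs])
        pred = recognition_model.predict(batch)
        n_correct = 0
        for r, p in zip(recs, pred):
            label = r.reference_label
            if class_mapping is not None:
                label = class_mapping.get(label, label)
            if label not in vocab:
                raise ValidationError(
                    f"class {label!r} not in recognition vocabulary and no mapping given")
            n_correct += int(vocab[p] == label)
        out[stage] = (n_correct, len(recs))
    return out


def aggregate_transfer(matrix: TransferMatrix, generation_group: list
                       ) -> TransferCurve:
    """Average accuracy over a group of generation models.

    Per recognition model, first average over the group's generation models
    (self-cells are missing and skipped), then average across recognition
    models; the error bar is the s.e.m. across recognition models.  Stages
    with no contributing model are reported as absent (NaN).
    """
    if not generation_group:
        raise ValidationError("empty generation group")
    arr, gens, stages, recs = matrix.accuracy_array()
    gsel = [gens.index(g) for g in generation_group]
    per_rec = _nanmean(arr[gsel], axis=0)  # (stage, rec)
    mean = np.full(len(stages), np.nan)
    sem = np.full(len(stages), np.nan)
    n_models = np.zeros(len(stages), dtype=int)
    for s in range(len(stages)):
        vals = per_rec[s][~np.isnan(per_rec[s])]
        n_models[s] = vals.size
        if vals.size:
            mean[s] = vals.mean()
            sem[s] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return TransferCurve(stages, mean, sem, n_models)


def _group_stat(per_gen_rec: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> float:
    """Difference of group means from a (gen × rec) array of stage-averaged
    accuracies: per recognition model, average over the group's generation
    models (missing skipped), then average across recognition models."""
    a = _nanmean(_nanmean(per_gen_rec[ga], axis=0))
    b = _nanmean(_nanmean(per_gen_rec[gb], axis=0))
    return float(a - b)


def transfer_permutation_test(matrix: TransferMatrix, group_a: list, group_b: list,
                              n_perm: int = 10_000, seed: int = 0,
                              convention: str = "add_one",
                              two_sided: bool = True) -> dict:
    """Permutation test for a difference between generation-model groups.

    Generation-model labels are permuted independently for each recognition
    model; missing self-cells travel with their label and remain missing in
    the averages.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    arr, gens, stages, recs = matrix.accuracy_array()
    ga = np.array([gens.index(g) for g in group_a])
    gb = np.array([gens.index(g) for g in group_b])
    n_gen = len(gens)
    n_rec = len(recs)
    # stage-averaged accuracy per (gen, rec); a self-cell is missing for every
    # stage, so averaging stages first is exact under that missingness pattern
    per_gen_rec = _nanmean(arr, axis=1)
    obs = _group_stat(per_gen_rec, ga, gb)
    rng = np.random.default_rng(seed)
    # permute generation labels independently per recognition model, vectorized
    perms = np.argsort(rng.random((n_perm, n_rec, n_gen)), axis=2)  # (P,R,G)
    permuted = per_gen_rec.T[np.arange(n_rec)[None, :, None], perms]  # (P,R,G)
    a = _nanmean(_nanmean(permuted[:, :, ga], axis=2), axis=1)
    b = _nanmean(_nanmean(permuted[:, :, gb], axis=2), axis=1)
    null = a - b
    if two_sided:
        p_val = perm_pvalue(abs(obs), np.abs(null), convention)
    else:
        p_val = perm_pvalue(obs, null, convention)
    return {"observed": obs, "null": null, "p": p_val, "n_perm": n_perm}
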