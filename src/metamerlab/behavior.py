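"""Behavioral statistics for metamer recognition experiments.

Inputs are trial-level response tables (participant, observer type, condition,
stimulus, true class, response class).  The analyses are permutation-based
throughout because recognition accuracies pile up near floor/ceiling:

* mixed-design repeated-measures ANOVA (between factor: observer human/model;
  within factor: generation stage) with the F statistic evaluated against
  label permutations;
* split-half reliability of confusion matrices;
* split-half reliability of per-stimulus recognizability;
* consistency of the most/least recognizable items across participant splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signals import ValidationError
from .transfer import perm_pvalue

__all__ = [
    "RESPONSE_COLUMNS",
    "validate_response_table",
    "accuracy_table",
    "PermutationTestResult",
    "SplitHalfResult",
    "mixed_anova_permutation",
    "confusion_matrix_counts",
    "confusion_split_half",
    "per_stimulus_reliability",
    "extreme_item_consistency",
]

RESPONSE_COLUMNS = ["participant_id", "observer_type", "condition", "stimulus_id",
                    "true_class", "response_class", "correct"]


def validate_response_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"response table missing columns {sorted(missing)}")
    derived = table.true_class == table.response_class
    if not (table.correct.astype(bool) == derived).all():
        raise ValidationError("correct flag inconsistent with response/true classes")
    dup = table.duplicated(["participant_id", "condition", "stimulus_id"])
    if dup.any():
        raise ValidationError("duplicate (participant, stimulus) within a condition")
    return table


def accuracy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per participant × condition (the ANOVA unit)."""
    out = (table.groupby(["participant_id", "observer_type", "condition"],
                         sort=True, observed=True)
           .correct.mean().reset_index(name="accuracy"))
    return out


@dataclass
class PermutationTestResult:
    f_observed: float
    eta_p2: float
    null_f: np.ndarray
    p: float
    n_perm: int
    effect: str


@dataclass
class SplitHalfResult:
    mean_rho: float
    n_splits: int
    n_overlap: int
    p: float

    def __post_init__(self):
        # printed-formula contract: p = (1 + n_overlap) / n_splits
        assert abs(self.p - (1 + self.n_overlap) / self.n_splits) < 1e-12


# ---------------------------------------------------------------------------
# Mixed / repeated-measures ANOVA with permutation inference
# ---------------------------------------------------------------------------

def _anova_ss(Y: np.ndarray, masks: np.ndarray | None):
    """Sums of squares for (..., N, W) accuracy arrays.

    ``masks``: (G, N) boolean group membership (between factor), or None for
    a single-factor repeated-measures design.  Returns a dict of SS and df.
    Balanced or unbalanced group sizes; cells must be complete.
    """
    n = Y.shape[-2]
    w = Y.shape[-1]
    gm = Y.mean(axis=(-1, -2), keepdims=True)
    subj_mean = Y.mean(axis=-1, keepdims=True)              # (..., N, 1)
    cond_mean = Y.mean(axis=-2, keepdims=True)              # (..., 1, W)
    ss = {}
    ss["subjects_total"] = (w * (subj_mean - gm) ** 2).sum(axis=(-1, -2))
    ss["within_total"] = ((Y - subj_mean) ** 2).sum(axis=(-1, -2))
    ss["cond"] = (n * (cond_mean - gm) ** 2).sum(axis=(-1, -2))
    if masks is None:
        ss["err_within"] = ss["within_total"] - ss["cond"]
        ss["df"] = {"cond": w - 1, "err_within": (n - 1) * (w - 1)}
        return ss
    g = masks.shape[0]
    ss_b = np.zeros(Y.shape[:-2])
    ss_int = np.zeros(Y.shape[:-2])
    for gi in range(g):
        m = masks[gi]
        ng = int(m.sum())
        grp = Y[..., m, :]
        grp_mean = grp.mean(axis=(-1, -2), keepdims=True)
        grp_cond = grp.mean(axis=-2, keepdims=True)
        ss_b = ss_b + (w * ng * (grp_mean - gm) ** 2).squeeze((-1, -2))
        ss_int = ss_int + (ng * (grp_cond - grp_mean - cond_mean + gm) ** 2
                           ).sum(axis=(-1, -2))
    ss["between"] = ss_b
    ss["interaction"] = ss_int
    ss["subj_within_groups"] = ss["subjects_total"] - ss_b
    ss["err_within"] = ss["within_total"] - ss["cond"] - ss_int
    ss["df"] = {
        "between": g - 1, "subj_within_groups": n - g,
        "cond": w - 1, "interaction": (g - 1) * (w - 1),
        "err_within": (n - g) * (w - 1),
    }
    return ss


def _f_from_ss(ss: dict, effect: str):
    df = ss["df"]
    if effect == "main_observer":
        num, den = "between", "subj_within_groups"
    elif effect == "interaction":
        num, den = "interaction", "err_within"
    elif effect == "main_stage":
        num, den = "cond", "err_within"
    else:
        raise ValidationError(f"unknown effect {effect!r}")
    ms_num = ss[num] / df[num]
    ms_den = ss[den] / df[den]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ms_den > 0, ms_num / np.where(ms_den > 0, ms_den, 1.0),
                     np.where(ms_num > 0, np.inf, 0.0))
        tot = ss[num] + ss[den]
        eta = np.where(tot > 0, ss[num] / np.where(tot > 0, tot, 1.0), 0.0)
    return f, eta


def _pivot(table: pd.DataFrame):
    acc = accuracy_table(validate_response_table(table))
    pivot = acc.pivot_table(index=["participant_id", "observer_type"],
                            columns="condition", values="accuracy")
    if pivot.isna().any().any():
        bad = pivot.stack(future_stack=True)
        cell = bad[bad.isna()].index[0]
        raise ValidationError(f"empty participant×condition cell: {cell}")
    groups = pivot.index.get_level_values("observer_type").to_numpy()
    return pivot.to_numpy(), groups, list(pivot.columns)


def mixed_anova_permutation(table: pd.DataFrame, design: str = "mixed",
                            effect: str = "interaction", n_perm: int = 10_000,
                            seed: int = 0, convention: str = "add_one"
                            ) -> PermutationTestResult:
    """Permutation-based mixed (or one-way repeated-measures) ANOVA.

    ``design='mixed'``: between factor = observer type, within factor =
    condition; effects ``main_observer`` or ``interaction``.  The null is
    built by permuting observer labels (main effect) or both observer labels
    and per-participant condition labels (interaction).

    ``design='single_factor'``: one-way repeated measures over conditions
    (``main_stage``); condition labels are permuted within participant.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    Y, groups, conditions = _pivot(table)
    n, w = Y.shape
    rng = np.random.default_rng(seed)

    if design == "single_factor":
        if effect != "main_stage":
            raise ValidationError("single_factor design tests main_stage")
        ss = _anova_ss(Y, None)
        f_obs, eta = _f_from_ss(ss, effect)
        perm_Y = _permute_within_rows(Y, n_perm, rng)
        null_f, _ = _f_from_ss(_anova_ss(perm_Y, None), effect)
    elif design == "mixed":
        labels = np.unique(groups)
        if len(labels) < 2:
            raise ValidationError("mixed design needs two observer groups")
        masks = np.stack([groups == lab for lab in labels])
        if masks.sum(axis=1).min() < 2:
            raise ValidationError("need >= 2 participants per observer group")
        ss = _anova_ss(Y, masks)
        f_obs, eta = _f_from_ss(ss, effect)
        null_f = np.empty(n_perm)
        if effect == "main_observer":
            for p in range(n_perm):
                pm = masks[:, rng.permutation(n)]
                null_f[p], _ = _f_from_ss(_anova_ss(Y, pm), effect)
        else:  # interaction: observer labels and per-participant stage labels
            perm_Y = _permute_within_rows(Y, n_perm, rng)
            for p in range(n_perm):
                pm = masks[:, rng.permutation(n)]
                null_f[p], _ = _f_from_ss(_anova_ss(perm_Y[p], pm), effect)
    else:
        raise ValidationError(f"unknown design {design!r}")
    p_val = perm_pvalue(float(f_obs), np.asarray(null_f, dtype=float), convention)
    return PermutationTestResult(float(f_obs), float(eta), np.asarray(null_f, float),
                                 p_val, n_perm, effect)


def _permute_within_rows(Y: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(P, N, W) stack of Y with each row's entries independently permuted."""
    n, w = Y.shape
    keys = rng.random((n_perm, n, w))
    idx = np.argsort(keys, axis=2)
    return np.take_along_axis(np.broadcast_to(Y, (n_perm, n, w)), idx, axis=2)


# ---------------------------------------------------------------------------
# Split-half analyses
# ---------------------------------------------------------------------------

def confusion_matrix_counts(table: pd.DataFrame, classes: list) -> np.ndarray:
    """class×class response counts (rows: true class)."""
    k = len(classes)
    ci = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k))
    ti = table.true_class.map(ci).to_numpy()
    ri = table.response_class.map(ci).to_numpy()
    np.add.at(counts, (ti, ri), 1)
    return counts


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / sums, np.nan)


def _half_masks(participants: np.ndarray, n_splits: int, rng) -> np.ndarray:
    """(S, P) boolean: True = first half.  With an odd participant count the
    extra participant joins the first half, at random per split."""
    p = participants.size
    order = np.argsort(rng.random((n_splits, p)), axis=1)
    half = (p + 1) // 2
    masks = np.zeros((n_splits, p), dtype=bool)
    np.put_along_axis(masks, order[:, :half], True, axis=1)
    return masks


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sum(Ac * Bc, axis=1) / (na * nb)


def confusion_split_half(table: pd.DataFrame, condition,
                         n_splits: int = 1_000, seed: int = 0,
                         off_diagonal_only: bool = False) -> SplitHalfResult:
    """Split-half reliability of the row-normalized confusion matrix.

    Per split: participants are halved at random, a confusion matrix is built
    and row-normalized per half, and the two are compared with a Spearman
    correlation over matrix cells.  A response-shuffled control (fresh
    shuffle per split) yields the comparison distribution;
    p = (1 + #{true − shuffled ≤ 0}) / n_splits.
    """
    sub = validate_response_table(table)
    sub = sub[sub.condition == condition]
    if sub.empty:
        raise ValidationError(f"condition {condition!r} absent")
    participants = np.sort(sub.participant_id.unique())
    if participants.size < 4:
        raise ValidationError("need >= 4 participants for split-half analysis")
    classes = sorted(set(sub.true_class) | set(sub.response_class))
    k = len(classes)
    ci = {c: i for i, c in enumerate(classes)}
    pi = {p: i for i, p in enumerate(participants)}
    t_idx = sub.true_class.map(ci).to_numpy()
    r_idx = sub.response_class.map(ci).to_numpy()
    p_idx = sub.participant_id.map(pi).to_numpy()
    n_tr = t_idx.size
    rng = np.random.default_rng(seed)
    masks = _half_masks(participants, n_splits, rng)          # (S, P)
    trial_in_h1 = masks[:, p_idx]                              # (S, T)

    def split_matrices(resp_idx):
        """(S, K, K) normalized confusion per half given response indices
        (either (T,) shared or (S, T) per split)."""
        cell = t_idx * k + resp_idx                            # (T,) or (S,T)
        cell = np.broadcast_to(cell, (n_splits, n_tr))
        s_off = (np.arange(n_splits) * k * k)[:, None]
        c1 = np.bincount((cell + s_off)[trial_in_h1], minlength=n_splits * k * k)
        c2 = np.bincount((cell + s_off)[~trial_in_h1], minlength=n_splits * k * k)
        m1 = _row_normalize(c1.reshape(n_splits, k, k).astype(float))
        m2 = _row_normalize(c2.reshape(n_splits, k, k).astype(float))
        return m1, m2

    m1, m2 = split_matrices(r_idx)
    shuffle = np.argsort(rng.random((n_splits, n_tr)), axis=1)
    m1s, m2s = split_matrices(r_idx[shuffle])

    def spearman_cells(a, b):
        A = a.reshape(n_splits, -1)
        B = b.reshape(n_splits, -1)
        if off_diagonal_only:
            off = ~np.eye(k, dtype=bool).ravel()
            A, B = A[:, off], B[:, off]
        valid = ~(np.isnan(A) | np.isnan(B))
        if valid.all():
            return _rowwise_pearson(_rank_rows(A), _rank_rows(B))
        out = np.empty(n_splits)
        for s in range(n_splits):  # rare path: some class had no trials in a half
            v = valid[s]
            out[s] = stats.spearmanr(A[s, v], B[s, v]).statistic
        return out

    rho_true = spearman_cells(m1, m2)
    rho_shuf = spearman_cells(m1s, m2s)
    n_overlap = int(np.sum((rho_true - rho_shuf) <= 0))
    return SplitHalfResult(float(np.nanmean(rho_true)), n_splits, n_overlap,
                           (1 + n_overlap) / n_splits)


def per_stimulus_reliability(table: pd.DataFrame, condition,
                             n_splits: int = 1_000, min_trials: int = 4,
                             seed: int = 0) -> tuple[float, float]:
    """Split-half reliability of per-stimulus recognizability.

    Per split, each half's per-stimulus proportion correct is computed from
    exactly ``min_trials`` randomly subsampled trials; stimuli with fewer
    trials in either half are excluded from that split.  Returns the mean
    Spearman ρ across splits and a p-value against response-shuffled splits.
    """
    sub = validate_response_table(table)
    sub = sub[sub.condition == condition]
    if sub.empty:
        raise ValidationError(f"condition {condition!r} absent")
    participants = np.sort(sub.participant_id.unique())
    stims = np.sort(sub.stimulus_id.unique())
    pi = {p: i for i, p in enumerate(participants)}
    si = {s: i for i, s in enumerate(stims)}
    p_idx = sub.participant_id.map(pi).to_numpy()
    s_idx = sub.stimulus_id.map(si).to_numpy()
    correct = sub.correct.to_numpy().astype(float)
    rng = np.random.default_rng(seed)
    masks = _half_masks(participants, n_splits, rng)
    trial_lists = [np.flatnonzero(s_idx == s) for s in range(len(stims))]

    def half_scores(vals: np.ndarray, in_h1: np.ndarray):
        s1 = np.full(len(stims), np.nan)
        s2 = np.full(len(stims), np.nan)
        for s, tl in enumerate(trial_lists):
            for target, sel in ((s1, tl[in_h1[tl]]), (s2, tl[~in_h1[tl]])):
                if sel.size >= min_trials:
                    pick = sel if sel.size == min_trials else \
                        rng.choice(sel, size=min_trials, replace=False)
                    target[s] = vals[pick].mean()
        return s1, s2

    rho_true = np.empty(n_splits)
    rho_shuf = np.empty(n_splits)
    any_valid = False
    for sp in range(n_splits):
        in_h1 = masks[sp, p_idx]
        a, b = half_scores(correct, in_h1)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            rho_true[sp] = rho_shuf[sp] = np.nan
            continue
        any_valid = True
        rho_true[sp] = stats.spearmanr(a[ok], b[ok]).statistic
        a2, b2 = half_scores(correct[rng.permutation(correct.size)], in_h1)
        ok2 = ~(np.isnan(a2) | np.isnan(b2))
        rho_shuf[sp] = stats.spearmanr(a2[ok2], b2[ok2]).statistic
    if not any_valid:
        raise ValidationError("no stimuli meet the per-half trial minimum")
    mean_rho = float(np.nanmean(rho_true))
    n_ge = int(np.nansum(rho_shuf >= mean_rho))
    return mean_rho, (1 + n_ge) / n_splits


def extreme_item_consistency(table: pd.DataFrame, condition, k: int = 50,
                             n_splits: int = 1_000, seed: int = 0) -> dict:
    """Held-out consistency of the most vs least recognizable stimuli.

    Per split, one half of participants selects the k highest- and k
    lowest-scoring stimuli; the other half scores them.  Reported:
    ``proportion_greater`` (splits where most > least) and
    ``p`` = proportion of splits where the difference is ≤ 0.
    """
    sub = validate_response_table(table)
    sub = sub[sub.condition == condition]
    if sub.empty:
        raise ValidationError(f"condition {condition!r} absent")
    participants = np.sort(sub.participant_id.unique())
    stims = np.sort(sub.stimulus_id.unique())
    if stims.size < 2 * k:
        raise ValidationError(f"need >= {2 * k} stimuli, have {stims.size}")
    pi = {p: i for i, p in enumerate(participants)}
    si = {s: i for i, s in enumerate(stims)}
    p_idx = sub.participant_id.map(pi).to_numpy()
    s_idx = sub.stimulus_id.map(si).to_numpy()
    correct = sub.correct.to_numpy().astype(float)
    rng = np.random.default_rng(seed)
    masks = _half_masks(participants, n_splits, rng)
    n_stim = stims.size
    diffs = np.empty(n_splits)
    for sp in range(n_splits):
        in_h1 = masks[sp, p_idx]
        cnt1 = np.bincount(s_idx[in_h1], minlength=n_stim)
        cor1 = np.bincount(s_idx[in_h1], weights=correct[in_h1], minlength=n_stim)
        cnt2 = np.bincount(s_idx[~in_h1], minlength=n_stim)
        cor2 = np.bincount(s_idx[~in_h1], weights=correct[~in_h1], minlength=n_stim)
        with np.errstate(invalid="ignore", divide="ignore"):
            score1 = cor1 / cnt1
            score2 = cor2 / cnt2
        score1 = np.where(cnt1 > 0, score1, -np.inf)  # unseen items rank lowest
        order = np.argsort(score1, kind="stable")
        least, most = order[:k], order[-k:]
        m2 = score2[most[cnt2[most] > 0]]
        l2 = score2[least[cnt2[least] > 0]]
        diffs[sp] = (np.mean(m2) if m2.size else np.nan) - \
                    (np.mean(l2) if l2.size else np.nan)
    prop_greater = float(np.nanmean(diffs > 0))
    p = float(np.nanmean(diffs <= 0))
    return {"proportion_greater": prop_greater, "p": p,
            "mean_difference": float(np.nanmean(diffs)), "n_splits": n_splits}
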