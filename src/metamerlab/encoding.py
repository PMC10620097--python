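"""Voxel-wise encoding with noise-ceiling correction, and RSA.

Model stage features (time-averaged where a time axis exists) predict voxel
responses through ridge regression.  Per voxel, the ridge parameter is chosen
by exact leave-one-out cross-validation over a large logarithmic grid; test
fidelity (squared Pearson r) is corrected by the product of voxel reliability
r'_v and prediction reliability r'_v̂ (both floored at the one-tailed P<0.05
critical Pearson correlation for the train/test sizes):

    r²* = r² / (r'_v · r'_v̂)

Best-stage selection is cross-validated across participants so no
participant's data picks its own stage.  The RSA route compares z-scored
response geometries with 1 − Pearson dissimilarity matrices and Spearman
correlations of their upper triangles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signals import ValidationError

__all__ = [
    "ridge_lambda_grid",
    "critical_pearson",
    "spearman_brown",
    "ridge_loo_select",
    "EncodingScore",
    "corrected_variance_pipeline",
    "best_stage_cross_validated",
    "compute_rdm",
    "rdm_similarity_cv",
    "train_test_splits",
]

# 81 logarithmically spaced ridge penalties: every power of ten in 1e-40..1e40
RIDGE_GRID = 10.0 ** np.arange(-40, 41)


def ridge_lambda_grid() -> np.ndarray:
    return RIDGE_GRID.copy()


def critical_pearson(n: int, alpha: float = 0.05) -> float:
    """One-tailed critical Pearson correlation at sample size n (df = n−2).

    This is the reliability floor used in the noise-ceiling correction:
    0.182 at n = 83, 0.183 at n = 82.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    t = stats.t.ppf(1 - alpha, n - 2)
    return float(t / np.sqrt(n - 2 + t ** 2))


def spearman_brown(r: float, n_factor: float) -> float:
    """Prophecy formula n·r / (1 + (n−1)·r) for an n-fold data increase."""
    if r <= -1:
        raise ValidationError("correlation must be > -1")
    return float(n_factor * r / (1.0 + (n_factor - 1.0) * r))


# ---------------------------------------------------------------------------
# Ridge with exact leave-one-out selection
# ---------------------------------------------------------------------------

def _center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    return X - mu, mu


def ridge_loo_select(X_train: np.ndarray, y_train: np.ndarray,
                     lambda_grid: np.ndarray | None = None):
    """Per-target ridge fit with λ chosen by exact leave-one-out CV.

    Features are mean-centered on the training set; an unpenalized intercept
    absorbs the target mean.  The LOO errors use the closed-form identity
    e_loo = e / (1 − h_ii), which for ridge equals explicit refitting.

    Parameters
    ----------
    X_train : (n, p)
    y_train : (n,) or (n, v) — multiple targets share the SVD
    Returns dict with weights (p, v), intercept (v,), lambda (v,),
    loo_mse (L, v).
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in regression inputs")
    single = y.ndim == 1
    if single:
        y = y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 training rows")
    grid = RIDGE_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    Xc, mu = _center(X)
    ybar = y.mean(axis=0)
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else slice(0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]  # drop numerically-null directions
    Uy = U.T @ yc                                   # (k, v)
    s2 = s ** 2
    shrink = s2[None, :] / (s2[None, :] + grid[:, None])    # (L, k)
    # hat diagonal: 1/n (intercept) + sum_k shrink * u_ik^2
    U2 = U ** 2                                      # (n, k)
    h = 1.0 / n + U2 @ shrink.T                      # (n, L)
    # fitted values for all lambdas: ybar + U (shrink * Uy)
    fitted = np.einsum("nk,lk,kv->lnv", U, shrink, Uy, optimize=True)
    resid = yc[None, :, :] - fitted                  # (L, n, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = resid / (1.0 - h.T[:, :, None])
    loo_mse = np.mean(loo ** 2, axis=1)              # (L, v)
    # h_ii -> 1 (interpolating fit) gives unbounded LOO error: never selected
    loo_mse = np.where(np.isfinite(loo_mse), loo_mse, np.inf)
    best = np.argmin(loo_mse, axis=0)                # (v,)
    # final refit per chosen lambda
    v = y.shape[1]
    W = np.empty((X.shape[1], v))
    for li in np.unique(best):
        cols = np.flatnonzero(best == li)
        coef = (Vt.T * (s / (s2 + grid[li]))) @ Uy[:, cols]
        W[:, cols] = coef
    intercept = ybar - mu @ W
    out = {"weights": W[:, 0] if single else W,
           "intercept": float(intercept[0]) if single else intercept,
           "lambda": float(grid[best[0]]) if single else grid[best],
           "loo_mse": loo_mse[:, 0] if single else loo_mse,
           "feature_mean": mu}
    return out


def _predict(fit: dict, X: np.ndarray) -> np.ndarray:
    return X @ fit["weights"] + fit["intercept"]


# ---------------------------------------------------------------------------
# Noise-ceiling-corrected encoding pipeline
# ---------------------------------------------------------------------------

def train_test_splits(n_stimuli: int, n_splits: int, seed: int,
                      train_fraction: float = 83.0 / 165.0):
    """Random train/test splits with proportions matching 83/82 of 165."""
    rng = np.random.default_rng(seed)
    n_train = int(round(n_stimuli * train_fraction))
    n_train = min(max(n_train, 3), n_stimuli - 3)
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n_stimuli)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


@dataclass
class EncodingScore:
    """Per-(voxel, stage) summary: median over splits of test r², reliability
    components and corrected variance r²* = r²/(r'_v·r'_v̂)."""

    r2: np.ndarray            # (voxels,)
    r_v: np.ndarray
    r_vhat: np.ndarray
    r2_corrected: np.ndarray
    chosen_lambda: np.ndarray
    per_split: dict           # raw (splits, voxels) arrays


def _pairwise_scan_reliability(scans: np.ndarray, n_factor: float = None) -> np.ndarray:
    """Median Spearman–Brown-corrected Pearson correlation between all scan
    pairs.  ``scans``: (stimuli, voxels, n_scans)."""
    n_scans = scans.shape[2]
    if n_scans < 2:
        raise ValidationError("need >= 2 scans for reliability")
    if n_factor is None:
        n_factor = n_scans
    pairs = [(i, j) for i in range(n_scans) for j in range(i + 1, n_scans)]
    vals = []
    for i, j in pairs:
        r = _columnwise_pearson(scans[:, :, i], scans[:, :, j])
        # the prophecy formula has a pole at r = -1/(n-1); a non-positive
        # split correlation means "no measurable reliability", mapped to 0
        # (the floor applied downstream takes over from there)
        vals.append(np.array([spearman_brown(x, n_factor) if x > 0 else 0.0
                              for x in r]))
    return np.median(np.stack(vals), axis=0)


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(Ac * Bc, axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def corrected_variance_pipeline(features: np.ndarray, voxels: np.ndarray,
                                n_splits: int = 10, seed: int = 0,
                                lambda_grid: np.ndarray | None = None
                                ) -> EncodingScore:
    """Full encoding analysis for one model stage.

    Parameters
    ----------
    features : (stimuli, units) stage feature matrix (time already averaged)
    voxels : (stimuli, voxels, scans) response array

    Per split: ridge (LOO-selected λ per voxel) fit on scan-averaged training
    responses, r² on the test stimuli; voxel reliability from inter-scan
    correlations of the test responses; prediction reliability from per-scan
    fits predicting the same scan's test data.  Reliabilities are floored at
    the critical Pearson correlation for the respective sample sizes, and
    medians over splits are reported.
    """
    X = np.asarray(features, dtype=np.float64)
    V = np.asarray(voxels, dtype=np.float64)
    if X.shape[0] != V.shape[0]:
        raise ValidationError("features and voxels disagree on stimulus count")
    if V.ndim != 3 or V.shape[2] < 2:
        raise ValidationError("voxels must be (stimuli, voxels, >=2 scans)")
    n_stim, n_vox, n_scans = V.shape
    mean_resp = V.mean(axis=2)
    splits = train_test_splits(n_stim, n_splits, seed)
    r2 = np.empty((n_splits, n_vox))
    rv = np.empty((n_splits, n_vox))
    rvh = np.empty((n_splits, n_vox))
    lam = np.empty((n_splits, n_vox))
    for si, (tr, te) in enumerate(splits):
        floor_v = critical_pearson(len(tr))
        floor_vh = critical_pearson(len(te))
        fit = ridge_loo_select(X[tr], mean_resp[tr], lambda_grid)
        pred = _predict(fit, X[te])
        r = _columnwise_pearson(pred, mean_resp[te])
        r2[si] = r ** 2
        lam[si] = fit["lambda"]
        rv[si] = np.maximum(_pairwise_scan_reliability(V[te]), floor_v)
        scan_preds = []
        for sc in range(n_scans):
            fit_sc = ridge_loo_select(X[tr], V[tr, :, sc], lambda_grid)
            scan_preds.append(_predict(fit_sc, X[te]))
        rvh[si] = np.maximum(
            _pairwise_scan_reliability(np.stack(scan_preds, axis=2)), floor_vh)
    r2_med = np.median(r2, axis=0)
    rv_med = np.median(rv, axis=0)
    rvh_med = np.median(rvh, axis=0)
    r2_star = np.median(r2 / (rv * rvh), axis=0)
    return EncodingScore(r2_med, rv_med, rvh_med, r2_star,
                         np.median(lam, axis=0),
                         {"r2": r2, "r_v": rv, "r_vhat": rvh, "lambda": lam})


def best_stage_cross_validated(summaries: np.ndarray, stage_names: list | None = None
                               ) -> dict:
    """Leave-one-participant-out best-stage selection.

    ``summaries``: (participants, stages) — e.g. ROI medians of corrected
    variance explained.  Each participant is scored at the stage that
    maximizes the average of the *other* participants' summaries.
    """
    S = np.asarray(summaries, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValidationError("need a (participants >= 2, stages) summary array")
    n_part, n_stage = S.shape
    chosen = np.empty(n_part, dtype=int)
    held_out = np.empty(n_part)
    for i in range(n_part):
        others = np.delete(S, i, axis=0).mean(axis=0)
        chosen[i] = int(np.argmax(others))
        held_out[i] = S[i, chosen[i]]
    modal = int(np.bincount(chosen, minlength=n_stage).argmax())
    out = {"per_participant": held_out, "chosen_stage": chosen,
           "mean": float(held_out.mean()), "modal_stage": modal}
    if stage_names is not None:
        out["modal_stage_name"] = stage_names[modal]
    return out


# ---------------------------------------------------------------------------
# Representational similarity
# ---------------------------------------------------------------------------

def compute_rdm(responses: np.ndarray, zscore_axis: str = "unit") -> np.ndarray:
    """Representational dissimilarity matrix: 1 − Pearson r between stimulus
    patterns after z-scoring each unit across stimuli (``zscore_axis``
    'stimulus' z-scores each pattern instead).  Zero-variance units are
    dropped with a warning-free mask."""
    R = np.asarray(responses, dtype=np.float64)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValidationError("need (stimuli >= 2, units >= 2) responses")
    if zscore_axis == "unit":
        sd = R.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValidationError("all units have zero variance")
        Z = (R[:, keep] - R[:, keep].mean(axis=0)) / sd[keep]
    elif zscore_axis == "stimulus":
        Z = (R - R.mean(axis=1, keepdims=True)) / R.std(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown zscore_axis {zscore_axis!r}")
    C = np.corrcoef(Z)
    rdm = 1.0 - C
    np.fill_diagonal(rdm, 0.0)
    return rdm


def _upper(rdm: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(rdm.shape[0], k=1)
    return rdm[iu]


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.spearmanr(a, b).statistic)


def rdm_similarity_cv(stage_features: dict, participant_voxels: list,
                      n_splits: int = 10, seed: int = 0) -> dict:
    """Cross-validated RDM similarity with best-stage selection on train
    stimuli, plus a leave-one-participant-out ceiling.

    ``stage_features``: stage name -> (stimuli, units); ``participant_voxels``:
    list of (stimuli, voxels) scan-averaged responses.  Per split the stage
    with the highest train-RDM Spearman ρ (per participant) is scored on the
    test stimuli; the per-participant result is the median over splits.  The
    ceiling correlates each participant's test RDM with the average of the
    others'.
    """
    stages = list(stage_features)
    n_stim = next(iter(stage_features.values())).shape[0]
    if n_stim < 6:
        raise ValidationError("too few stimuli to split")
    n_part = len(participant_voxels)
    if n_part < 2:
        raise ValidationError("need >= 2 participants for the ceiling")
    splits = train_test_splits(n_stim, n_splits, seed)
    rho = np.empty((n_part, n_splits))
    picked = np.empty((n_part, n_splits), dtype=int)
    ceiling = np.empty((n_part, n_splits))
    part_rdm_te = []
    for si, (tr, te) in enumerate(splits):
        model_tr = {s: compute_rdm(f[tr]) for s, f in stage_features.items()}
        model_te = {s: compute_rdm(f[te]) for s, f in stage_features.items()}
        rdm_te_all = []
        for p, vox in enumerate(participant_voxels):
            p_tr = compute_rdm(vox[tr])
            p_te = compute_rdm(vox[te])
            rdm_te_all.append(p_te)
            train_rhos = [_spearman(_upper(model_tr[s]), _upper(p_tr))
                          for s in stages]
            best = int(np.argmax(train_rhos))
            picked[p, si] = best
            rho[p, si] = _spearman(_upper(model_te[stages[best]]), _upper(p_te))
        for p in range(n_part):
            others = np.mean([rdm_te_all[q] for q in range(n_part) if q != p], axis=0)
            ceiling[p, si] = _spearman(_upper(rdm_te_all[p]), _upper(others))
        part_rdm_te.append(rdm_te_all)
    per_part = np.median(rho, axis=1)
    modal = [int(np.bincount(picked[p], minlength=len(stages)).argmax())
             for p in range(n_part)]
    return {
        "per_participant_rho": per_part,
        "mean_rho": float(per_part.mean()),
        "chosen_stage": [stages[m] for m in modal],
        "ceiling_per_participant": np.median(ceiling, axis=1),
        "ceiling": float(np.mean(np.median(ceiling, axis=1))),
    }
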