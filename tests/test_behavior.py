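"""Behavioral statistics: permutation ANOVA and split-half reliability."""

import numpy as np
import pandas as pd
import pytest

import metamerlab as ml
from metamerlab import behavior
from metamerlab.behavior import RESPONSE_COLUMNS
from metamerlab.signals import ValidationError

from conftest import make_response_table


def _anova_ss_oracle(Y, groups):
    """Independent textbook sums-of-squares computation (balanced design)."""
    n, w = Y.shape
    labs = np.unique(groups)
    gm = Y.mean()
    ss_b = sum(w * (groups == g).sum() * (Y[groups == g].mean() - gm) ** 2
               for g in labs)
    ss_subj_tot = w * np.sum((Y.mean(axis=1) - gm) ** 2)
    ss_w = n * np.sum((Y.mean(axis=0) - gm) ** 2)
    ss_int = 0.0
    for g in labs:
        sub = Y[groups == g]
        for j in range(w):
            ss_int += sub.shape[0] * (sub[:, j].mean() - sub.mean()
                                      - Y[:, j].mean() + gm) ** 2
    ss_tot_within = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2)
    ss_subj_within = ss_subj_tot - ss_b
    ss_err = ss_tot_within - ss_w - ss_int
    g = len(labs)
    return {
        "main_observer": (ss_b / (g - 1)) / (ss_subj_within / (n - g)),
        "interaction": (ss_int / ((g - 1) * (w - 1))) / (ss_err / ((n - g) * (w - 1))),
        "main_stage": (ss_w / (w - 1)) / (ss_err / ((n - g) * (w - 1))),
    }


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("effect", ["main_observer", "interaction"])
def test_f_matches_ss_oracle_on_random_designs(seed, effect):
    rng = np.random.default_rng(seed)
    accs = {"human": {"c1": 0.7, "c2": 0.5, "c3": 0.9},
            "model": {"c1": 0.8, "c2": 0.8, "c3": 0.8}}
    tab = make_response_table(rng, accs, n_per_group=4 + seed % 3)
    res = ml.mixed_anova_permutation(tab, "mixed", effect, n_perm=10, seed=0)
    acc = behavior.accuracy_table(tab)
    pivot = acc.pivot_table(index=["participant_id", "observer_type"],
                            columns="condition", values="accuracy")
    Y = pivot.to_numpy()
    groups = pivot.index.get_level_values(1).to_numpy()
    assert res.f_observed == pytest.approx(_anova_ss_oracle(Y, groups)[effect],
                                           rel=1e-10)
    assert 0.0 <= res.eta_p2 <= 1.0


def test_single_factor_f_matches_oracle():
    rng = np.random.default_rng(7)
    accs = {"human": {"c1": 0.9, "c2": 0.6, "c3": 0.3}}
    tab = make_response_table(rng, accs, groups=("human",), n_per_group=6)
    res = ml.mixed_anova_permutation(tab, "single_factor", "main_stage",
                                     n_perm=50, seed=1)
    acc = behavior.accuracy_table(tab)
    Y = acc.pivot_table(index="participant_id", columns="condition",
                        values="accuracy").to_numpy()
    n, w = Y.shape
    gm = Y.mean()
    ss_w = n * np.sum((Y.mean(axis=0) - gm) ** 2)
    ss_subj = w * np.sum((Y.mean(axis=1) - gm) ** 2)
    ss_err = np.sum((Y - gm) ** 2) - ss_w - ss_subj
    f = (ss_w / (w - 1)) / (ss_err / ((n - 1) * (w - 1)))
    assert res.f_observed == pytest.approx(f, rel=1e-10)
    assert res.p < 0.05


def test_identical_groups_give_zero_f():
    """Two observer groups with identical accuracies: no main effect."""
    rng = np.random.default_rng(3)
    rows = []
    for i in range(4):
        n_ok = rng.integers(2, 9, size=3)  # participant-specific accuracies
        for g in ("human", "model"):  # mirrored across observer groups
            for c, cond in enumerate(["s1", "s2", "s3"]):
                for t in range(10):
                    ok = t < n_ok[c]
                    rows.append((f"{g}{i}", g, cond, f"st{t}", "a",
                                 "a" if ok else "b", ok))
    tab = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    res = ml.mixed_anova_permutation(tab, "mixed", "main_observer",
                                     n_perm=200, seed=0)
    assert res.f_observed == pytest.approx(0.0, abs=1e-20)
    assert res.p > 0.5


def test_interaction_power():
    """Humans declining with stage while models stay at ceiling is detected
    at p <= 0.01 in nearly every replicate (n = 20 per group)."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        rng = np.random.default_rng(100 + rep)
        accs = {"human": {"s1": 0.95, "s2": 0.6, "s3": 0.2},
                "model": {"s1": 0.97, "s2": 0.97, "s3": 0.97}}
        tab = make_response_table(rng, accs, n_per_group=20, n_trials=20)
        res = ml.mixed_anova_permutation(tab, "mixed", "interaction",
                                         n_perm=500, seed=rep)
        hits += res.p <= 0.01
    assert hits >= int(0.95 * n_rep)


def test_anova_validation():
    rng = np.random.default_rng(0)
    accs = {"human": {"c1": 0.7, "c2": 0.7}, "model": {"c1": 0.8, "c2": 0.8}}
    tab = make_response_table(rng, accs)
    bad = tab[~((tab.participant_id == "human0") & (tab.condition == "c1"))]
    with pytest.raises(ValidationError, match="cell"):
        ml.mixed_anova_permutation(bad, "mixed", "main_observer", n_perm=10)
    with pytest.raises(ValidationError):
        ml.mixed_anova_permutation(tab, "mixed", "main_observer", n_perm=0)


def test_response_table_validation():
    rows = [("p0", "human", "c", "s0", "a", "b", True)]  # inconsistent flag
    with pytest.raises(ValidationError):
        behavior.validate_response_table(pd.DataFrame(rows,
                                                      columns=RESPONSE_COLUMNS))


# -- split-half confusion matrices ------------------------------------------

def _consistent_confusion_table(rng, n_part=8, n_trials=60, p_correct=0.3):
    """Errors concentrate on one specific wrong class per true class."""
    classes = ["a", "b", "c", "d"]
    target_error = {"a": "b", "b": "a", "c": "d", "d": "c"}
    rows = []
    for i in range(n_part):
        for t in range(n_trials):
            true = classes[t % 4]
            if rng.random() < p_correct:
                resp = true
            elif rng.random() < 0.9:
                resp = target_error[true]
            else:
                resp = rng.choice([c for c in classes if c != true])
            rows.append((f"p{i}", "human", "meta", f"st{t}", true, resp,
                         true == resp))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def test_split_half_consistent_confusions():
    tab = _consistent_confusion_table(np.random.default_rng(0))
    res = ml.confusion_split_half(tab, "meta", n_splits=200, seed=1)
    assert res.n_overlap == 0
    assert res.p == pytest.approx(1 / 200)
    assert res.mean_rho > 0.5


def test_split_half_formula_contract():
    tab = _consistent_confusion_table(np.random.default_rng(2), p_correct=0.9)
    res = ml.confusion_split_half(tab, "meta", n_splits=100, seed=3)
    assert res.p == (1 + res.n_overlap) / 100


def test_split_half_random_responses_not_significant():
    """Uniform guessing: true and shuffled splits are exchangeable."""
    ps = []
    for rep in range(5):
        rng = np.random.default_rng(10 + rep)
        classes = ["a", "b", "c", "d"]
        rows = [(f"p{i}", "human", "x", f"st{t}", classes[t % 4],
                 classes[rng.integers(4)],
                 classes[t % 4] == classes[rng.integers(4)]) for i in range(8)
                for t in range(40)]
        tab = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
        tab["correct"] = tab.true_class == tab.response_class
        ps.append(ml.confusion_split_half(tab, "x", n_splits=100,
                                          seed=rep).p)
    assert np.mean(ps) > 0.2


def test_confusion_row_normalization():
    tab = _consistent_confusion_table(np.random.default_rng(4))
    counts = behavior.confusion_matrix_counts(tab, ["a", "b", "c", "d"])
    normed = counts / counts.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(normed.sum(axis=1), 1.0)


def test_split_half_validation():
    tab = _consistent_confusion_table(np.random.default_rng(5), n_part=3)
    with pytest.raises(ValidationError):
        ml.confusion_split_half(tab, "meta")
    with pytest.raises(ValidationError):
        ml.confusion_split_half(tab, "absent-condition")


# -- per-stimulus reliability ------------------------------------------------

def _item_table(rng, item_difficulty, n_part=10):
    """Every participant attempts every stimulus once; per-item p(correct)."""
    rows = []
    for i in range(n_part):
        for s, p in enumerate(item_difficulty):
            ok = rng.random() < p
            rows.append((f"p{i}", "human", "c", f"s{s:03d}", "a",
                         "a" if ok else "b", ok))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def test_item_reliability_deterministic_difficulty():
    rng = np.random.default_rng(0)
    difficulty = np.tile([0.02, 0.98], 20)  # items always missed or always hit
    rho, p = behavior.per_stimulus_reliability(_item_table(rng, difficulty),
                                               "c", n_splits=100, seed=1)
    assert rho > 0.8
    assert p == pytest.approx(1 / 100)


def test_item_reliability_exchangeable_items():
    rng = np.random.default_rng(1)
    difficulty = np.full(40, 0.5)
    rho, _ = behavior.per_stimulus_reliability(_item_table(rng, difficulty),
                                               "c", n_splits=100, seed=2)
    assert abs(rho) < 0.25


def test_item_reliability_trial_minimum():
    """Stimuli with fewer than min_trials in a half are excluded."""
    rng = np.random.default_rng(2)
    tab = _item_table(rng, np.full(10, 0.5), n_part=6)  # 3 per half < 4
    with pytest.raises(ValidationError):
        behavior.per_stimulus_reliability(tab, "c", n_splits=10, seed=0)


# -- most/least recognizable items -------------------------------------------

def test_extreme_items_with_spread():
    rng = np.random.default_rng(0)
    difficulty = np.concatenate([np.full(30, 0.1), np.full(30, 0.9)])
    res = behavior.extreme_item_consistency(_item_table(rng, difficulty, 12),
                                            "c", k=20, n_splits=200, seed=1)
    assert res["proportion_greater"] >= 0.95
    assert res["p"] <= 0.05


def test_extreme_items_no_item_effects():
    rng = np.random.default_rng(1)
    res = behavior.extreme_item_consistency(_item_table(rng, np.full(60, 0.5), 12),
                                            "c", k=20, n_splits=200, seed=2)
    assert 0.2 < res["proportion_greater"] < 0.8


def test_extreme_items_k_too_large():
    rng = np.random.default_rng(2)
    with pytest.raises(ValidationError):
        behavior.extreme_item_consistency(_item_table(rng, np.full(10, 0.5)),
                                          "c", k=50)
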