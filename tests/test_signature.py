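from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secromine.signature import (
    derive_panel,
    evaluate_panel,
    fisher_combine,
    loocv_backward_elimination,
    per_protein_auc,
    roc_auc,
    score_group,
    train_decision_function,
    wilcoxon_rank_sum,
)

from conftest import rng


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_enumeration_p(x, y):
    """Brute-force two-sided rank-sum p over all label arrangements."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def test_exact_p_for_fully_separated_triples():
    p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2 of 20 arrangements as extreme


def test_identical_multisets_give_p_one():
    assert wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_exact_method_matches_enumeration(seed):
    g = rng(seed)
    nx, ny = int(g.integers(2, 6)), int(g.integers(2, 6))
    vals = g.permutation(np.arange(1.0, nx + ny + 1))  # tie-free
    x, y = vals[:nx], vals[nx:]
    assert wilcoxon_rank_sum(x, y) == pytest.approx(_exact_enumeration_p(x, y))


def test_empty_input_error():
    with pytest.raises(ValueError, match="nonempty"):
        wilcoxon_rank_sum([], [1.0])


def test_null_rejection_rate_calibrated():
    g = rng(5)
    rej = 0
    reps = 400
    for _ in range(reps):
        x, y = g.normal(0, 1, 20), g.normal(0, 1, 20)
        rej += wilcoxon_rank_sum(x, y) <= 0.05
    assert abs(rej / reps - 0.05) <= 0.03


# ---------------------------------------------------------------------------
# group scoring


def test_fisher_combination_of_two_halves():
    # -2(ln 0.5 + ln 0.5) = 2.7726 on 4 df
    assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=2e-4)


def test_single_protein_score_equals_its_wilcoxon_p():
    g = rng(6)
    X = pd.DataFrame([g.normal(0, 1, 12)], index=["P1"],
                     columns=[f"s{i}" for i in range(12)])
    labels = np.array([True] * 6 + [False] * 6)
    expected = wilcoxon_rank_sum(X.iloc[0, :6], X.iloc[0, 6:])
    assert score_group(X, labels) == pytest.approx(expected)


def test_noise_protein_worsens_a_significant_group():
    g = rng(7)
    labels = np.array([True] * 10 + [False] * 10)
    cols = [f"s{i}" for i in range(20)]
    worse = 0
    reps = 40
    for _ in range(reps):
        strong = np.where(labels, 2.0, 0.0) + g.normal(0, 0.5, 20)
        noise = g.normal(0, 1, 20)
        X1 = pd.DataFrame([strong], index=["P1"], columns=cols)
        X2 = pd.DataFrame([strong, noise], index=["P1", "P2"], columns=cols)
        worse += score_group(X2, labels) > score_group(X1, labels)
    assert worse / reps > 0.7


# ---------------------------------------------------------------------------
# linear SVM decision values


def _toy(n=20, sep=1.0, sd=0.1, seed=8):
    g = rng(seed)
    x = np.concatenate([g.normal(-sep, sd, n // 2), g.normal(sep, sd, n // 2)])
    X = pd.DataFrame([x], index=["P1"], columns=[f"s{i}" for i in range(n)])
    y = np.array([False] * (n // 2) + [True] * (n // 2))
    return X, y


def test_separable_training_values_correctly_signed():
    X, y = _toy()
    model = train_decision_function(X, y)
    d = model.decision_values(X)
    assert np.all(d[y] > 0) and np.all(d[~y] < 0)


def test_duplicated_feature_leaves_decision_values_unchanged():
    X, y = _toy(seed=9)
    X2 = pd.concat([X, X.rename(index={"P1": "P1b"})])
    d1 = train_decision_function(X, y).decision_values(X)
    d2 = train_decision_function(X2, y).decision_values(X2)
    np.testing.assert_allclose(d1, d2, atol=1e-6)


def test_single_class_is_an_error():
    X, _ = _toy()
    with pytest.raises(ValueError, match="single class"):
        train_decision_function(X, np.ones(X.shape[1], bool))


def test_permuted_labels_give_chance_auc():
    g = rng(10)
    X, y = _toy(n=40, sep=2.0, seed=10)
    aucs = []
    for _ in range(25):
        yp = g.permutation(y)
        if yp.all() or not yp.any():
            continue
        model = train_decision_function(X, yp)
        aucs.append(roc_auc(model.decision_values(X), yp).auc)
    assert 0.35 < np.mean(aucs) < 0.75  # training fit inflates slightly


# ---------------------------------------------------------------------------
# ROC / AUC


def test_perfect_separation_auc_one():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]).auc == 1.0


def test_three_of_four_concordant_pairs():
    curve = roc_auc([0.9, 0.7, 0.8, 0.6], [True, True, False, False])
    assert curve.auc == pytest.approx(0.75)


def test_complete_ties_give_half():
    assert roc_auc([1.0] * 6, [True] * 3 + [False] * 3).auc == pytest.approx(0.5)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.2], [True, True])


def _brute_force_auc(values, y):
    pos = values[y]
    neg = values[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("seed,n", [(0, 20), (1, 57), (2, 200)])
def test_auc_matches_all_pairs_concordance(seed, n):
    g = rng(seed)
    values = np.round(g.normal(0, 1, n), 1)  # rounding forces ties
    y = g.random(n) < 0.5
    if y.all() or not y.any():
        y[0] = ~y[0]
    assert roc_auc(values, y).auc == pytest.approx(_brute_force_auc(values, y), abs=1e-12)


def test_auc_invariant_under_monotone_transforms():
    g = rng(3)
    values = g.normal(0, 1, 80)
    y = g.random(80) < 0.4
    base = roc_auc(values, y).auc
    for f in (lambda v: 3 * v + 7, np.tanh, lambda v: np.exp(v / 2)):
        assert roc_auc(f(values), y).auc == pytest.approx(base, abs=1e-12)


def test_curve_endpoints_and_ranges():
    g = rng(4)
    curve = roc_auc(g.normal(0, 1, 50), g.random(50) < 0.5)
    assert np.all((curve.sensitivity >= 0) & (curve.sensitivity <= 1))
    assert np.all((curve.specificity >= 0) & (curve.specificity <= 1))


# ---------------------------------------------------------------------------
# per-protein AUC


def test_planted_marker_has_high_auc_and_orientation_symmetry():
    g = rng(5)
    n = 60
    y = np.array([True] * 30 + [False] * 30)
    up = np.where(y, 2.0, 0.0) + g.normal(0, 0.5, n)
    X = pd.DataFrame(
        {"c" + str(i): v for i, v in enumerate(np.vstack([up, -up, g.normal(0, 1, n)]).T)}
    )
    X.index = ["up", "down", "null"]
    aucs = per_protein_auc(X, y)
    assert aucs["up"] > 0.9
    assert aucs["down"] == pytest.approx(aucs["up"])  # mirrored twin
    assert 0.3 < aucs["null"] < 0.75


def test_null_proteins_center_at_half():
    g = rng(6)
    y = g.random(40) < 0.5
    X = pd.DataFrame(g.normal(0, 1, (100, 40)),
                     index=[f"P{i}" for i in range(100)],
                     columns=[f"s{i}" for i in range(40)])
    # unoriented concordance centers at chance level
    raw = np.array([roc_auc(row.to_numpy(), y).auc for _, row in X.iterrows()])
    assert abs(raw.mean() - 0.5) < 0.05
    oriented = per_protein_auc(X, y)
    assert (oriented >= 0.5).all()  # orientation guarantee
    np.testing.assert_allclose(oriented, np.maximum(raw, 1 - raw), atol=1e-12)


# ---------------------------------------------------------------------------
# LOOCV backward elimination


def _planted_matrix(n_informative=2, n_null=8, n_per_class=10, effect=2.0, seed=0):
    g = rng(seed)
    n = 2 * n_per_class
    y = np.array([True] * n_per_class + [False] * n_per_class)
    rows = []
    names = []
    for i in range(n_informative):
        rows.append(np.where(y, effect, 0.0) + g.normal(0, 0.5, n))
        names.append(f"INF{i}")
    for i in range(n_null):
        rows.append(g.normal(0, 1, n))
        names.append(f"NULL{i}")
    X = pd.DataFrame(rows, index=names, columns=[f"s{i}" for i in range(n)])
    return X, pd.Series(y, index=X.columns)


def test_single_protein_degenerate_path():
    X, y = _planted_matrix(n_informative=1, n_null=0, seed=1)
    res = loocv_backward_elimination(X, y)
    assert res.chosen_size == 1 and res.chosen_panel == ["INF0"]
    assert list(res.auc_by_size.index) == [1]
    assert res.loo_decision_values[1].notna().all()


def test_planted_informative_proteins_survive_elimination():
    hits = 0
    for seed in range(5):
        X, y = _planted_matrix(seed=seed)
        res = loocv_backward_elimination(X, y)
        kept = set(res.elimination_path[2])
        hits += kept == {"INF0", "INF1"}
    assert hits >= 4


def test_elimination_path_nested_and_deterministic():
    X, y = _planted_matrix(seed=3)
    res1 = loocv_backward_elimination(X, y)
    res2 = loocv_backward_elimination(X, y)
    assert res1.chosen_panel == res2.chosen_panel
    pd.testing.assert_frame_equal(res1.loo_decision_values, res2.loo_decision_values)
    sizes = sorted(res1.elimination_path, reverse=True)
    assert sizes == list(range(X.shape[0], 0, -1))
    for big, small in zip(sizes, sizes[1:]):
        assert set(res1.elimination_path[small]) < set(res1.elimination_path[big])


def test_all_null_matrix_gives_chance_level_auc():
    # individual sizes scatter widely (fold-wise selection regresses the
    # left-out sample toward the wrong side); the run-level mean over sizes,
    # averaged over replicates, sits at chance
    means = []
    for seed in range(3):
        g = rng(seed)
        X = pd.DataFrame(g.normal(0, 1, (10, 48)),
                         index=[f"P{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(48)])
        y = pd.Series([True] * 24 + [False] * 24, index=X.columns)
        res = loocv_backward_elimination(X, y)
        means.append(res.auc_by_size.mean())
    assert 0.35 <= np.mean(means) <= 0.65


def test_degenerate_class_sizes_rejected():
    X, _ = _planted_matrix()
    y = pd.Series([True] * 2 + [False] * 18, index=X.columns)
    with pytest.raises(ValueError, match="3 per class"):
        loocv_backward_elimination(X, y)


def test_prefilter_caps_start_set():
    X, y = _planted_matrix(n_informative=2, n_null=20, seed=4)
    res = loocv_backward_elimination(X, y, max_start_proteins=6)
    assert max(res.elimination_path) == 6
    assert {"INF0", "INF1"} <= set(res.elimination_path[6])


def test_derive_panel_matches_path():
    X, y = _planted_matrix(seed=5)
    res = loocv_backward_elimination(X, y)
    assert sorted(derive_panel(X, y, res.chosen_size)) == res.chosen_panel


# ---------------------------------------------------------------------------
# fixed-panel evaluation


def test_empty_panel_error():
    X, y = _planted_matrix()
    with pytest.raises(ValueError, match="empty panel"):
        evaluate_panel([], X, y, X, y)


def test_missing_panel_protein_named():
    X, y = _planted_matrix()
    with pytest.raises(KeyError, match="GHOST"):
        evaluate_panel(["GHOST"], X, y, X, y)


def test_training_cohort_as_test_is_optimistic():
    X, y = _planted_matrix(n_informative=2, n_null=4, effect=1.0, seed=6)
    res = loocv_backward_elimination(X, y)
    panel = res.chosen_panel
    resub = evaluate_panel(panel, X, y, X, y)
    assert resub.auc >= res.auc_by_size[res.chosen_size] - 1e-9


def test_transfer_evaluation_on_fresh_cohort():
    Xtr, ytr = _planted_matrix(effect=1.5, seed=7)
    Xte, yte = _planted_matrix(effect=1.5, seed=8)
    curve = evaluate_panel(["INF0", "INF1"], Xtr, ytr, Xte, yte)
    assert curve.auc > 0.9
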