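"""Biomarker-signature search and evaluation.

The wrapper search works per left-out sample: starting from the full protein
set, every single-protein removal is scored (per-protein two-sided Wilcoxon
rank-sum p-values of the remaining group, combined by Fisher's method), the
most significant remaining group is kept, a linear soft-margin SVM (cost 1,
features standardized with training statistics) is trained on the remaining
samples, and the left-out sample's decision value is recorded — down to a
single protein.  Decision values are pooled across folds per panel size;
the size with the best pooled ROC AUC wins (smallest size on ties) and the
final panel is re-derived by running the identical elimination on the full
training set.  Fixed panels are evaluated on an independent test cohort by
training on the whole training cohort and scoring the test samples.

Everything here is deterministic given the input order; ties in the
elimination are broken by the smaller absolute group-mean difference, then
lexicographically by protein id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

__all__ = [
    "RocCurve",
    "DecisionModel",
    "SignatureResult",
    "wilcoxon_rank_sum",
    "fisher_combine",
    "score_group",
    "train_decision_function",
    "roc_auc",
    "per_protein_auc",
    "derive_panel",
    "loocv_backward_elimination",
    "evaluate_panel",
]

_TINY_P = 1e-300


# ---------------------------------------------------------------------------
# rank statistics


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null enumeration when nA + nB <= ``exact_limit`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum needs two nonempty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # complete ties: no evidence either way
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= exact_limit and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def fisher_combine(pvalues) -> float:
    """Fisher's method: −2·Σ ln p against chi-square with 2k d.f."""
    p = np.clip(np.asarray(pvalues, dtype=float), _TINY_P, 1.0)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, 2 * p.size))


def _per_protein_pvalues(X: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Wilcoxon p per protein (row of X) for a binary label vector."""
    out = {}
    for prot, row in X.iterrows():
        v = row.to_numpy(dtype=float)
        out[prot] = wilcoxon_rank_sum(v[labels], v[~labels])
    return pd.Series(out)


def score_group(X: pd.DataFrame, labels, method: str = "fisher") -> float:
    """Significance score of a protein group (smaller = more significant).

    ``fisher`` (default): Fisher combination of the per-protein Wilcoxon
    p-values.  ``decision-wilcoxon``: Wilcoxon p of the group's SVM training
    decision values between the classes.
    """
    if X.shape[0] == 0:
        raise ValueError("empty protein group")
    labels = _as_bool_labels(labels, X.columns)
    if method == "fisher":
        return fisher_combine(_per_protein_pvalues(X, labels).to_numpy())
    if method == "decision-wilcoxon":
        model = train_decision_function(X, labels)
        d = model.decision_values(X)
        return wilcoxon_rank_sum(d[labels], d[~labels])
    raise ValueError(f"unknown group score method {method!r}")


# ---------------------------------------------------------------------------
# linear SVM decision values


def _as_bool_labels(labels, columns) -> np.ndarray:
    """Coerce labels to a boolean case vector aligned with the sample axis."""
    if isinstance(labels, pd.Series):
        labels = labels.reindex(columns).to_numpy()
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    uniq = sorted(pd.unique(arr).tolist())
    if len(uniq) == 1:
        return arr == uniq[0]
    if len(uniq) != 2:
        raise ValueError(f"labels must be binary, got {uniq}")
    return arr == uniq[1]  # lexicographically larger label = positive class


@dataclass
class DecisionModel:
    """Linear SVM plus the training standardization statistics."""

    proteins: list[str]
    mean: np.ndarray
    sd: np.ndarray
    svc: SVC

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        """Signed margin distances; class call = sign at threshold zero."""
        missing = [p for p in self.proteins if p not in X.index]
        if missing:
            raise KeyError(f"panel protein(s) missing from matrix: {missing}")
        Z = (X.loc[self.proteins].to_numpy(dtype=float).T - self.mean) / self.sd
        return self.svc.decision_function(Z)


def train_decision_function(X: pd.DataFrame, labels) -> DecisionModel:
    """Train a maximal-margin linear classifier (cost 1) on proteins × samples.

    Features are standardized with the training mean/SD; the same statistics
    are applied to later samples.  Raises on single-class input.
    """
    y = _as_bool_labels(labels, X.columns)
    if y.all() or not y.any():
        raise ValueError("training data contain a single class")
    data = X.to_numpy(dtype=float).T  # samples × features
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (data - mean) / sd
    svc = SVC(kernel="linear", C=1.0)
    svc.fit(Z, y.astype(int))
    return DecisionModel(proteins=list(X.index), mean=mean, sd=sd, svc=svc)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _mann_whitney_auc(values: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected concordance P(case value > control value) + ½ P(tie)."""
    ranks = stats.rankdata(values)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(decision_values, labels) -> RocCurve:
    """ROC curve and AUC of decision values against binary labels.

    The AUC is the tie-corrected Mann–Whitney concordance (identical to the
    area under the step curve); all-equal values give 0.5.
    """
    values = np.asarray(decision_values, dtype=float)
    y = _as_bool_labels(labels, None) if not isinstance(labels, pd.Series) else _as_bool_labels(
        labels, labels.index
    )
    if y.all() or not y.any():
        raise ValueError("roc_auc needs both classes present")
    if values.shape != y.shape:
        raise ValueError("decision values and labels differ in length")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), values, drop_intermediate=False)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=_mann_whitney_auc(values, y),
    )


def per_protein_auc(X: pd.DataFrame, labels) -> pd.Series:
    """Single-protein AUCs, each oriented so AUC >= 0.5.

    Missing samples are excluded per protein; proteins with fewer than two
    samples in a class get NaN.
    """
    y = _as_bool_labels(labels, X.columns)
    out = {}
    for prot, row in X.iterrows():
        v = row.to_numpy(dtype=float)
        ok = np.isfinite(v)
        yy = y[ok]
        if yy.sum() < 2 or (~yy).sum() < 2:
            out[prot] = np.nan
            continue
        a = _mann_whitney_auc(v[ok], yy)
        out[prot] = max(a, 1.0 - a)
    return pd.Series(out, name="auc")


# ---------------------------------------------------------------------------
# backward elimination


def _elimination_order(
    X: pd.DataFrame,
    labels: np.ndarray,
    group_score: str = "fisher",
) -> list[str]:
    """Full removal order (first removed → last removed) for one data set.

    At each step every single-protein removal is scored; the removal whose
    remaining group scores best (smallest combined p) is applied.  Tie-break:
    smaller |group-mean difference| first, then protein id.
    """
    proteins = list(X.index)
    abs_delta = (
        X.loc[:, X.columns[labels]].mean(axis=1) - X.loc[:, X.columns[~labels]].mean(axis=1)
    ).abs()
    order: list[str] = []
    if group_score == "fisher":
        pvals = _per_protein_pvalues(X, labels)
        neg2ln = -2.0 * np.log(np.clip(pvals, _TINY_P, 1.0))
        current = list(proteins)
        total = float(neg2ln[current].sum())
        while len(current) > 1:
            stat_wo = total - neg2ln[current].to_numpy()
            p_wo = stats.chi2.sf(stat_wo, 2 * (len(current) - 1))
            cand = pd.DataFrame(
                {
                    "p": p_wo,
                    "delta": abs_delta[current].to_numpy(),
                    "prot": current,
                }
            )
            cand = cand.sort_values(["p", "delta", "prot"], kind="stable")
            drop = cand.iloc[0]["prot"]
            order.append(drop)
            current.remove(drop)
            total -= float(neg2ln[drop])
        order.append(current[0])
        return order
    # generic (group-dependent) scorer: quadratic number of score calls
    current = list(proteins)
    while len(current) > 1:
        best = None
        for j in current:
            rest = [p for p in current if p != j]
            s = score_group(X.loc[rest], labels, method=group_score)
            key = (s, float(abs_delta[j]), j)
            if best is None or key < best[0]:
                best = (key, j)
        order.append(best[1])
        current.remove(best[1])
    order.append(current[0])
    return order


def _sets_from_order(proteins: list[str], order: list[str]) -> dict[int, tuple[str, ...]]:
    """Nested kept-sets by size implied by a removal order (incl. full size)."""
    sets: dict[int, tuple[str, ...]] = {len(proteins): tuple(proteins)}
    current = list(proteins)
    for drop in order[:-1]:
        current.remove(drop)
        sets[len(current)] = tuple(current)
    return sets


def derive_panel(
    X: pd.DataFrame,
    labels,
    size: int,
    group_score: str = "fisher",
) -> list[str]:
    """Backward-eliminate on the full data down to ``size`` proteins."""
    y = _as_bool_labels(labels, X.columns)
    if not (1 <= size <= X.shape[0]):
        raise ValueError(f"panel size {size} out of range 1..{X.shape[0]}")
    order = _elimination_order(X, y, group_score)
    return list(_sets_from_order(list(X.index), order)[size])


@dataclass
class SignatureResult:
    """Outcome of the LOOCV backward-elimination search."""

    elimination_path: dict[int, tuple[str, ...]]  # full-training nested sets
    loo_decision_values: pd.DataFrame  # samples × sizes, pooled LOO outputs
    auc_by_size: pd.Series
    chosen_size: int
    chosen_panel: list[str]
    fold_orders: dict[str, list[str]] = field(default_factory=dict)
    labels: pd.Series | None = None
    test_auc: float | None = None

    def fold_selection_frequency(self) -> pd.Series:
        """How often each protein survived to the chosen size across folds."""
        counts: dict[str, int] = {}
        for sid, order in self.fold_orders.items():
            kept = order[-self.chosen_size:]
            for p in kept:
                counts[p] = counts.get(p, 0) + 1
        return pd.Series(counts).sort_values(ascending=False) / max(len(self.fold_orders), 1)


def _impute_row_median(X: pd.DataFrame) -> pd.DataFrame:
    if not X.isna().to_numpy().any():
        return X
    med = X.median(axis=1, skipna=True)
    return X.apply(lambda col: col.fillna(med))


def loocv_backward_elimination(
    X: pd.DataFrame,
    labels,
    group_score: str = "fisher",
    max_start_proteins: int = 200,
) -> SignatureResult:
    """Leave-one-out wrapper search for a discriminating protein panel.

    ``X`` is proteins × samples; ``labels`` a binary vector/Series over the
    samples.  For each left-out sample the elimination is re-run on the
    remaining samples and the left-out decision value recorded at every
    panel size; sizes are scored by pooled ROC AUC, the best size (smallest
    on ties) is re-derived on the full training set.

    With more than ``max_start_proteins`` proteins, the start set is
    pre-filtered to the proteins with the smallest full-training Wilcoxon
    p-values (logged in the result's elimination path domain).
    """
    y = _as_bool_labels(labels, X.columns)
    if X.shape[1] < 6 or y.sum() < 3 or (~y).sum() < 3:
        raise ValueError(
            "loocv_backward_elimination needs >= 6 samples and >= 3 per class"
        )
    X = _impute_row_median(X.astype(float))
    if X.shape[0] > max_start_proteins:
        p_full = _per_protein_pvalues(X, y).sort_values(kind="stable")
        X = X.loc[sorted(p_full.index[:max_start_proteins])]

    k0 = X.shape[0]
    samples = list(X.columns)
    loo = pd.DataFrame(np.nan, index=samples, columns=range(k0, 0, -1))
    fold_orders: dict[str, list[str]] = {}
    for i, sid in enumerate(samples):
        train_ids = [s for s in samples if s != sid]
        y_tr = y[np.arange(len(samples)) != i]
        if y_tr.all() or not y_tr.any():
            continue  # fold degenerate; left-out value stays missing
        Xtr = X[train_ids]
        order = _elimination_order(Xtr, y_tr, group_score)
        fold_orders[sid] = order
        sets = _sets_from_order(list(Xtr.index), order)
        for size in range(k0, 0, -1):
            kept = list(sets[size])
            model = train_decision_function(Xtr.loc[kept], y_tr)
            loo.loc[sid, size] = float(model.decision_values(X.loc[kept, [sid]])[0])

    label_series = pd.Series(y, index=samples)
    aucs = {}
    for size in loo.columns:
        vals = loo[size]
        ok = vals.notna()
        aucs[size] = roc_auc(vals[ok].to_numpy(), label_series[ok]).auc
    auc_by_size = pd.Series(aucs).sort_index(ascending=False)
    best = auc_by_size.max()
    chosen_size = int(min(s for s, a in auc_by_size.items() if a == best))

    full_order = _elimination_order(X, y, group_score)
    path = _sets_from_order(list(X.index), full_order)
    chosen_panel = sorted(path[chosen_size])
    return SignatureResult(
        elimination_path=path,
        loo_decision_values=loo,
        auc_by_size=auc_by_size,
        chosen_size=chosen_size,
        chosen_panel=chosen_panel,
        fold_orders=fold_orders,
        labels=label_series,
    )


def evaluate_panel(
    panel: list[str],
    train_X: pd.DataFrame,
    train_labels,
    test_X: pd.DataFrame,
    test_labels,
) -> RocCurve:
    """Transfer evaluation of a fixed panel on an independent cohort.

    Trains the linear SVM on the full training cohort restricted to the
    panel and computes the ROC on the test cohort's decision values.
    """
    if not panel:
        raise ValueError("empty panel")
    for name, mat in (("training", train_X), ("test", test_X)):
        missing = [p for p in panel if p not in mat.index]
        if missing:
            raise KeyError(f"panel protein(s) missing from the {name} matrix: {missing}")
    Xtr = _impute_row_median(train_X.loc[panel].astype(float))
    Xte = _impute_row_median(test_X.loc[panel].astype(float))
    model = train_decision_function(Xtr, train_labels)
    d = model.decision_values(Xte)
    y_te = _as_bool_labels(test_labels, Xte.columns)
    return roc_auc(d, y_te)
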