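"""Differential-abundance testing with empirical-Bayes variance moderation.

Per protein, a two-sample comparison of normalized log2 ratios is performed
with a moderated t-statistic: the per-protein pooled variance s² is shrunk
toward a prior variance s0² estimated across all proteins,

    s̃² = (d0·s0² + df·s²) / (d0 + df),
    t̃  = ΔM / (s̃·sqrt(1/nA + 1/nB)),      p from t with d0 + df d.f.

The prior (d0, s0²) is fitted by matching the first two moments of log s² to
the scaled-F sampling distribution implied by the hierarchical model
(inverse-chi-square prior on the true variances).  Multiplicity is controlled
with the Benjamini–Hochberg step-up adjustment (Bonferroni available as a
config switch).

For the secretome contrast, the cross-cell-line direction-consistency filter
additionally requires that at least ``min_consistent`` case samples deviate
from the control-group mean in the direction of the overall difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .preprocess import ProteinMatrix

__all__ = [
    "EBayesHyperparams",
    "fit_ebayes",
    "moderated_t_test",
    "bh_adjust",
    "consistency_filter",
]

TABLE_COLUMNS = [
    "protein",
    "delta_M",
    "s2",
    "t_mod",
    "df_total",
    "p_raw",
    "p_adj",
    "direction",
    "consistency_count",
    "significant",
    "n_a",
    "n_b",
]


@dataclass(frozen=True)
class EBayesHyperparams:
    """Prior degrees of freedom and prior variance of the variance model.

    ``d0 = 0`` disables moderation (ordinary t); ``d0 = inf`` pools fully.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")
        if self.d0 < 0:
            raise ValueError(f"d0 must be >= 0 (may be inf), got {self.d0}")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_ebayes(s2, df) -> EBayesHyperparams:
    """Estimate (d0, s0²) from per-protein variances by moment matching.

    ``df`` may be a scalar or a per-protein vector of residual degrees of
    freedom.  When the dispersion of log s² does not exceed its sampling
    expectation, d0 = inf is returned with s0² = mean(s²).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError(
            "fit_ebayes needs at least 2 proteins with df >= 1; "
            "use an ordinary two-sample t-test instead"
        )
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; nothing to moderate")
    if np.any(s2 == 0):
        warnings.warn(
            "zero residual variances excluded from the prior fit", stacklevel=2
        )
        keep = s2 > 0
        s2, df = s2[keep], df[keep]

    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return EBayesHyperparams(d0=d0, s0_sq=s0_sq)


def bh_adjust(p, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved).

    ``method="bonferroni"`` switches to the Bonferroni bound.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method=key)[1]
    return out


def _resolve_samples(matrix: ProteinMatrix, group, cohort: str | None) -> list[str]:
    if isinstance(group, str):
        ids = matrix.sample_ids(group=group, cohort=cohort)
    else:
        ids = list(group)
    if not ids:
        raise ValueError(f"no samples for group {group!r} (cohort {cohort!r})")
    return ids


def moderated_t_test(
    matrix: ProteinMatrix,
    group_a,
    group_b,
    cohort: str | None = None,
    hyper: EBayesHyperparams | None = None,
    alpha: float = 0.05,
    adjust_method: str = "bh",
    missing_fraction_max: float = 0.3,
) -> pd.DataFrame:
    """Moderated two-sample test of group A vs group B, per protein.

    ``group_a``/``group_b`` are group labels (resolved against the matrix's
    sample metadata, optionally within one cohort) or explicit sample-id
    lists.  ΔM is mean(A) − mean(B), so ``direction == "up"`` means higher in
    group A.  Proteins missing in more than ``missing_fraction_max`` of
    either group's samples are dropped (logged via warning); remaining
    missing entries are excluded pairwise.
    """
    ids_a = _resolve_samples(matrix, group_a, cohort)
    ids_b = _resolve_samples(matrix, group_b, cohort)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(ids_a)} and {len(ids_b)})"
        )
    Xa = matrix.M[ids_a].to_numpy(dtype=float)
    Xb = matrix.M[ids_b].to_numpy(dtype=float)

    frac_a = np.mean(np.isnan(Xa), axis=1)
    frac_b = np.mean(np.isnan(Xb), axis=1)
    na = np.sum(~np.isnan(Xa), axis=1)
    nb = np.sum(~np.isnan(Xb), axis=1)
    keep = (frac_a <= missing_fraction_max) & (frac_b <= missing_fraction_max)
    keep &= (na >= 2) & (nb >= 2)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} protein(s) dropped from testing "
            f"(missing in > {missing_fraction_max:.0%} of a group)",
            stacklevel=2,
        )
    index = matrix.M.index[keep]
    Xa, Xb, na, nb = Xa[keep], Xb[keep], na[keep], nb[keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(Xa, axis=1)
        mb = np.nanmean(Xb, axis=1)
        ssa = np.nansum((Xa - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((Xb - mb[:, None]) ** 2, axis=1)
    df_resid = na + nb - 2.0
    s2 = (ssa + ssb) / df_resid
    delta = ma - mb

    if hyper is None:
        hyper = fit_ebayes(s2, df_resid)
    d0, s0 = hyper.d0, hyper.s0_sq
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, 0.0)
        t_mod = np.where((se == 0) & (delta == 0), 0.0, t_mod)
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(p_raw, method=adjust_method)

    table = pd.DataFrame(
        {
            "protein": matrix.proteins.reindex(index).to_numpy(),
            "delta_M": delta,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(delta > 0, "up", np.where(delta < 0, "down", "")),
            "consistency_count": np.nan,
            "significant": p_adj <= alpha,
            "n_a": na,
            "n_b": nb,
        },
        index=index,
    )
    table.attrs["hyper"] = hyper
    table.attrs["alpha"] = alpha
    table.attrs["group_a"] = group_a if isinstance(group_a, str) else "custom"
    table.attrs["group_b"] = group_b if isinstance(group_b, str) else "custom"
    return table


def consistency_filter(
    matrix: ProteinMatrix,
    table: pd.DataFrame,
    case_group,
    control_group,
    cohort: str | None = None,
    min_consistent: int = 14,
) -> pd.DataFrame:
    """Cross-case direction-consistency filter on a differential table.

    ``consistency_count`` is the number of case samples whose per-sample M,
    relative to the control-group mean profile, has the sign of ΔM; a
    protein stays significant only if that count reaches ``min_consistent``.
    Proteins with ΔM exactly 0 have undefined consistency and are rejected.
    """
    ids_case = _resolve_samples(matrix, case_group, cohort)
    ids_ctrl = _resolve_samples(matrix, control_group, cohort)
    if min_consistent > len(ids_case):
        raise ValueError(
            f"min_consistent ({min_consistent}) exceeds the number of case "
            f"samples ({len(ids_case)})"
        )
    Xc = matrix.M.loc[table.index, ids_case].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ctrl_mean = np.nanmean(
            matrix.M.loc[table.index, ids_ctrl].to_numpy(dtype=float), axis=1
        )
    sign = np.sign(table["delta_M"].to_numpy())
    dev = Xc - ctrl_mean[:, None]
    count = np.nansum(np.sign(dev) == sign[:, None], axis=1).astype(float)
    count[sign == 0] = 0.0
    if (sign == 0).any():
        warnings.warn(
            f"{int((sign == 0).sum())} protein(s) with delta_M == 0: "
            "consistency undefined, rejected",
            stacklevel=2,
        )
    out = table.copy()
    out["consistency_count"] = count
    out["significant"] = out["significant"] & (count >= min_consistent) & (sign != 0)
    out.attrs = dict(table.attrs)
    out.attrs["min_consistent"] = min_consistent
    return out
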