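"""From spot tables to a normalized protein matrix.

Stages, in order, per array:

1. **Spot quality**: SNR = (foreground median − background median) /
   background SD, per channel.  Spots flagged by the scanner or failing
   ``SNR >= snr_threshold`` in either channel are excluded from ratios
   (they stay in the audit trail).
2. **Background correction**: the normexp convolution model — observed
   foreground-minus-background is Normal(mu, sigma²) background residue plus
   Exponential(alpha) true signal — fitted per array and channel by maximum
   likelihood; each spot is replaced by E[signal | observed] plus a constant
   offset, which keeps all intensities positive and damps the variance of
   low-intensity log-ratios.
3. **Normalization**: robust loess of M = log2(sample/reference) on
   A = mean log2 intensity, fitted within the array; the fitted trend
   (dye bias) is subtracted.
4. **Replicate aggregation**: median of the passing replicate spots per
   antibody; antibodies with no passing spot become missing values.

The result is a :class:`ProteinMatrix` (antibody × sample M and A values with
sample metadata) plus a :class:`QcReport` with pass fractions, SNR summaries
and intra/inter-array coefficients of variation.  Sample-level QC clustering
(1 − Pearson distance, average linkage) is provided by :func:`qc_cluster`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .array_io import ArrayScan

__all__ = [
    "ProteinMatrix",
    "QcReport",
    "ClusterResult",
    "compute_snr",
    "snr_pass_mask",
    "filter_spots",
    "fit_normexp",
    "normexp_conditional_expectation",
    "normexp_correct",
    "loess_normalize",
    "aggregate_replicates",
    "build_protein_matrix",
    "qc_cluster",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ProteinMatrix:
    """Antibody × sample matrix of normalized log2 ratios.

    ``M`` holds log2(sample/reference), ``A`` the spot-average log2
    intensity, both aggregated over passing replicate spots (NaN where no
    replicate passed).  Rows are antibodies; ``proteins`` maps each antibody
    to its target protein (aggregation is per antibody, reporting per
    protein).  ``spot_pass`` keeps the spot-granular pass mask per sample for
    audit.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns group, cohort, panel_id
    proteins: pd.Series  # antibody_id -> protein name
    spot_pass: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M.index.duplicated().any() or self.M.columns.duplicated().any():
            raise ValueError("ProteinMatrix row/column labels must be unique")
        if not self.M.index.equals(self.A.index) or not self.M.columns.equals(self.A.columns):
            raise ValueError("M and A must share labels")

    def sample_ids(self, group: str | None = None, cohort: str | None = None) -> list[str]:
        s = self.samples
        keep = pd.Series(True, index=s.index)
        if group is not None:
            keep &= s["group"] == group
        if cohort is not None:
            keep &= s["cohort"] == cohort
        return list(s.index[keep])

    @classmethod
    def from_m(
        cls,
        M: pd.DataFrame,
        groups,
        cohorts=None,
        proteins: pd.Series | None = None,
    ) -> "ProteinMatrix":
        """Wrap a plain proteins × samples M table (A set to zero)."""
        samples = pd.DataFrame(
            {
                "group": list(groups),
                "cohort": list(cohorts) if cohorts is not None else "TRAINING",
                "panel_id": "P1",
            },
            index=M.columns,
        )
        samples.index.name = "sample_id"
        if proteins is None:
            proteins = pd.Series(M.index, index=M.index)
        return cls(
            M=M, A=pd.DataFrame(0.0, index=M.index, columns=M.columns),
            samples=samples, proteins=proteins,
        )

    def subset(self, sample_ids: list[str]) -> "ProteinMatrix":
        return ProteinMatrix(
            M=self.M[sample_ids],
            A=self.A[sample_ids],
            samples=self.samples.loc[sample_ids],
            proteins=self.proteins,
            spot_pass={k: v for k, v in self.spot_pass.items() if k in set(sample_ids)},
        )


@dataclass
class QcReport:
    """Per-array pass fractions and SNR summaries; replicate CV tables."""

    array_stats: pd.DataFrame  # per sample: pass fractions, SNR mean/sd, counts
    intra_cv: pd.DataFrame  # antibody × sample CV of replicate spots (raw scale)
    inter_cv: pd.Series  # antibody-level CV across arrays (raw scale)

    def mean_intra_cv(self) -> pd.Series:
        """Per-antibody intra-array CV averaged over arrays."""
        return self.intra_cv.mean(axis=1, skipna=True)


@dataclass
class ClusterResult:
    """Average-linkage dendrogram of samples on 1 − Pearson distances."""

    linkage: np.ndarray  # scipy linkage matrix (merge list)
    sample_ids: list[str]
    distances: pd.DataFrame

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two sample sets separated by the final merge."""
        from scipy.cluster.hierarchy import fcluster

        lab = fcluster(self.linkage, t=2, criterion="maxclust")
        ids = np.asarray(self.sample_ids)
        return set(ids[lab == 1]), set(ids[lab == 2])


# ---------------------------------------------------------------------------
# SNR & filtering


def compute_snr(fg, bg, bg_sd):
    """Signal-to-noise ratio (fg − bg) / bg_sd, element-wise.

    Below-background spots give negative SNR and hence fail any positive
    threshold.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    bg_sd = np.asarray(bg_sd, dtype=float)
    if np.any(bg_sd <= 0):
        raise ValueError("degenerate background: bg_sd must be > 0 for every spot")
    return (fg - bg) / bg_sd


def snr_pass_mask(
    scan: ArrayScan, snr_threshold: float = 2.0, channels: str = "both"
) -> pd.DataFrame:
    """Boolean per-spot mask with columns sample/ref/unflagged/passing.

    ``channels`` selects which channel(s) gate the ``passing`` column:
    ``"both"``, ``"sample"`` or ``"ref"``.  Gating on the reference channel
    only treats a weak sample-channel signal as genuine biology (a low
    ratio) rather than a bad spot — the common reference is the same pool on
    every array, so its SNR indicates spot integrity.
    """
    s = scan.spots
    snr_s = compute_snr(s["f_sample"], s["b_sample"], s["b_sample_sd"])
    snr_r = compute_snr(s["f_ref"], s["b_ref"], s["b_ref_sd"])
    unflagged = (s["flag"] == 0).to_numpy()
    mask = pd.DataFrame(
        {
            "sample": snr_s >= snr_threshold,
            "ref": snr_r >= snr_threshold,
            "unflagged": unflagged,
        }
    )
    gate = {
        "both": mask["sample"] & mask["ref"],
        "sample": mask["sample"],
        "ref": mask["ref"],
    }
    if channels not in gate:
        raise ValueError(f"channels must be one of {sorted(gate)}, got {channels!r}")
    mask["passing"] = gate[channels] & mask["unflagged"]
    return mask


def filter_spots(
    scan: ArrayScan, snr_threshold: float = 2.0, channels: str = "both"
) -> ArrayScan:
    """Drop flagged spots and spots failing the SNR gate.

    A scanner flag always wins: a flagged spot is removed regardless of its
    SNR.  An empty result is allowed but warned about.
    """
    mask = snr_pass_mask(scan, snr_threshold, channels)["passing"].to_numpy()
    if not mask.any():
        warnings.warn(f"{scan.sample_id}: no spot passed the SNR filter", stacklevel=2)
    out = scan.copy()
    out.spots = scan.spots[mask].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# normexp background correction


def _normexp_nll(params: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = params
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    ll = (
        -log_alpha
        + (mu - x) / alpha
        + sigma**2 / (2.0 * alpha**2)
        + log_ndtr((x - mu) / sigma - sigma / alpha)
    )
    return -float(np.sum(ll))


def _moments_init(x: np.ndarray) -> tuple[float, float, float]:
    m1 = float(np.mean(x))
    v = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    alpha = (m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else max(np.sqrt(v) / 2.0, 1e-6)
    sigma2 = max(v - alpha**2, 0.05 * v, 1e-12)
    mu = m1 - alpha
    return mu, float(np.sqrt(sigma2)), float(alpha)


def fit_normexp(x: np.ndarray, max_fit_spots: int = 2000) -> tuple[float, float, float]:
    """Fit the normal+exponential convolution to background-subtracted x.

    Returns (mu, sigma, alpha): Normal(mu, sigma²) background residue plus
    Exponential(mean alpha) signal.  Maximum likelihood with
    method-of-moments initialization; falls back to the moments estimates on
    non-convergence (warned).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError(
            f"normexp needs at least 10 spots to estimate parameters, got {x.size}"
        )
    if np.var(x) == 0:
        raise FloatingPointError("degenerate fit: zero-variance input")
    mu0, sigma0, alpha0 = _moments_init(x)
    fit_x = x
    if x.size > max_fit_spots:  # deterministic thinning for speed
        order = np.sort(x)
        idx = np.linspace(0, x.size - 1, max_fit_spots).astype(int)
        fit_x = order[idx]
    res = minimize(
        _normexp_nll,
        x0=np.array([mu0, np.log(sigma0), np.log(alpha0)]),
        args=(fit_x,),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-7},
    )
    if res.success and np.all(np.isfinite(res.x)):
        mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    else:
        warnings.warn(
            "normexp MLE did not converge; using method-of-moments estimates",
            stacklevel=2,
        )
        mu, sigma, alpha = mu0, sigma0, alpha0
    return float(mu), sigma, alpha


def normexp_conditional_expectation(
    x: np.ndarray, mu: float, sigma: float, alpha: float
) -> np.ndarray:
    """E[signal | observed = x] under the normal+exponential model.

    Closed form: with mu_sx = x − mu − sigma²/alpha and z = mu_sx/sigma,
    E[S|x] = mu_sx + sigma·phi(z)/Phi(z); always positive and monotone
    nondecreasing in x.
    """
    x = np.asarray(x, dtype=float)
    mu_sx = x - mu - sigma**2 / alpha
    z = mu_sx / sigma
    # phi(z)/Phi(z) via logs; stable far into the left tail
    ratio = np.exp(-0.5 * z**2 - _LOG_SQRT_2PI - log_ndtr(z))
    return np.maximum(mu_sx + sigma * ratio, 1e-12)


def normexp_correct(fg, bg, offset: float = 50.0) -> np.ndarray:
    """Background-correct one channel of one array.

    Fits normexp to fg − bg, returns E[signal | observed] + offset.  The
    offset is added after correction, so two runs differing only in offset
    differ by exactly that constant.  A degenerate (zero-variance) input
    falls back to max(x − mean(x), eps) + offset.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    x = fg - bg
    if x.size < 10:
        raise ValueError(f"normexp needs at least 10 spots, got {x.size}")
    if np.var(x) == 0:
        warnings.warn(
            "normexp: zero-variance input, degenerate fit rejected; "
            "falling back to background subtraction",
            stacklevel=2,
        )
        return np.maximum(x - np.mean(x), 1e-6) + offset
    mu, sigma, alpha = fit_normexp(x)
    return normexp_conditional_expectation(x, mu, sigma, alpha) + offset


# ---------------------------------------------------------------------------
# loess normalization


def loess_normalize(
    M, A, span: float = 0.3, iterations: int = 4
) -> np.ndarray:
    """Remove the intensity-dependent trend of M on A within one array.

    Robust locally weighted regression (tricube weights, bisquare
    reweighting) of M on A; returns M − fit, so the per-A-bin median of the
    result is approximately zero for any smooth bias.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape or M.ndim != 1:
        raise ValueError("M and A must be 1-D arrays of equal length")
    if M.size < 20:
        raise ValueError(f"loess needs at least 20 spots, got {M.size}")
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(A))):
        raise ValueError("loess inputs must be finite")
    if span <= 0 or span * M.size < 4:
        raise ValueError(
            f"span {span} too small for {M.size} points (needs span*n >= 4)"
        )
    delta = 0.01 * (A.max() - A.min())
    fit = _sm_lowess(
        M, A, frac=span, it=iterations, delta=delta, return_sorted=False
    )
    return M - fit


# ---------------------------------------------------------------------------
# replicate aggregation


def aggregate_replicates(
    spots: pd.DataFrame,
    values: np.ndarray,
    passing: np.ndarray,
    min_replicates: int = 1,
) -> pd.Series:
    """Median of `values` over passing replicate spots, per antibody.

    Antibodies with fewer than ``min_replicates`` passing spots get NaN.
    """
    s = pd.Series(np.where(passing, values, np.nan), index=spots["antibody_id"].to_numpy())
    grouped = s.groupby(level=0, sort=False)
    med = grouped.median()
    n = grouped.count()
    med[n < min_replicates] = np.nan
    return med


# ---------------------------------------------------------------------------
# the pipeline


def _process_scan(
    scan: ArrayScan,
    snr_threshold: float,
    normexp_offset: float,
    loess_span: float,
    loess_iterations: int,
    min_replicates: int,
    snr_channels: str,
) -> tuple[pd.Series, pd.Series, dict, np.ndarray, pd.Series]:
    s = scan.spots
    mask = snr_pass_mask(scan, snr_threshold, snr_channels)
    passing = mask["passing"].to_numpy()
    unflagged = mask["unflagged"].to_numpy()
    quantified = passing & mask["sample"].to_numpy()  # above background in both

    cs = normexp_correct(s["f_sample"].to_numpy(), s["b_sample"].to_numpy(), normexp_offset)
    cr = normexp_correct(s["f_ref"].to_numpy(), s["b_ref"].to_numpy(), normexp_offset)
    M_raw = np.log2(cs / cr)
    A = 0.5 * np.log2(cs * cr)

    M = np.full_like(M_raw, np.nan)
    if passing.sum() >= 20:
        M[passing] = loess_normalize(
            M_raw[passing], A[passing], span=loess_span, iterations=loess_iterations
        )
    else:
        M[passing] = M_raw[passing] - np.median(M_raw[passing]) if passing.any() else np.nan

    m_agg = aggregate_replicates(s, M, passing, min_replicates)
    a_agg = aggregate_replicates(s, A, passing, min_replicates)

    snr_s = compute_snr(s["f_sample"], s["b_sample"], s["b_sample_sd"])
    snr_r = compute_snr(s["f_ref"], s["b_ref"], s["b_ref_sd"])
    above = np.concatenate([snr_s[snr_s > 0], snr_r[snr_r > 0]])
    stats = {
        "frac_pass_sample": float(np.mean(mask["sample"][unflagged])),
        "frac_pass_ref": float(np.mean(mask["ref"][unflagged])),
        "mean_snr": float(np.mean(above)) if above.size else np.nan,
        "sd_snr": float(np.std(above, ddof=1)) if above.size > 1 else np.nan,
        "n_spots": int(len(s)),
        "n_flagged": int((~unflagged).sum()),
        "n_pass": int(passing.sum()),
    }

    # intra-array CV of replicate spots on the raw background-subtracted
    # scale; only spots quantifiable in the sample channel enter the CV
    net = np.where(quantified, s["f_sample"].to_numpy() - s["b_sample"].to_numpy(), np.nan)
    net = np.where(net > 0, net, np.nan)
    g = pd.Series(net, index=s["antibody_id"].to_numpy()).groupby(level=0, sort=False)
    cv = g.std(ddof=1) / g.mean()
    cv[g.count() < 2] = np.nan
    return m_agg, a_agg, stats, passing, cv


def build_protein_matrix(
    scans: list[ArrayScan],
    panel: pd.DataFrame,
    snr_threshold: float = 2.0,
    normexp_offset: float = 50.0,
    loess_span: float = 0.3,
    loess_iterations: int = 4,
    min_replicates: int = 1,
    snr_channels: str = "ref",
) -> tuple[ProteinMatrix, QcReport]:
    """Run the full per-array pipeline and assemble the M/A matrices.

    The default spot-inclusion gate (``snr_channels="ref"``) requires the
    common-reference channel to clear the SNR threshold; a sample channel at
    background then yields a strongly negative (but quantified) log-ratio
    instead of a missing value, which keeps down-regulated proteins in the
    analysis.  Use ``"both"`` to require both channels.
    """
    if not scans:
        raise ValueError("no scans given")
    antibody_order = [a for a in panel["antibody_id"]]
    m_cols, a_cols, stat_rows, cv_cols = {}, {}, {}, {}
    spot_pass: dict[str, np.ndarray] = {}
    meta_rows = {}
    net_cols = {}
    for scan in scans:
        m_agg, a_agg, stats, passing, cv = _process_scan(
            scan, snr_threshold, normexp_offset, loess_span, loess_iterations,
            min_replicates, snr_channels,
        )
        sid = scan.sample_id
        m_cols[sid] = m_agg
        a_cols[sid] = a_agg
        stat_rows[sid] = stats
        cv_cols[sid] = cv
        spot_pass[sid] = passing
        meta_rows[sid] = {
            "group": scan.group,
            "cohort": scan.cohort,
            "panel_id": scan.panel_id,
        }
        s = scan.spots
        raw_net = s["f_sample"].to_numpy() - s["b_sample"].to_numpy()
        net = pd.Series(
            np.where(passing & (raw_net > 0), raw_net, np.nan),
            index=s["antibody_id"].to_numpy(),
        )
        net_cols[sid] = net.groupby(level=0, sort=False).median()

    seen = pd.unique(
        np.concatenate([np.asarray(c.index, dtype=object) for c in m_cols.values()])
    )
    index = [a for a in antibody_order if a in set(seen)]
    M = pd.DataFrame(m_cols).reindex(index)
    A = pd.DataFrame(a_cols).reindex(index)
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample_id"
    proteins = panel.set_index("antibody_id")["protein"].reindex(index)

    net = pd.DataFrame(net_cols).reindex(index)
    inter_cv = net.std(axis=1, ddof=1) / net.mean(axis=1)
    qc = QcReport(
        array_stats=pd.DataFrame.from_dict(stat_rows, orient="index"),
        intra_cv=pd.DataFrame(cv_cols).reindex(index),
        inter_cv=inter_cv,
    )
    matrix = ProteinMatrix(M=M, A=A, samples=samples, proteins=proteins, spot_pass=spot_pass)
    return matrix, qc


# ---------------------------------------------------------------------------
# QC clustering


def qc_cluster(matrix: ProteinMatrix) -> ClusterResult:
    """Average-linkage clustering of samples on 1 − Pearson correlation.

    Correlations are pairwise-complete over shared non-missing proteins;
    zero-variance profiles (or pairs with no overlap) get the maximum
    distance 2.0, with a warning.
    """
    if matrix.M.shape[1] < 3:
        raise ValueError("qc_cluster needs at least 3 samples")
    corr = matrix.M.corr(method="pearson", min_periods=3)
    dist = 1.0 - corr
    if dist.isna().to_numpy().any():
        warnings.warn(
            "zero-variance or non-overlapping sample profiles; "
            "setting their distance to the maximum (2.0)",
            stacklevel=2,
        )
        dist = dist.fillna(2.0)
    d = dist.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = _scipy_linkage(squareform(d, checks=False), method="average")
    return ClusterResult(linkage=Z, sample_ids=list(matrix.M.columns), distances=dist)
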