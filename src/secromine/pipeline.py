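"""End-to-end orchestration: scans → matrices → markers → signature AUCs.

This is the programmatic counterpart of the command-line ``run`` command; it
also powers the simulation studies in the test-suite and the reproduction
script.  All stage parameters are collected in :class:`PipelineSettings`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import ArrayScan
from .diffabund import consistency_filter, moderated_t_test
from .markers import MarkerSet, intersect_markers
from .preprocess import ProteinMatrix, QcReport, build_protein_matrix
from .signature import RocCurve, derive_panel, evaluate_panel

__all__ = ["PipelineSettings", "PipelineResult", "protein_level_matrix", "analyze_experiment"]

SERUM_GROUPS = ("PDAC", "CP", "HEALTHY")
SECRETOME_GROUPS = ("TUMOR_SECRETOME", "CONTROL_SECRETOME")


@dataclass
class PipelineSettings:
    snr_threshold: float = 2.0
    normexp_offset: float = 50.0
    loess_span: float = 0.3
    loess_iterations: int = 4
    alpha: float = 0.05
    adjust_method: str = "bh"
    min_consistent: int = 14
    missing_fraction_max: float = 0.3
    group_score: str = "fisher"
    max_start_proteins: int = 200
    panel_size: int | None = None  # None: size of the shared marker set
    snr_channels: str = "ref"
    # which CP contrast(s) veto a shared marker; a PDAC-specific marker is
    # expected to differ between PDAC and CP sera, so only CP-vs-healthy
    # vetoes by default ("both" adds the PDAC-vs-CP contrast)
    cp_exclusion: str = "cp-vs-healthy"


@dataclass
class PipelineResult:
    secretome_matrix: ProteinMatrix | None
    serum_matrix: ProteinMatrix
    secretome_qc: QcReport | None
    serum_qc: QcReport
    secretome_table: pd.DataFrame | None
    serum_pdac_table: pd.DataFrame
    cp_tables: dict[str, pd.DataFrame]
    marker_set: MarkerSet | None
    shared_panel: list[str] = field(default_factory=list)
    serum_only_panel: list[str] = field(default_factory=list)
    shared_roc: RocCurve | None = None
    serum_only_roc: RocCurve | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        out = dict(self.counts)
        if self.shared_roc is not None:
            out["shared_panel_test_auc"] = self.shared_roc.auc
        if self.serum_only_roc is not None:
            out["serum_only_panel_test_auc"] = self.serum_only_roc.auc
        return out


def protein_level_matrix(matrix: ProteinMatrix) -> pd.DataFrame:
    """M matrix re-indexed by protein (median over a protein's antibodies)."""
    M = matrix.M.copy()
    M.index = matrix.proteins.reindex(M.index).to_numpy()
    if M.index.duplicated().any():
        M = M.groupby(level=0, sort=False).median()
    return M


def analyze_experiment(
    scans: list[ArrayScan],
    panel: pd.DataFrame,
    settings: PipelineSettings | None = None,
    with_secretome: bool = True,
    with_signature: bool = True,
) -> PipelineResult:
    """Run the complete discovery workflow on a collection of scans.

    Stages: per-study preprocessing; secretome contrast (tumor vs control
    secretome, with the cross-cell-line consistency filter); serum contrasts
    on the training cohort (PDAC vs healthy, CP vs healthy, PDAC vs CP);
    marker intersection; and transfer evaluation of the shared-marker panel
    and the best equal-sized serum-only panel on the test cohort.
    """
    st = settings or PipelineSettings()
    secretome_scans = [s for s in scans if s.group in SECRETOME_GROUPS]
    serum_scans = [s for s in scans if s.group in SERUM_GROUPS]
    if not serum_scans:
        raise ValueError("no serum arrays among the scans")

    kw = dict(
        snr_threshold=st.snr_threshold,
        normexp_offset=st.normexp_offset,
        loess_span=st.loess_span,
        loess_iterations=st.loess_iterations,
        snr_channels=st.snr_channels,
    )
    serum_matrix, serum_qc = build_protein_matrix(serum_scans, panel, **kw)
    counts: dict[str, int] = {
        "n_serum_arrays": len(serum_scans),
        "n_serum_antibodies": int(serum_matrix.M.shape[0]),
    }

    secretome_matrix = secretome_qc = secretome_table = None
    if with_secretome and secretome_scans:
        secretome_matrix, secretome_qc = build_protein_matrix(secretome_scans, panel, **kw)
        counts["n_secretome_arrays"] = len(secretome_scans)
        table = moderated_t_test(
            secretome_matrix,
            "TUMOR_SECRETOME",
            "CONTROL_SECRETOME",
            alpha=st.alpha,
            adjust_method=st.adjust_method,
            missing_fraction_max=st.missing_fraction_max,
        )
        secretome_table = consistency_filter(
            secretome_matrix,
            table,
            "TUMOR_SECRETOME",
            "CONTROL_SECRETOME",
            min_consistent=st.min_consistent,
        )
        counts["n_secretome_significant"] = int(secretome_table["significant"].sum())

    serum_pdac = moderated_t_test(
        serum_matrix,
        "PDAC",
        "HEALTHY",
        cohort="TRAINING",
        alpha=st.alpha,
        adjust_method=st.adjust_method,
        missing_fraction_max=st.missing_fraction_max,
    )
    counts["n_serum_significant"] = int(serum_pdac["significant"].sum())
    cp_tables = {
        "cp_vs_healthy": moderated_t_test(
            serum_matrix, "CP", "HEALTHY", cohort="TRAINING",
            alpha=st.alpha, adjust_method=st.adjust_method,
            missing_fraction_max=st.missing_fraction_max,
        ),
        "pdac_vs_cp": moderated_t_test(
            serum_matrix, "PDAC", "CP", cohort="TRAINING",
            alpha=st.alpha, adjust_method=st.adjust_method,
            missing_fraction_max=st.missing_fraction_max,
        ),
    }

    marker_set = None
    if secretome_table is not None:
        cp_veto = (
            list(cp_tables.values())
            if st.cp_exclusion == "both"
            else [cp_tables["cp_vs_healthy"]]
        )
        marker_set = intersect_markers(secretome_table, serum_pdac, cp_veto)
        counts["n_shared_markers"] = len(marker_set.shared)
        counts["n_serum_only_markers"] = len(marker_set.proteins("serum_only"))
        counts["n_secretome_only_markers"] = len(marker_set.proteins("secretome_only"))

    result = PipelineResult(
        secretome_matrix=secretome_matrix,
        serum_matrix=serum_matrix,
        secretome_qc=secretome_qc,
        serum_qc=serum_qc,
        secretome_table=secretome_table,
        serum_pdac_table=serum_pdac,
        cp_tables=cp_tables,
        marker_set=marker_set,
        counts=counts,
    )
    if not with_signature or marker_set is None:
        return result

    shared = marker_set.shared
    if not shared:
        return result
    size = st.panel_size or len(shared)

    Mp = protein_level_matrix(serum_matrix)
    meta = serum_matrix.samples
    train_ids = list(meta.index[(meta["cohort"] == "TRAINING") & meta["group"].isin(["PDAC", "HEALTHY"])])
    test_ids = list(meta.index[(meta["cohort"] == "TEST") & meta["group"].isin(["PDAC", "HEALTHY"])])
    y_train = meta.loc[train_ids, "group"] == "PDAC"
    y_test = meta.loc[test_ids, "group"] == "PDAC"
    Xtr, Xte = Mp[train_ids], Mp[test_ids]

    shared_avail = [p for p in shared if p in Xtr.index and p in Xte.index]
    result.shared_panel = shared_avail
    if shared_avail:
        result.shared_roc = evaluate_panel(shared_avail, Xtr, y_train, Xte, y_test)

    serum_only = [
        p for p in marker_set.proteins("serum_only") if p in Xtr.index and p in Xte.index
    ]
    if len(serum_only) >= size:
        # pre-filter to keep the wrapper search desk-scale, then eliminate
        # down to the same size as the shared panel on the training cohort
        by_p = serum_pdac.set_index("protein")["p_raw"]
        ranked = sorted(serum_only, key=lambda p: (float(by_p.get(p, 1.0)), p))
        start = sorted(ranked[: st.max_start_proteins])
        from .signature import _impute_row_median

        panel_so = derive_panel(
            _impute_row_median(Xtr.loc[start]), y_train, size, group_score=st.group_score
        )
        result.serum_only_panel = sorted(panel_so)
        result.serum_only_roc = evaluate_panel(panel_so, Xtr, y_train, Xte, y_test)
    return result
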