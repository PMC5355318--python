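"""Synthetic two-color antibody-microarray experiments with planted truth.

The generator emulates a secretome/serum biomarker study: conditioned-medium
profiles of tumor cell lines against a fibroblast control, and serum profiles
of PDAC patients, chronic-pancreatitis (CP) patients and healthy donors in a
training and an independent test cohort.  Each "hybridization" yields a
two-channel spot table (sample dye vs. pooled common reference) in the same
dialect the real scanners produce, so the entire downstream pipeline can be
exercised and scored against known planted markers.

Generative model, per study
---------------------------
* Per-protein baseline abundance: log2 a_p ~ Normal(log2(signal_scale),
  abundance_log2_sd).  Marker proteins are planted on above-median baselines
  (markers that are undetectable on the platform could never have been
  reported by an antibody array, so this reflects the ascertainment of the
  design being emulated).
* Per-sample true signal: log2 S_pi = log2 a_p + Δ_p·1[group affected]
  + Normal(0, biological_sd); Δ_p is the planted log2 effect with a random
  direction.
* Common reference: geometric mean of the study's sample abundances, scaled
  by 2**reference_scale_log2 (the pool is applied at a higher effective
  concentration, which is why reference-channel spots pass the
  signal-to-noise gate more often than sample-channel spots).
* Spot foreground = background + signal · dye-bias(A) · lognormal replicate
  noise + small additive measurement noise; the dye bias is a smooth
  quadratic-in-A multiplicative distortion of the sample channel only, so
  loess normalization is genuinely exercised.
* Recorded background median and background SD mimic pixel statistics: the
  SD is large (local pixel spread, the denominator of SNR) while the median
  itself fluctuates only slightly spot to spot.

Marker classes: ``shared`` (differential in secretome and PDAC serum, same
direction, larger secretome effect), ``secretome_only``, ``serum_only``,
``cp_confounded`` (differential in both PDAC and CP sera — the confounder
class the marker intersection must reject), and ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .array_io import ArrayScan

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_protein_matrix",
]

MARKER_CLASSES = ("shared", "secretome_only", "serum_only", "cp_confounded", "null")


class SimulationConfig(BaseModel):
    """All knobs of the simulated study; the defaults are the study design."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # panel layout
    n_antibodies: int = Field(default=735, gt=0)
    n_antibodies_extended: int = Field(default=1439, gt=0)
    n_panel1_missing: int = Field(default=5, ge=0)
    n_replicate_spots: int = Field(default=4, gt=0)

    # samples
    secretome_cell_lines: int = Field(default=16, gt=0)
    secretome_control_arrays: int = Field(default=3, ge=3)
    train_pdac: int = Field(default=47, gt=0)
    train_cp: int = Field(default=18, gt=0)
    train_healthy: int = Field(default=27, gt=0)
    test_pdac: int = Field(default=25, gt=0)
    test_cp: int = Field(default=25, gt=0)
    test_healthy: int = Field(default=22, gt=0)

    # planted truth
    n_secretome_markers: int = Field(default=112, ge=0)
    n_serum_markers: int = Field(default=189, ge=0)
    n_shared_markers: int = Field(default=8, ge=0)
    n_cp_confounded: int = Field(default=20, ge=0)
    effect_size_secretome: float = Field(default=2.0, ge=0)
    effect_size_serum: float = Field(default=0.75, ge=0)
    effect_size_shared_serum: float = Field(default=1.8, ge=0)

    # noise / intensity model
    replicate_cv: float = Field(default=0.165)
    biological_sd_secretome: float = Field(default=0.5, ge=0)
    biological_sd_serum: float = Field(default=1.0, ge=0)
    # per-sample disease-severity multiplier of the planted effects
    # (markers co-vary within a patient, which bounds panel performance)
    severity_sd_secretome: float = Field(default=0.25, ge=0)
    severity_sd_serum: float = Field(default=0.5, ge=0)
    dye_bias_amplitude: float = 0.4
    background_mean: float = Field(default=400.0, gt=0)
    background_sd: float = Field(default=50.0, gt=0)
    signal_scale: float = Field(default=260.0, gt=0)
    abundance_log2_sd: float = Field(default=2.0, gt=0)
    reference_scale_log2: float = 1.0
    foreground_noise_sd: float = Field(default=10.0, ge=0)
    flagged_fraction: float = Field(default=0.01, ge=0, lt=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimulationConfig":
        if not (0.0 < self.replicate_cv < 1.0):
            raise ValueError(f"replicate_cv must lie in (0, 1), got {self.replicate_cv}")
        if self.n_shared_markers > min(self.n_secretome_markers, self.n_serum_markers):
            raise ValueError(
                "n_shared_markers exceeds min(n_secretome_markers, n_serum_markers): "
                f"{self.n_shared_markers} > "
                f"{min(self.n_secretome_markers, self.n_serum_markers)}"
            )
        if self.n_panel1_missing >= self.n_antibodies:
            raise ValueError("n_panel1_missing must be smaller than n_antibodies")
        core = self.n_antibodies - self.n_panel1_missing
        if self.n_antibodies_extended < core:
            raise ValueError(
                "n_antibodies_extended smaller than the shared panel core "
                f"({self.n_antibodies_extended} < {core})"
            )
        if self.n_secretome_markers > core:
            raise ValueError(
                f"n_secretome_markers ({self.n_secretome_markers}) exceeds the "
                f"cross-panel antibody core ({core})"
            )
        n_serum_side = (
            self.n_secretome_markers
            + (self.n_serum_markers - self.n_shared_markers)
            + self.n_cp_confounded
        )
        if n_serum_side > self.n_antibodies_extended:
            raise ValueError(
                f"marker counts ({n_serum_side}) exceed the extended panel "
                f"({self.n_antibodies_extended})"
            )
        return self


@dataclass
class GroundTruth:
    """Planted per-protein truth: class, direction, log2 effects per context."""

    table: pd.DataFrame  # index: protein; columns below

    COLUMNS = (
        "antibody_id",
        "marker_class",
        "direction",
        "effect_secretome",
        "effect_serum_pdac",
        "effect_serum_cp",
    )

    def counts(self) -> dict[str, int]:
        c = self.table["marker_class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in MARKER_CLASSES}

    def proteins_of(self, marker_class: str) -> list[str]:
        t = self.table
        return list(t.index[t["marker_class"] == marker_class])


@dataclass
class SimulatedExperiment:
    scans: list[ArrayScan]
    truth: GroundTruth
    panel: pd.DataFrame  # antibody manifest (antibody_id, protein, panels)
    samples: pd.DataFrame  # sample manifest


def simulate_protein_matrix(
    n_proteins: int,
    n_case: int,
    n_control: int,
    n_markers: int = 0,
    effect_log2: float = 0.0,
    sd: float = 0.6,
    seed: int = 0,
    case_group: str = "PDAC",
    control_group: str = "HEALTHY",
):
    """Matrix-level simulation for statistical calibration studies.

    Draws normalized M values directly (Normal noise of SD ``sd`` in log2
    units) with the first ``n_markers`` proteins shifted by ``effect_log2``
    (alternating sign) in the case group, bypassing the array level.
    Returns ``(ProteinMatrix, marker_protein_ids)``.
    """
    from .preprocess import ProteinMatrix

    rng = np.random.default_rng(seed)
    prots = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    cols = [f"CASE{i + 1:03d}" for i in range(n_case)] + [
        f"CTRL{i + 1:03d}" for i in range(n_control)
    ]
    M = sd * rng.standard_normal((n_proteins, n_case + n_control))
    signs = np.where(np.arange(n_markers) % 2 == 0, 1.0, -1.0)
    M[:n_markers, :n_case] += (signs * effect_log2)[:, None]
    frame = pd.DataFrame(M, index=prots, columns=cols)
    groups = [case_group] * n_case + [control_group] * n_control
    return ProteinMatrix.from_m(frame, groups), prots[:n_markers]


def _plant_effects(config: SimulationConfig, rng: np.random.Generator, proteins: list[str],
                   core: list[str], panel2: list[str]) -> pd.DataFrame:
    """Assign marker classes, directions and per-context log2 effects.

    Secretome-side markers (shared and secretome-only) live on the antibody
    core present on both panels; serum-only and CP-confounded markers are
    planted uniformly over the extended serum panel, so — as on the real
    platform pair — part of the serum signature targets proteins the smaller
    secretome array never measured.
    """
    n = len(proteins)
    table = pd.DataFrame(
        {
            "marker_class": np.repeat("null", n),
            "direction": np.repeat("", n),
            "effect_secretome": np.zeros(n),
            "effect_serum_pdac": np.zeros(n),
            "effect_serum_cp": np.zeros(n),
        },
        index=pd.Index(proteins, name="protein"),
    )
    n_shared = config.n_shared_markers
    n_sec_only = config.n_secretome_markers - n_shared
    n_ser_only = config.n_serum_markers - n_shared
    n_cp = config.n_cp_confounded
    picked_core = rng.choice(core, size=n_shared + n_sec_only, replace=False)
    remaining = [p for p in panel2 if p not in set(picked_core)]
    picked_p2 = rng.choice(remaining, size=n_ser_only + n_cp, replace=False)
    picked = np.concatenate([picked_core, picked_p2])
    classes = (
        ["shared"] * n_shared
        + ["secretome_only"] * n_sec_only
        + ["serum_only"] * n_ser_only
        + ["cp_confounded"] * n_cp
    )
    table.loc[picked, "marker_class"] = classes
    sign = rng.choice([-1.0, 1.0], size=len(picked))
    table.loc[picked, "direction"] = np.where(sign > 0, "up", "down")
    u = rng.uniform(0.75, 1.25, size=len(picked))  # per-marker magnitude spread
    for i, (prot, cls) in enumerate(zip(picked, classes)):
        if cls == "shared":
            serum = config.effect_size_shared_serum * u[i]
            # secretome variation is substantially bigger than in serum
            secretome = serum * rng.uniform(1.5, 2.5)
            table.loc[prot, "effect_secretome"] = sign[i] * secretome
            table.loc[prot, "effect_serum_pdac"] = sign[i] * serum
        elif cls == "secretome_only":
            table.loc[prot, "effect_secretome"] = sign[i] * config.effect_size_secretome * u[i]
        elif cls == "serum_only":
            table.loc[prot, "effect_serum_pdac"] = sign[i] * config.effect_size_serum * u[i]
        else:  # cp_confounded: same shift in PDAC and CP sera
            eff = sign[i] * config.effect_size_serum * u[i]
            table.loc[prot, "effect_serum_pdac"] = eff
            table.loc[prot, "effect_serum_cp"] = eff
    # a class-level effect size of zero demotes its markers back to null
    eff_cols = ["effect_secretome", "effect_serum_pdac", "effect_serum_cp"]
    zero = (table[eff_cols] == 0).all(axis=1)
    table.loc[zero, "marker_class"] = "null"
    table.loc[zero, "direction"] = ""
    return table


def _spot_grid(n_proteins: int, n_reps: int) -> pd.DataFrame:
    """Deterministic grid layout: one block per replicate, 40 columns wide."""
    p = np.arange(n_proteins)
    block = np.repeat(np.arange(1, n_reps + 1), n_proteins)
    row = np.tile(p // 40 + 1, n_reps)
    col = np.tile(p % 40 + 1, n_reps)
    return pd.DataFrame({"block": block, "row": row, "column": col})


def _dye_bias_log2(a_true: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth quadratic intensity-dependent bias of the sample channel (log2)."""
    if amplitude == 0:
        return np.zeros_like(a_true)
    mid = np.median(a_true)
    half = max(1e-6, (np.quantile(a_true, 0.975) - np.quantile(a_true, 0.025)) / 2)
    z = (a_true - mid) / half
    return amplitude * (z**2 - 1.0 / 3.0)


def _simulate_study(
    config: SimulationConfig,
    rng: np.random.Generator,
    panel: pd.DataFrame,
    truth: pd.DataFrame,
    sample_meta: pd.DataFrame,
    effect_for_group: dict[str, str],
    biological_sd: float,
    severity_sd: float,
    sample_dye: str,
) -> list[ArrayScan]:
    """Generate all arrays of one study (shared reference pool)."""
    antibodies = list(panel["antibody_id"])
    proteins = list(panel["protein"])
    n_p = len(antibodies)
    n_s = len(sample_meta)
    n_r = config.n_replicate_spots

    base_log2 = np.log2(config.signal_scale) + config.abundance_log2_sd * rng.standard_normal(n_p)
    # planted markers sit on detectable (above-median) baselines
    is_marker = (truth.loc[proteins, "marker_class"] != "null").to_numpy()
    base_log2[is_marker] = np.log2(config.signal_scale) + config.abundance_log2_sd * np.abs(
        rng.standard_normal(is_marker.sum())
    )

    effects = np.zeros((n_p, n_s))
    for j, (_, meta) in enumerate(sample_meta.iterrows()):
        col = effect_for_group.get(meta["group"])
        if col is not None:
            # per-sample severity scales all of a sample's marker effects
            # jointly: markers co-vary within a patient/cell line
            severity = 1.0 + severity_sd * rng.standard_normal()
            effects[:, j] = truth.loc[proteins, col].to_numpy() * severity
    s_log2 = (
        base_log2[:, None]
        + effects
        + biological_sd * rng.standard_normal((n_p, n_s))
    )
    # common reference: a pool covering every protein at its baseline
    # abundance (intracellular lysate pool / all-sera pool), applied at a
    # higher effective concentration; it does not carry the disease effects
    r_log2 = base_log2 + config.reference_scale_log2

    a_true = 0.5 * (s_log2 + r_log2[:, None])
    bias = _dye_bias_log2(a_true, config.dye_bias_amplitude)
    s_lin = 2.0 ** (s_log2 + bias)
    r_lin = 2.0 ** r_log2

    sigma_ln = np.sqrt(np.log1p(config.replicate_cv**2))
    grid = _spot_grid(n_p, n_r)
    scans: list[ArrayScan] = []
    for j, (sid, meta) in enumerate(sample_meta.iterrows()):
        def _channel(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            rep = np.exp(sigma_ln * rng.standard_normal((n_r, n_p)) - 0.5 * sigma_ln**2)
            b_true = config.background_mean + 0.1 * config.background_sd * rng.standard_normal(
                (n_r, n_p)
            )
            fg = b_true + signal * rep + config.foreground_noise_sd * rng.standard_normal(
                (n_r, n_p)
            )
            b_sd = config.background_sd * np.exp(0.05 * rng.standard_normal((n_r, n_p)))
            return (
                np.maximum(np.rint(fg), 0.0),
                np.maximum(np.rint(b_true), 0.0),
                np.round(b_sd, 1),
            )

        f_s, b_s, sd_s = _channel(s_lin[:, j])
        f_r, b_r, sd_r = _channel(np.broadcast_to(r_lin, (n_p,)))
        flags = np.where(
            rng.random((n_r, n_p)) < config.flagged_fraction, -100, 0
        ).astype(np.int64)
        spots = pd.DataFrame(
            {
                "block": grid["block"].to_numpy(),
                "column": grid["column"].to_numpy(),
                "row": grid["row"].to_numpy(),
                "antibody_id": np.tile(antibodies, n_r),
                "f_sample": f_s.ravel(),
                "b_sample": b_s.ravel(),
                "b_sample_sd": sd_s.ravel(),
                "f_ref": f_r.ravel(),
                "b_ref": b_r.ravel(),
                "b_ref_sd": sd_r.ravel(),
                "flag": flags.ravel(),
            }
        )
        scans.append(
            ArrayScan(
                sample_id=str(sid),
                group=meta["group"],
                cohort=meta["cohort"],
                panel_id=meta["panel_id"],
                spots=spots,
                sample_dye=sample_dye,
            )
        )
    return scans


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate the full two-study design (secretome + two serum cohorts).

    Returns one :class:`ArrayScan` per sample, the planted
    :class:`GroundTruth`, and panel/sample manifests.  The output is a pure
    function of ``config`` (including ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)

    n_core = config.n_antibodies - config.n_panel1_missing
    n_extra = config.n_antibodies_extended - n_core
    n_total = config.n_antibodies + n_extra
    antibodies = [f"AB{i + 1:05d}" for i in range(n_total)]
    proteins = [f"PROT{i + 1:05d}" for i in range(n_total)]
    # panel 1 = first n_antibodies; its last n_panel1_missing antibodies are
    # absent from panel 2, which adds n_extra new antibodies instead
    on_p1 = np.arange(n_total) < config.n_antibodies
    on_p2 = (np.arange(n_total) < n_core) | (np.arange(n_total) >= config.n_antibodies)
    panel = pd.DataFrame(
        {
            "antibody_id": antibodies,
            "protein": proteins,
            "panels": [
                ",".join(p for p, on in (("P1", a), ("P2", b)) if on)
                for a, b in zip(on_p1, on_p2)
            ],
        }
    )
    core_proteins = [p for p, a, b in zip(proteins, on_p1, on_p2) if a and b]
    panel2_proteins = [p for p, b in zip(proteins, on_p2) if b]

    truth_table = _plant_effects(config, rng, proteins, core_proteins, panel2_proteins)
    truth_table.insert(0, "antibody_id", antibodies)
    truth = GroundTruth(table=truth_table)

    # --- sample manifests -------------------------------------------------
    def _meta(prefix: str, n: int, group: str, cohort: str, dye: str, panel_id: str) -> pd.DataFrame:
        ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "group": group,
                "cohort": cohort,
                "sample_dye": dye,
                "panel_id": panel_id,
            }
        ).set_index("sample_id", drop=False)

    secretome_meta = pd.concat(
        [
            _meta("SEC_T", config.secretome_cell_lines, "TUMOR_SECRETOME", "TRAINING", "DY649", "P1"),
            _meta("SEC_C", config.secretome_control_arrays, "CONTROL_SECRETOME", "TRAINING", "DY649", "P1"),
        ]
    )
    serum_meta = pd.concat(
        [
            _meta("TR_PD", config.train_pdac, "PDAC", "TRAINING", "DY549", "P2"),
            _meta("TR_CP", config.train_cp, "CP", "TRAINING", "DY549", "P2"),
            _meta("TR_HE", config.train_healthy, "HEALTHY", "TRAINING", "DY549", "P2"),
            _meta("TE_PD", config.test_pdac, "PDAC", "TEST", "DY549", "P2"),
            _meta("TE_CP", config.test_cp, "CP", "TEST", "DY549", "P2"),
            _meta("TE_HE", config.test_healthy, "HEALTHY", "TEST", "DY549", "P2"),
        ]
    )

    panel1 = panel[on_p1].reset_index(drop=True)
    panel2 = panel[on_p2].reset_index(drop=True)

    secretome_scans = _simulate_study(
        config,
        rng,
        panel1,
        truth_table,
        secretome_meta,
        {"TUMOR_SECRETOME": "effect_secretome"},
        config.biological_sd_secretome,
        config.severity_sd_secretome,
        sample_dye="DY649",
    )
    serum_scans = _simulate_study(
        config,
        rng,
        panel2,
        truth_table,
        serum_meta,
        {"PDAC": "effect_serum_pdac", "CP": "effect_serum_cp"},
        config.biological_sd_serum,
        config.severity_sd_serum,
        sample_dye="DY549",
    )

    samples = pd.concat([secretome_meta, serum_meta])
    samples["file"] = samples["sample_id"] + ".gpr"
    return SimulatedExperiment(
        scans=secretome_scans + serum_scans,
        truth=truth,
        panel=panel,
        samples=samples,
    )
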