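"""Reading and writing spot-level antibody-microarray quantification files.

The on-disk dialect is a tab-delimited table whose column names follow the
GenePix Results vocabulary (``Block``, ``Column``, ``Row``, ``ID``,
``F635 Median``, ``B635 Median``, ``B635 SD``, ``F532 Median``,
``B532 Median``, ``B532 SD``, ``Flags``).  An ATF-style preamble before the
header line is tolerated but never written.  Which dye carries the sample and
which the common reference is *not* encoded in the file; it comes from the
sample manifest, so dye-swapped designs (sample on DY-649 for one study, on
DY-549 for the other) are handled uniformly.

In memory an array is an :class:`ArrayScan`: sample metadata plus a
:class:`pandas.DataFrame` of spots in role-mapped columns (``f_sample``,
``b_sample`` ... rather than per-dye names), so every downstream stage is
independent of the dye orientation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "COHORTS",
    "DYES",
    "SPOT_COLUMNS",
    "ArrayScan",
    "GprFormatError",
    "ManifestError",
    "SpotValidationError",
    "read_gpr",
    "write_gpr",
    "read_manifests",
    "write_manifests",
]

GROUPS = ("PDAC", "CP", "HEALTHY", "TUMOR_SECRETOME", "CONTROL_SECRETOME")
COHORTS = ("TRAINING", "TEST")
DYES = ("DY649", "DY549")

#: canonical in-memory spot columns, in storage order
SPOT_COLUMNS = [
    "block",
    "column",
    "row",
    "antibody_id",
    "f_sample",
    "b_sample",
    "b_sample_sd",
    "f_ref",
    "b_ref",
    "b_ref_sd",
    "flag",
]

# GPR column name for each (role column, dye) pair; 635 nm excites DY-649
# (red), 532 nm excites DY-549 (green).
_DYE_WAVELENGTH = {"DY649": "635", "DY549": "532"}
_INT_COLS = ["block", "column", "row", "flag"]
_FLOAT_COLS = ["f_sample", "b_sample", "b_sample_sd", "f_ref", "b_ref", "b_ref_sd"]


class GprFormatError(ValueError):
    """Raised when a quantification file does not match the dialect."""


class SpotValidationError(ValueError):
    """Raised when spot values violate basic validity (negative intensity...)."""


class ManifestError(ValueError):
    """Raised for malformed panel or sample manifests."""


@dataclass
class ArrayScan:
    """All spots of one hybridized slide plus its sample metadata."""

    sample_id: str
    group: str
    cohort: str
    panel_id: str
    spots: pd.DataFrame
    sample_dye: str = "DY649"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ManifestError(
                f"unknown group {self.group!r}; allowed: {', '.join(GROUPS)}"
            )
        if self.cohort not in COHORTS:
            raise ManifestError(
                f"unknown cohort {self.cohort!r}; allowed: {', '.join(COHORTS)}"
            )
        if self.sample_dye not in DYES:
            raise ManifestError(
                f"unknown dye {self.sample_dye!r}; allowed: {', '.join(DYES)}"
            )
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise SpotValidationError(f"spot table missing columns: {missing}")
        self.spots = self.spots[SPOT_COLUMNS].reset_index(drop=True)
        _validate_spots(self.spots, origin=self.sample_id)

    def __eq__(self, other: object) -> bool:  # dataclass default chokes on frames
        if not isinstance(other, ArrayScan):
            return NotImplemented
        meta_eq = (
            self.sample_id == other.sample_id
            and self.group == other.group
            and self.cohort == other.cohort
            and self.panel_id == other.panel_id
            and self.sample_dye == other.sample_dye
        )
        return meta_eq and self.spots.equals(other.spots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def copy(self) -> "ArrayScan":
        return replace(self, spots=self.spots.copy())


def _validate_spots(spots: pd.DataFrame, origin: str = "?") -> None:
    pos = spots[["block", "column", "row"]]
    if pos.duplicated().any():
        dup = pos[pos.duplicated()].iloc[0]
        raise SpotValidationError(
            f"{origin}: duplicate grid position "
            f"(block={dup.block}, column={dup.column}, row={dup.row})"
        )
    vals = spots[_FLOAT_COLS].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        r = spots.iloc[i]
        raise SpotValidationError(
            f"{origin}: invalid intensity {_FLOAT_COLS[j]}={vals[i, j]!r} at "
            f"block={r.block}, column={r.column}, row={r.row} "
            "(intensities must be finite and >= 0)"
        )


def _gpr_columns(sample_dye: str) -> dict[str, str]:
    """Map canonical spot columns to GPR column names for a dye orientation."""
    s = _DYE_WAVELENGTH[sample_dye]
    r = _DYE_WAVELENGTH[[d for d in DYES if d != sample_dye][0]]
    return {
        "block": "Block",
        "column": "Column",
        "row": "Row",
        "antibody_id": "ID",
        "f_sample": f"F{s} Median",
        "b_sample": f"B{s} Median",
        "b_sample_sd": f"B{s} SD",
        "f_ref": f"F{r} Median",
        "b_ref": f"B{r} Median",
        "b_ref_sd": f"B{r} SD",
        "flag": "Flags",
    }


def read_gpr(
    path: str | os.PathLike,
    *,
    sample_id: str,
    group: str,
    cohort: str,
    panel_id: str = "P1",
    sample_dye: str = "DY649",
) -> ArrayScan:
    """Read one quantification file into an :class:`ArrayScan`.

    ``sample_dye`` (from the sample manifest) decides whether the 635 nm or
    the 532 nm channel is the sample; the other channel is the common
    reference.  The file may start with an ATF-style preamble, which is
    skipped; the line holding ``Block`` starts the table.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines[:64]):
        fields = line.rstrip("\n").split("\t")
        if "Block" in [f.strip().strip('"') for f in fields]:
            header_idx = i
            break
    if header_idx is None:
        raise GprFormatError(
            f"{path}: no header line containing a 'Block' column found "
            "in the first 64 lines"
        )
    table = "\n".join(lines[header_idx:])
    df = pd.read_csv(io.StringIO(table), sep="\t", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().strip('"') for c in df.columns]

    colmap = _gpr_columns(sample_dye)
    missing = [gpr for gpr in colmap.values() if gpr not in df.columns]
    if missing:
        raise GprFormatError(
            f"{path}: missing required column(s) {missing} in header line "
            f"{header_idx + 1}"
        )
    out = pd.DataFrame({canon: df[gpr] for canon, gpr in colmap.items()})
    for c in _INT_COLS:
        out[c] = np.array([int(v) for v in out[c]], dtype=np.int64)
    for c in _FLOAT_COLS:
        # Python's float() is correctly rounded (pd.to_numeric is not)
        out[c] = np.array([float(v) for v in out[c]], dtype=float)
    out["antibody_id"] = out["antibody_id"].astype(str)
    return ArrayScan(
        sample_id=sample_id,
        group=group,
        cohort=cohort,
        panel_id=panel_id,
        spots=out,
        sample_dye=sample_dye,
    )


def write_gpr(scan: ArrayScan, path: str | os.PathLike) -> None:
    """Write a scan back to the tab-delimited dialect (inverse of read_gpr).

    Output is bit-stable for a fixed scan: values are rendered with Python's
    shortest-roundtrip float repr, so ``read_gpr(write_gpr(x)) == x``.
    """
    colmap = _gpr_columns(scan.sample_dye)
    cols = list(colmap.values())
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in scan.spots.itertuples(index=False):
            vals = [
                str(int(v)) if c in _INT_COLS else (v if c == "antibody_id" else repr(float(v)))
                for c, v in zip(SPOT_COLUMNS, row)
            ]
            fh.write("\t".join(vals) + "\n")


def read_manifests(
    panel_path: str | os.PathLike, sample_path: str | os.PathLike
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the antibody-panel and sample manifests.

    Panel manifest (TSV, required columns ``antibody_id``, ``protein``;
    optional ``panels`` as a comma-separated list of panel ids): one row per
    antibody.  Several antibodies may map to the same protein; aggregation
    stays per-antibody, reporting is per-protein.

    Sample manifest (TSV, required columns ``sample_id``, ``group``,
    ``cohort``; optional ``sample_dye``, ``panel_id``, ``file``): one row per
    hybridized array.
    """
    panel = pd.read_csv(panel_path, sep="\t", dtype=str)
    for col in ("antibody_id", "protein"):
        if col not in panel.columns:
            raise ManifestError(f"panel manifest missing required column {col!r}")
    if panel["antibody_id"].duplicated().any():
        dup = panel.loc[panel["antibody_id"].duplicated(), "antibody_id"].iloc[0]
        raise ManifestError(f"panel manifest: duplicate antibody id {dup!r}")
    if "panels" not in panel.columns:
        panel["panels"] = "P1"

    samples = pd.read_csv(sample_path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "cohort"):
        if col not in samples.columns:
            raise ManifestError(f"sample manifest missing required column {col!r}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ManifestError(f"sample manifest: duplicate sample id {dup!r}")
    bad_group = sorted(set(samples["group"]) - set(GROUPS))
    if bad_group:
        raise ManifestError(
            f"sample manifest: unknown group label(s) {bad_group}; "
            f"allowed: {', '.join(GROUPS)}"
        )
    bad_cohort = sorted(set(samples["cohort"]) - set(COHORTS))
    if bad_cohort:
        raise ManifestError(
            f"sample manifest: unknown cohort label(s) {bad_cohort}; "
            f"allowed: {', '.join(COHORTS)}"
        )
    if "sample_dye" not in samples.columns:
        samples["sample_dye"] = "DY649"
    bad_dye = sorted(set(samples["sample_dye"]) - set(DYES))
    if bad_dye:
        raise ManifestError(
            f"sample manifest: unknown dye label(s) {bad_dye}; "
            f"allowed: {', '.join(DYES)}"
        )
    if "panel_id" not in samples.columns:
        samples["panel_id"] = "P1"
    return panel.set_index("antibody_id", drop=False), samples.set_index(
        "sample_id", drop=False
    )


def write_manifests(
    panel: pd.DataFrame,
    samples: pd.DataFrame,
    panel_path: str | os.PathLike,
    sample_path: str | os.PathLike,
) -> None:
    panel.to_csv(panel_path, sep="\t", index=False)
    samples.to_csv(sample_path, sep="\t", index=False)
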