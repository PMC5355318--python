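"""Cross-referencing secretome and serum differential tables.

The discovery rule for candidate serum markers: a protein qualifies as a
``shared`` marker when it is differentially abundant in the tumor-cell
secretome, differentially abundant in PDAC serum versus healthy serum *in
the same direction*, and shows no differential abundance in either
chronic-pancreatitis (CP) contrast — markers that also move in the benign
confounder disease are useless for distinguishing cancer from pancreatitis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MarkerSet", "intersect_markers", "compare_proteome_overlap"]


@dataclass
class MarkerSet:
    """Per-protein provenance (shared / secretome_only / serum_only) table."""

    table: pd.DataFrame  # index protein; columns below

    def proteins(self, provenance: str) -> list[str]:
        t = self.table
        return sorted(t.index[t["provenance"] == provenance])

    @property
    def shared(self) -> list[str]:
        return self.proteins("shared")


def _by_protein(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse an antibody-indexed differential table to protein level.

    With several antibodies per protein, the protein counts as significant
    if any of its antibodies is, and direction/magnitude come from the
    antibody with the smallest raw p.
    """
    t = table.sort_values("p_raw", kind="stable")
    best = t.drop_duplicates(subset="protein", keep="first").set_index("protein")
    sig = table.groupby("protein")["significant"].any()
    best = best.copy()
    best["significant"] = sig.reindex(best.index)
    return best


def intersect_markers(
    secretome: pd.DataFrame,
    serum_pdac: pd.DataFrame,
    cp_contrasts: pd.DataFrame | list[pd.DataFrame],
) -> MarkerSet:
    """Build the shared / secretome-only / serum-only marker sets.

    ``shared`` = significant in the secretome contrast AND significant in
    serum PDAC-vs-healthy AND same direction AND not significant in any of
    the supplied CP contrasts (typically CP-vs-healthy and PDAC-vs-CP).
    A protein absent from a CP table (e.g. dropped for missingness there)
    counts as not CP-significant.
    """
    if isinstance(cp_contrasts, pd.DataFrame):
        cp_contrasts = [cp_contrasts]
    sec = _by_protein(secretome)
    ser = _by_protein(serum_pdac)
    common = sec.index.intersection(ser.index)
    if len(common) == 0:
        raise ValueError(
            "secretome and serum tables share no proteins; "
            "were the panels intersected?"
        )
    cp_sig: set[str] = set()
    for cp in cp_contrasts:
        t = _by_protein(cp)
        cp_sig |= set(t.index[t["significant"]])

    rows = []
    for prot in common:
        s_row, r_row = sec.loc[prot], ser.loc[prot]
        sec_sig = bool(s_row["significant"])
        ser_sig = bool(r_row["significant"])
        concordant = s_row["direction"] == r_row["direction"] and s_row["direction"] != ""
        in_cp = prot in cp_sig
        if sec_sig and ser_sig and concordant and not in_cp:
            prov = "shared"
        elif sec_sig:
            prov = "secretome_only"
        elif ser_sig:
            prov = "serum_only"
        else:
            continue
        rows.append(
            {
                "protein": prot,
                "provenance": prov,
                "secretome_direction": s_row["direction"],
                "secretome_delta": float(s_row["delta_M"]),
                "serum_direction": r_row["direction"],
                "serum_delta": float(r_row["delta_M"]),
                "cp_significant": in_cp,
            }
        )
    # secretome-significant proteins not measurable in serum remain secretome_only
    for prot in sec.index.difference(ser.index):
        if bool(sec.loc[prot, "significant"]):
            rows.append(
                {
                    "protein": prot,
                    "provenance": "secretome_only",
                    "secretome_direction": sec.loc[prot, "direction"],
                    "secretome_delta": float(sec.loc[prot, "delta_M"]),
                    "serum_direction": "",
                    "serum_delta": np.nan,
                    "cp_significant": prot in cp_sig,
                }
            )
    for prot in ser.index.difference(sec.index):
        if bool(ser.loc[prot, "significant"]):
            rows.append(
                {
                    "protein": prot,
                    "provenance": "serum_only",
                    "secretome_direction": "",
                    "secretome_delta": np.nan,
                    "serum_direction": ser.loc[prot, "direction"],
                    "serum_delta": float(ser.loc[prot, "delta_M"]),
                    "cp_significant": prot in cp_sig,
                }
            )
    table = (
        pd.DataFrame(rows).set_index("protein").sort_index()
        if rows
        else pd.DataFrame(
            columns=[
                "provenance",
                "secretome_direction",
                "secretome_delta",
                "serum_direction",
                "serum_delta",
                "cp_significant",
            ]
        )
    )
    return MarkerSet(table=table)


def compare_proteome_overlap(
    secretome: pd.DataFrame, intracellular: pd.DataFrame
) -> pd.DataFrame:
    """Proteins significant and direction-concordant in both tables.

    Returns a tidy table with both log2 magnitudes (paired bar-chart ready).
    """
    sec = _by_protein(secretome)
    intra = _by_protein(intracellular)
    common = sec.index.intersection(intra.index)
    rows = []
    for prot in common:
        s, i = sec.loc[prot], intra.loc[prot]
        if (
            bool(s["significant"])
            and bool(i["significant"])
            and s["direction"] == i["direction"]
            and s["direction"] != ""
        ):
            rows.append(
                {
                    "protein": prot,
                    "direction": s["direction"],
                    "secretome_delta": float(s["delta_M"]),
                    "intracellular_delta": float(i["delta_M"]),
                }
            )
    return (
        pd.DataFrame(rows).set_index("protein").sort_index()
        if rows
        else pd.DataFrame(columns=["direction", "secretome_delta", "intracellular_delta"])
    )
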