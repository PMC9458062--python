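"""Cellular dosimetry: nucleus dose from cell-surface and cytoplasm activity.

For a single cell with activity bound to the plasma membrane (cell
surface, CS) and internalized into the cytoplasm (Cy), the mean
absorbed dose to the nucleus is

    D_N = N_CS · S(N←CS) + N_Cy · S(N←Cy)

where N_CS, N_Cy are the total nuclear transformations (Bq·s) in each
compartment — time-integrals of the per-cell activity — and the
S values (Gy per Bq·s) encode, for a given nuclide and cell/nucleus
geometry, the dose to the nucleus per decay in the source compartment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cumulated import integrate_sampled
from .nuclide import Radionuclide

__all__ = [
    "CellGeometry",
    "SValueTable",
    "CellularDoseResult",
    "nucleus_dose",
    "cell_cumulated_activities",
]

Compartment = Literal["cell_surface", "cytoplasm"]


class CellGeometry(BaseModel):
    """Concentric-spheres cell model: cell and nucleus radii in µm."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    cell_radius_um: float = Field(gt=0)
    nucleus_radius_um: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CellGeometry":
        if not self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("nucleus radius must be smaller than cell radius")
        return self

    def key(self) -> tuple[float, float]:
        return (self.cell_radius_um, self.nucleus_radius_um)


class SValueTable(BaseModel):
    """(nuclide, geometry, source compartment) → Gy per Bq·s to the nucleus."""

    model_config = ConfigDict(extra="forbid")

    rows: list[dict]

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
    ) -> "SValueTable":
        """Records are (nuclide, geometry, compartment, s) with an optional
        trailing cell_line element for line-specific rows."""
        rows = []
        for rec in records:
            nuc, geo, comp, s = rec[:4]
            rows.append({
                "nuclide": nuc, "cell_radius_um": geo.cell_radius_um,
                "nucleus_radius_um": geo.nucleus_radius_um,
                "source_compartment": comp, "s_gy_per_bq_s": float(s),
                "cell_line": rec[4] if len(rec) > 4 else None,
            })
        tab = cls(rows=rows)
        tab._validate()
        return tab

    @classmethod
    def from_csv(cls, path: str | Path) -> "SValueTable":
        df = pd.read_csv(path)
        required = {"nuclide", "cell_radius_um", "nucleus_radius_um",
                    "source_compartment", "s_gy_per_bq_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"S-value CSV missing columns: {sorted(missing)}")
        cols = sorted(required) + (["cell_line"] if "cell_line" in df.columns
                                   else [])
        rows = df[cols].to_dict("records")
        for r in rows:
            val = r.get("cell_line")
            r["cell_line"] = None if (val is None or pd.isna(val)) else str(val)
        tab = cls(rows=rows)
        tab._validate()
        return tab

    def to_csv(self, path: str | Path) -> None:
        cols = ["nuclide", "cell_radius_um", "nucleus_radius_um",
                "source_compartment", "s_gy_per_bq_s"]
        if any(r.get("cell_line") for r in self.rows):
            cols.append("cell_line")
        pd.DataFrame(self.rows)[cols].to_csv(path, index=False)

    def _validate(self) -> None:
        keys = [(r["nuclide"], r["cell_radius_um"], r["nucleus_radius_um"],
                 r["source_compartment"], r.get("cell_line"))
                for r in self.rows]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate S-value keys")
        if any(r["s_gy_per_bq_s"] < 0 for r in self.rows):
            raise ValueError("S values must be ≥ 0")

    def lookup(
        self,
        nuclide: str,
        geometry: CellGeometry,
        compartment: Compartment,
        cell_line: str | None = None,
    ) -> float:
        """Exact-key S-value lookup; a line-specific row (matching
        ``cell_line``) takes precedence over a line-agnostic one."""
        fallback = None
        for r in self.rows:
            if (r["nuclide"] == nuclide
                    and r["cell_radius_um"] == geometry.cell_radius_um
                    and r["nucleus_radius_um"] == geometry.nucleus_radius_um
                    and r["source_compartment"] == compartment):
                line = r.get("cell_line")
                if cell_line is not None and line == cell_line:
                    return float(r["s_gy_per_bq_s"])
                if line is None and fallback is None:
                    fallback = float(r["s_gy_per_bq_s"])
                elif cell_line is None and fallback is None:
                    fallback = float(r["s_gy_per_bq_s"])
        if fallback is not None:
            return fallback
        raise KeyError((nuclide, geometry.key(), compartment, cell_line))


class CellularDoseResult(BaseModel):
    """Nucleus dose split by source compartment for one cell line."""

    model_config = ConfigDict(extra="forbid")

    cell_line: str
    n_cs_bq_s: float = Field(ge=0)
    n_cy_bq_s: float = Field(ge=0)
    dose_cs_gy: float = Field(ge=0)
    dose_cy_gy: float = Field(ge=0)
    dose_total_gy: float = Field(ge=0)


def nucleus_dose(
    n_cs_bq_s: float,
    n_cy_bq_s: float,
    s_table: SValueTable,
    nuclide: Radionuclide | str,
    geometry: CellGeometry,
    cell_line: str = "",
) -> CellularDoseResult:
    """Nucleus dose D_N = N_CS·S(N←CS) + N_Cy·S(N←Cy) in Gy.

    Both S rows must exist for (nuclide, geometry); a missing row raises
    ``KeyError`` naming the missing key.
    """
    nuc_name = nuclide.name if isinstance(nuclide, Radionuclide) else nuclide
    line = cell_line or None
    s_cs = s_table.lookup(nuc_name, geometry, "cell_surface", line)
    s_cy = s_table.lookup(nuc_name, geometry, "cytoplasm", line)
    dose_cs = n_cs_bq_s * s_cs
    dose_cy = n_cy_bq_s * s_cy
    return CellularDoseResult(
        cell_line=cell_line,
        n_cs_bq_s=n_cs_bq_s,
        n_cy_bq_s=n_cy_bq_s,
        dose_cs_gy=dose_cs,
        dose_cy_gy=dose_cy,
        dose_total_gy=dose_cs + dose_cy,
    )


def cell_cumulated_activities(
    uptake_times_h: Sequence[float],
    uptake_bq_per_cell: Sequence[float],
    internalized_times_h: Sequence[float],
    internalized_bq_per_cell: Sequence[float],
    nuclide: Radionuclide,
    tail_model: Literal["exp_fit", "physical_decay"] = "exp_fit",
) -> tuple[float, float]:
    """Integrate membrane and cytoplasm per-cell activity curves to Bq·s.

    Delegates to :func:`radiokinetics.cumulated.integrate_sampled` per
    compartment; returns (N_CS, N_Cy).
    """
    n_cs = integrate_sampled(uptake_times_h, uptake_bq_per_cell,
                             nuclide, tail_model, region="cell_surface")
    n_cy = integrate_sampled(internalized_times_h, internalized_bq_per_cell,
                             nuclide, tail_model, region="cytoplasm")
    return n_cs.n_transformations, n_cy.n_transformations
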