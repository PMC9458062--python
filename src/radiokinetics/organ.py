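"""Organ and tumor absorbed doses from cumulated activities (MIRD schema).

D_target = Σ_source N_source · DF_target←source, with N in MBq·s and
dose factors in mGy/MBq·s for a fixed geometry (e.g. a 25 g mouse
whole-body model, or a unit-density sphere for a small tumor). Dose is
linear in administered activity under fixed kinetics, so a dose
computed at one administered activity scales by a simple ratio.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cumulated import CumulatedActivity

__all__ = [
    "DoseFactorTable",
    "AbsorbedDoseResult",
    "absorbed_dose",
    "scale_dose",
    "derive_df_fixture",
]


class DoseFactorTable(BaseModel):
    """(source, target, geometry) → dose factor in mGy per MBq·s.

    Exact-key lookup only; a missing key is an error, never a silent
    zero, and no interpolation across geometries is attempted.
    """

    model_config = ConfigDict(extra="forbid")

    rows: list[dict]

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, float, str]]
    ) -> "DoseFactorTable":
        rows = [
            {"source_region": s, "target_region": t,
             "df_mgy_per_mbq_s": float(df), "geometry": g}
            for s, t, df, g in records
        ]
        tab = cls(rows=rows)
        tab._validate()
        return tab

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseFactorTable":
        df = pd.read_csv(path)
        required = {"source_region", "target_region", "df_mgy_per_mbq_s", "geometry"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dose-factor CSV missing columns: {sorted(missing)}")
        tab = cls(rows=df[sorted(required)].to_dict("records"))
        tab._validate()
        return tab

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows)[
            ["source_region", "target_region", "df_mgy_per_mbq_s", "geometry"]
        ].to_csv(path, index=False)

    def _validate(self) -> None:
        keys = [(r["source_region"], r["target_region"], r["geometry"])
                for r in self.rows]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (source, target, geometry) keys")
        if any(r["df_mgy_per_mbq_s"] < 0 for r in self.rows):
            raise ValueError("dose factors must be ≥ 0")

    def lookup(self, source: str, target: str) -> float:
        """Dose factor for (source → target), any geometry; unique match required."""
        hits = [r for r in self.rows
                if r["source_region"] == source and r["target_region"] == target]
        if not hits:
            raise KeyError((source, target))
        if len(hits) > 1:
            raise ValueError(
                f"ambiguous dose factor for ({source!r}, {target!r}): "
                f"{len(hits)} geometries; filter the table first"
            )
        return float(hits[0]["df_mgy_per_mbq_s"])

    def has(self, source: str, target: str) -> bool:
        return any(r["source_region"] == source and r["target_region"] == target
                   for r in self.rows)


class AbsorbedDoseResult(BaseModel):
    """Absorbed dose to one target with per-source contributions (Gy)."""

    model_config = ConfigDict(extra="forbid")

    target_region: str
    dose_gy: float = Field(ge=0)
    administered_activity_mbq: float
    contributions: list[tuple[str, float]]


def absorbed_dose(
    cumulated: Sequence[CumulatedActivity],
    df_table: DoseFactorTable,
    target: str,
) -> AbsorbedDoseResult:
    """Sum N_source·DF_target←source/1000 over all contributing sources.

    Every source region with N > 0 must have a dose-factor row for the
    target when it is expected to contribute; sources entirely absent
    from the table for this target are an error (no silent zeros) —
    except sources with N = 0, which contribute nothing regardless.
    """
    if not cumulated:
        raise ValueError("no cumulated activities supplied")
    admins = {c.administered_activity_mbq for c in cumulated
              if c.administered_activity_mbq is not None}
    if len(admins) > 1:
        raise ValueError(
            f"cumulated activities mix administered activities: {sorted(admins)}"
        )
    administered = admins.pop() if admins else 0.0

    missing = [c.region for c in cumulated
               if c.n_transformations > 0 and not df_table.has(c.region, target)]
    if missing:
        raise KeyError(
            f"no dose factor for sources {missing} → target {target!r}"
        )
    contributions = []
    for c in cumulated:
        if c.n_transformations == 0 and not df_table.has(c.region, target):
            continue
        dose = c.n_transformations * df_table.lookup(c.region, target) / 1000.0
        contributions.append((c.region, dose))
    return AbsorbedDoseResult(
        target_region=target,
        dose_gy=sum(d for _, d in contributions),
        administered_activity_mbq=administered,
        contributions=contributions,
    )


def scale_dose(
    result: AbsorbedDoseResult, new_administered_mbq: float
) -> AbsorbedDoseResult:
    """Rescale a dose to a different administered activity (fixed kinetics)."""
    if result.administered_activity_mbq <= 0:
        raise ValueError("original administered activity must be > 0 to scale")
    if new_administered_mbq <= 0:
        raise ValueError("new administered activity must be > 0")
    ratio = new_administered_mbq / result.administered_activity_mbq
    return AbsorbedDoseResult(
        target_region=result.target_region,
        dose_gy=result.dose_gy * ratio,
        administered_activity_mbq=new_administered_mbq,
        contributions=[(s, d * ratio) for s, d in result.contributions],
    )


def derive_df_fixture(
    n_table: Mapping[str, float],
    d_table: Mapping[str, float],
    geometry: str = "derived_from_published_doses",
) -> DoseFactorTable:
    """Back-derive self-dose factors DF = D/N·1000 from printed (N, D) pairs.

    This builds a *circular* fixture: feeding it back through
    :func:`absorbed_dose` reproduces the printed doses by construction.
    It validates pipeline wiring and unit handling only — it is not a
    source of genuine dose factors, which must come from a radiation
    transport code.
    """
    if set(n_table) != set(d_table):
        raise ValueError("region keys of N and D tables must match")
    records = []
    for region in n_table:
        n, d = n_table[region], d_table[region]
        if n == 0:
            if d > 0:
                raise ValueError(f"{region}: D > 0 with N = 0 is inconsistent")
            df = 0.0
        else:
            df = d / n * 1000.0
        records.append((region, region, df, geometry))
    return DoseFactorTable.from_records(records)
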