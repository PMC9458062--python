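"""CSV/JSON readers and writers for the pipeline's tabular interfaces.

Dialect is fixed: UTF-8, comma separator, '.' decimal, header required.
JSON field names carry units (``…_gy``, ``…_mbq_s``, ``…_per_h``) so
the Bq·s / MBq·s distinction cannot be confused.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .biokinetics import TimeActivityCurve, TimeActivitySample
from .cellular import CellularDoseResult
from .cumulated import CumulatedActivity
from .organ import AbsorbedDoseResult

__all__ = [
    "read_time_activity_csv",
    "write_time_activity_csv",
    "write_cumulated_csv",
    "write_dose_report",
    "write_cell_dose_csv",
]

_TA_REQUIRED = ["region", "time_h", "value_pct_ia", "decay_corrected"]
_TA_OPTIONAL = ["sd_pct_ia", "n_animals"]


def read_time_activity_csv(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Read time–activity curves, one per region, from the package dialect.

    Required columns: region, time_h, value_pct_ia, decay_corrected
    (0/1); optional: sd_pct_ia, n_animals. Raises ``ValueError`` with
    the offending row index on malformed rows.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty or headerless CSV") from None
    missing = [c for c in _TA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    curves: dict[str, TimeActivityCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("time_h")
        samples = []
        for idx, row in grp.iterrows():
            try:
                samples.append(TimeActivitySample(
                    time_h=float(row["time_h"]),
                    value_pct_ia=float(row["value_pct_ia"]),
                    decay_corrected=bool(int(row["decay_corrected"])),
                    sd_pct_ia=(float(row["sd_pct_ia"])
                               if "sd_pct_ia" in grp.columns
                               and pd.notna(row["sd_pct_ia"]) else None),
                    n_animals=(int(row["n_animals"])
                               if "n_animals" in grp.columns
                               and pd.notna(row["n_animals"]) else None),
                ))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: bad row {idx + 2}: {exc}") from None
        curves[str(region)] = TimeActivityCurve(region=str(region), samples=samples)
    if not curves:
        raise ValueError(f"{path}: no data rows")
    return curves


def write_time_activity_csv(
    curves: dict[str, TimeActivityCurve], path: str | Path
) -> None:
    rows = []
    for region, curve in curves.items():
        for s in curve.samples:
            rows.append({
                "region": region,
                "time_h": s.time_h,
                "value_pct_ia": s.value_pct_ia,
                "sd_pct_ia": s.sd_pct_ia,
                "n_animals": s.n_animals,
                "decay_corrected": int(s.decay_corrected),
            })
    pd.DataFrame(rows, columns=_TA_REQUIRED[:3] + _TA_OPTIONAL
                 + ["decay_corrected"]).to_csv(path, index=False)


def write_cumulated_csv(
    results: Sequence[CumulatedActivity], path: str | Path
) -> None:
    pd.DataFrame([
        {"region": c.region,
         "n_transformations": c.n_transformations,
         "units": c.units,
         "method": c.method,
         "administered_activity_mbq": c.administered_activity_mbq}
        for c in results
    ]).to_csv(path, index=False)


def write_dose_report(
    results: Sequence[AbsorbedDoseResult],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write per-target doses with per-source contributions."""
    if csv_path is not None:
        rows = []
        for r in results:
            for source, dose in r.contributions:
                rows.append({
                    "target_region": r.target_region,
                    "source_region": source,
                    "contribution_gy": dose,
                    "dose_gy": r.dose_gy,
                    "administered_activity_mbq": r.administered_activity_mbq,
                })
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [
            {"target_region": r.target_region,
             "dose_gy": r.dose_gy,
             "administered_activity_mbq": r.administered_activity_mbq,
             "contributions": [
                 {"source_region": s, "dose_gy": d} for s, d in r.contributions
             ]}
            for r in results
        ]
        Path(json_path).write_text(json.dumps(payload, indent=1) + "\n",
                                   encoding="utf-8")


def write_cell_dose_csv(
    results: Sequence[CellularDoseResult], path: str | Path
) -> None:
    pd.DataFrame([
        {"cell_line": r.cell_line,
         "n_cs_bq_s": r.n_cs_bq_s,
         "n_cy_bq_s": r.n_cy_bq_s,
         "dose_cs_gy": r.dose_cs_gy,
         "dose_cy_gy": r.dose_cy_gy,
         "dose_total_gy": r.dose_total_gy}
        for r in results
    ]).to_csv(path, index=False)
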