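"""Published reference values from the ¹³¹I-C19 preclinical study.

These are the printed results of a biodistribution and dosimetry study
of ¹³¹I-C19 (an iodinated K-Ras4B/PDE6δ-targeting compound labelled
with iodine-131) in tumor-bearing mice and colorectal cancer cell
lines. They serve as worked-example inputs and consistency fixtures:

* the fitted blood-clearance models (effective and decay-corrected),
* per-organ/tumor total nuclear transformations and absorbed doses at
  5 MBq administered (25 g mouse model; 0.1 g unit-density sphere for
  the tumor),
* per-cell-line cumulated activities by compartment and the resulting
  nucleus doses,
* the cell/nucleus geometries used for the cellular S values.

Dose factors and S values were not published; ``derived_*`` helpers
back-derive self-dose fixtures from the printed (N, D) pairs. Those
fixtures are circular by construction and are suitable only for
pipeline-wiring and unit-handling checks, never as physical data.
"""

from __future__ import annotations

from .biokinetics import BiokineticModel, ExponentialTerm, Representation
from .cellular import CellGeometry, SValueTable
from .nuclide import I131
from .organ import DoseFactorTable, derive_df_fixture

__all__ = [
    "ADMINISTERED_MBQ",
    "BLOOD_MODEL_EFFECTIVE",
    "BLOOD_MODEL_BIOLOGICAL",
    "ORGAN_N_MBQ_S",
    "ORGAN_DOSE_GY",
    "CELL_N_BQ_S",
    "CELL_DOSE_GY",
    "CELL_GEOMETRIES",
    "EXPOSURE_BQ_PER_CELL",
    "MEMBRANE_PEAK_PCT",
    "derived_organ_df_table",
    "derived_cell_s_table",
]

#: Administered activity of the biodistribution study (MBq per mouse).
ADMINISTERED_MBQ = 5.0

#: Fitted blood clearance of ¹³¹I-C19 (effective, as measured):
#: A(t) = 89.8·e^(−1.524 t) + 10.2·e^(−0.033 t)  [%IA, t in h]
BLOOD_MODEL_EFFECTIVE = BiokineticModel(
    region="blood",
    representation=Representation.effective_A,
    nuclide=I131,
    terms=[
        ExponentialTerm(coefficient_pct_ia=89.8, rate_per_h=1.524),
        ExponentialTerm(coefficient_pct_ia=10.2, rate_per_h=0.033),
    ],
)

#: Decay-corrected blood clearance (biological kinetics of the compound):
#: q(t) = 89.8·e^(−1.520 t) + 10.2·e^(−0.029 t). The published report
#: prints the slow-phase amplitude inconsistently (0.260 in the formula,
#: "remaining 10.2%" in the narrative and in the effective model); the
#: narrative amplitude pair is used here, matching the effective model.
BLOOD_MODEL_BIOLOGICAL = BiokineticModel(
    region="blood",
    representation=Representation.biological_q,
    nuclide=I131,
    terms=[
        ExponentialTerm(coefficient_pct_ia=89.8, rate_per_h=1.520),
        ExponentialTerm(coefficient_pct_ia=10.2, rate_per_h=0.029),
    ],
)

#: Total nuclear transformations per source region at 5 MBq (MBq·s).
ORGAN_N_MBQ_S: dict[str, float] = {
    "liver": 3816.0,
    "pancreas": 399.0,
    "kidney": 1796.0,
    "colon": 504.0,
    "lung": 421.0,
    "spleen": 151.0,
    "tumor": 7020.0,
}

#: Absorbed dose per region at 5 MBq administered (Gy).
ORGAN_DOSE_GY: dict[str, float] = {
    "liver": 0.34,
    "pancreas": 0.18,
    "kidney": 0.12,
    "colon": 0.14,
    "lung": 0.40,
    "spleen": 0.19,
    "tumor": 3.55,
}

#: Per-cell cumulated activities (Bq·s) by compartment.
CELL_N_BQ_S: dict[str, dict[str, float]] = {
    "HCT116": {"cell_surface": 2023.0, "cytoplasm": 47.0},
    "LoVo": {"cell_surface": 1609.0, "cytoplasm": 918.0},
    "SW620": {"cell_surface": 4248.0, "cytoplasm": 367.2},
}

#: Published nucleus dose per compartment (Gy).
CELL_DOSE_GY: dict[str, dict[str, float]] = {
    "HCT116": {"cell_surface": 0.18, "cytoplasm": 0.01},
    "LoVo": {"cell_surface": 0.15, "cytoplasm": 0.14},
    "SW620": {"cell_surface": 0.38, "cytoplasm": 0.05},
}

#: Cell and nucleus radii used for the cellular S values (µm).
CELL_GEOMETRIES: dict[str, CellGeometry] = {
    "HCT116": CellGeometry(cell_radius_um=10.0, nucleus_radius_um=5.0),
    "LoVo": CellGeometry(cell_radius_um=10.0, nucleus_radius_um=6.0),
    "SW620": CellGeometry(cell_radius_um=10.0, nucleus_radius_um=6.0),
}

#: Exposure activity in the uptake experiments (Bq per cell).
EXPOSURE_BQ_PER_CELL = 1.44

#: Peak membrane uptake at 3 h, % of exposure activity, per cell line.
MEMBRANE_PEAK_PCT: dict[str, float] = {
    "HCT116": 43.6,
    "LoVo": 40.2,
    "SW620": 45.6,
}


def derived_organ_df_table() -> DoseFactorTable:
    """Self-dose factor fixture DF = D/N back-derived from the organ table."""
    return derive_df_fixture(ORGAN_N_MBQ_S, ORGAN_DOSE_GY)


def derived_cell_s_table() -> SValueTable:
    """Cellular S-value fixture back-derived per cell line as D/N (Gy/Bq·s).

    LoVo and SW620 share the same stated geometry, yet their back-derived
    cell-surface S values disagree at the ~4% level — an artifact of the
    2-decimal rounding of the printed doses, since a genuine S value
    depends only on nuclide and geometry. The fixture therefore carries
    line-specific rows (the optional ``cell_line`` key) so each line
    round-trips its own printed doses; consistency checks across lines
    must tolerate the rounding (±0.005 Gy per compartment).
    """
    records = []
    for line in ("HCT116", "LoVo", "SW620"):
        geo = CELL_GEOMETRIES[line]
        for comp in ("cell_surface", "cytoplasm"):
            s = CELL_DOSE_GY[line][comp] / CELL_N_BQ_S[line][comp]
            records.append((I131.name, geo, comp, s, line))
    return SValueTable.from_records(records)


def per_line_s_table(line: str) -> SValueTable:
    """S-value fixture derived from a single cell line's own (N, D) pair.

    Using the line's own derived values reproduces that line's printed
    doses exactly, which is what the round-trip consistency checks need.
    """
    geo = CELL_GEOMETRIES[line]
    records = [
        (I131.name, geo, comp,
         CELL_DOSE_GY[line][comp] / CELL_N_BQ_S[line][comp])
        for comp in ("cell_surface", "cytoplasm")
    ]
    return SValueTable.from_records(records)
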