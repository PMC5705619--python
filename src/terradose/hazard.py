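"""Radiological hazard indices and NORM exemption screening.

Radium equivalent activity folds the three activities into one gamma-output
index (370 Bq/kg of ²²⁶Ra, 259 Bq/kg of ²³²Th and 4810 Bq/kg of ⁴⁰K are
taken to deliver the same dose rate):

    Ra_eq = C_U + (10/7)·C_Th + (10/130)·C_K          [Bq/kg]
    H_ex  = C_U/370 + C_Th/259 + C_K/4810             (= Ra_eq/370)
    H_in  = C_U/185 + C_Th/259 + C_K/4810             (= H_ex + C_U/370)

Under the secular-equilibrium assumption the measured ²³⁸U concentration
stands in for ²²⁶Ra in all three formulas.  Excess lifetime cancer risk
is ELCR = E·DL·RF with E in Sv/y, a 70-year duration of life and the ICRP
public risk factor 0.05/Sv, i.e. 3.5×10⁻⁶ per µSv/y at defaults.

NORM screening compares per-radionuclide activities (Bq/g) against the
oil-and-gas exemption levels; one bundled entry, "Pb-238 (as printed)",
reproduces its source verbatim even though no such nuclide exists, and is
excluded from default screening rather than silently reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .dosimetry import absorbed_dose_rate, annual_effective_dose, _combine
from .io import ActivityRecord, DoseCoefficients, data_path

__all__ = [
    "HazardResult",
    "RiskConfig",
    "ExemptionEntry",
    "radium_equivalent",
    "external_hazard",
    "internal_hazard",
    "excess_lifetime_cancer_risk",
    "hazard_table",
    "load_exemption_table",
    "norm_screen",
    "soil_ra226_screen",
    "BQ_PER_PCI",
    "RA226_SOIL_EXCESS_LIMIT_BQ_G",
]

#: 1 pCi = 0.037 Bq.
BQ_PER_PCI = 0.037

#: Allowed ²²⁶Ra excess over background in soil, Bq/g (5 pCi/g).
RA226_SOIL_EXCESS_LIMIT_BQ_G = 0.185


@dataclass(frozen=True)
class RiskConfig:
    """Lifetime-risk parameters: duration of life (y) and risk per Sv."""

    duration_of_life: float = 70.0
    risk_factor: float = 0.05

    def __post_init__(self) -> None:
        if self.duration_of_life <= 0 or self.risk_factor <= 0:
            raise ValueError("risk parameters must be > 0")


@dataclass(frozen=True)
class HazardResult:
    sample_id: str
    ra_eq: float  # Bq/kg
    ra_eq_uncertainty: float
    elcr: float
    elcr_uncertainty: float
    h_ex: float
    h_ex_uncertainty: float
    h_in: float
    h_in_uncertainty: float


@dataclass(frozen=True)
class ExemptionEntry:
    radionuclide: str
    level_bq_per_g: float
    level_pci_per_g: float
    default_screen: bool = True


def radium_equivalent(
    rec: ActivityRecord, uncertainty_mode: str = "linear"
) -> tuple[float, float]:
    """Radium equivalent activity, Bq/kg."""
    ra = rec.c_u + 10.0 / 7.0 * rec.c_th + 10.0 / 130.0 * rec.c_k
    sigma = _combine(
        [rec.u_u, 10.0 / 7.0 * rec.u_th, 10.0 / 130.0 * rec.u_k], uncertainty_mode
    )
    return ra, sigma


def external_hazard(
    rec: ActivityRecord, uncertainty_mode: str = "linear"
) -> tuple[float, float]:
    """External hazard index (dimensionless; < 1 for safe use)."""
    h = rec.c_u / 370.0 + rec.c_th / 259.0 + rec.c_k / 4810.0
    sigma = _combine(
        [rec.u_u / 370.0, rec.u_th / 259.0, rec.u_k / 4810.0], uncertainty_mode
    )
    return h, sigma


def internal_hazard(
    rec: ActivityRecord, uncertainty_mode: str = "linear"
) -> tuple[float, float]:
    """Internal hazard index; penalizes ²²⁶Ra (inhalation pathway) twofold."""
    h = rec.c_u / 185.0 + rec.c_th / 259.0 + rec.c_k / 4810.0
    sigma = _combine(
        [rec.u_u / 185.0, rec.u_th / 259.0, rec.u_k / 4810.0], uncertainty_mode
    )
    return h, sigma


def excess_lifetime_cancer_risk(
    effective_dose: float,
    effective_dose_uncertainty: float = 0.0,
    cfg: RiskConfig | None = None,
) -> tuple[float, float]:
    """ELCR from an annual effective dose in µSv/y (dimensionless risk)."""
    if effective_dose < 0:
        raise ValueError("effective dose must be >= 0")
    cfg = cfg or RiskConfig()
    factor = 1e-6 * cfg.duration_of_life * cfg.risk_factor
    return effective_dose * factor, effective_dose_uncertainty * factor


def hazard_table(
    records: Sequence[ActivityRecord],
    coeff: DoseCoefficients | None = None,
    cfg: RiskConfig | None = None,
    uncertainty_mode: str = "linear",
) -> tuple[list[HazardResult], pd.DataFrame]:
    """Per-sample hazard results plus a min/max/mean summary frame."""
    if not records:
        raise ValueError("cannot build a hazard table from no records")
    coeff = coeff or DoseCoefficients()
    cfg = cfg or RiskConfig()
    results = []
    for rec in records:
        ra, ra_sd = radium_equivalent(rec, uncertainty_mode)
        hex_, hex_sd = external_hazard(rec, uncertainty_mode)
        hin, hin_sd = internal_hazard(rec, uncertainty_mode)
        d, d_sd = absorbed_dose_rate(rec, coeff, uncertainty_mode)
        e, e_sd = annual_effective_dose(d, d_sd, coeff)
        elcr, elcr_sd = excess_lifetime_cancer_risk(e, e_sd, cfg)
        results.append(
            HazardResult(
                sample_id=rec.sample_id,
                ra_eq=ra,
                ra_eq_uncertainty=ra_sd,
                elcr=elcr,
                elcr_uncertainty=elcr_sd,
                h_ex=hex_,
                h_ex_uncertainty=hex_sd,
                h_in=hin,
                h_in_uncertainty=hin_sd,
            )
        )
    frame = pd.DataFrame(
        {
            "ra_eq_bq_kg": [r.ra_eq for r in results],
            "elcr": [r.elcr for r in results],
            "h_in": [r.h_in for r in results],
            "h_ex": [r.h_ex for r in results],
        }
    )
    summary = frame.agg(["min", "max", "mean"])
    return results, summary


def load_exemption_table() -> list[ExemptionEntry]:
    """The bundled oil-and-gas NORM exemption levels."""
    frame = pd.read_csv(data_path("exemption_levels.csv"))
    return [
        ExemptionEntry(
            radionuclide=row.radionuclide,
            level_bq_per_g=float(row.bq_per_g),
            level_pci_per_g=float(row.pci_per_g),
            default_screen=bool(row.default_screen),
        )
        for row in frame.itertuples()
    ]


def norm_screen(
    radionuclide: str,
    activity_bq_per_g: float,
    table: Sequence[ExemptionEntry] | None = None,
) -> str:
    """Classify a material against the NORM exemption level.

    Returns ``"exempt"`` when the activity does not exceed the level
    (boundary inclusive) and ``"NORM-controlled"`` otherwise.
    """
    table = table if table is not None else load_exemption_table()
    for entry in table:
        if entry.radionuclide == radionuclide:
            return (
                "exempt"
                if activity_bq_per_g <= entry.level_bq_per_g
                else "NORM-controlled"
            )
    raise KeyError(f"no exemption level for radionuclide {radionuclide!r}")


def soil_ra226_screen(activity_bq_per_g: float, background_bq_per_g: float) -> bool:
    """True (pass) if the ²²⁶Ra excess over background is ≤ 0.185 Bq/g."""
    if activity_bq_per_g < 0 or background_bq_per_g < 0:
        raise ValueError("activities must be >= 0")
    return activity_bq_per_g - background_bq_per_g <= RA226_SOIL_EXCESS_LIMIT_BQ_G
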