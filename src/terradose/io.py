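"""Reading and writing of activity-concentration and result tables.

The canonical exchange format is CSV (UTF-8, "." decimal separator) with
one row per soil sample carrying the specific activities of the three
primordial radionuclides (²³⁸U, ²³²Th, ⁴⁰K) in Bq/kg together with their
1σ instrument uncertainties.  A 26-sample survey table is bundled as a
fixture (``load_survey_table``) along with the gamma-line and NORM
exemption registries used elsewhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ActivityRecord",
    "DoseCoefficients",
    "DEFAULT_DIALECT",
    "read_activity_table",
    "records_to_frame",
    "write_activity_table",
    "summarize_table",
    "write_report",
    "load_survey_table",
    "data_path",
]

#: Default CSV column names for activity tables.
DEFAULT_DIALECT: Mapping[str, str] = {
    "sample_id": "sample_id",
    "c_u": "u_bqkg",
    "c_th": "th_bqkg",
    "c_k": "k_bqkg",
    "u_u": "u_sd",
    "u_th": "th_sd",
    "u_k": "k_sd",
}

_REQUIRED = ("sample_id", "c_u", "c_th", "c_k")
_UNCERTAINTY = ("u_u", "u_th", "u_k")


@dataclass(frozen=True)
class ActivityRecord:
    """Specific activities of one soil sample, Bq/kg, with 1σ uncertainties."""

    sample_id: str
    c_u: float
    c_th: float
    c_k: float
    u_u: float = 0.0
    u_th: float = 0.0
    u_k: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_u", "c_th", "c_k"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative concentration {name}"
                )
        for name in _UNCERTAINTY:
            if getattr(self, name) < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative uncertainty {name}"
                )


@dataclass(frozen=True)
class DoseCoefficients:
    """Activity-to-dose conversion constants.

    ``k_u``, ``k_th``, ``k_k`` are the UNSCEAR air-kerma conversion
    coefficients in nGy/h per Bq/kg; ``occupancy`` is the outdoor
    occupancy fraction; ``sv_per_gy`` combines the 0.7 Sv/Gy effective
    dose factor with the nGy→µSv scale, so the annual effective dose in
    µSv/y is ``D × hours_per_year × sv_per_gy``.
    """

    k_u: float = 0.462
    k_th: float = 0.604
    k_k: float = 0.0417
    occupancy: float = 0.20
    sv_per_gy: float = 0.7e-3

    def __post_init__(self) -> None:
        for name in ("k_u", "k_th", "k_k", "occupancy", "sv_per_gy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"dose coefficient {name} must be > 0")

    @property
    def hours_per_year(self) -> float:
        """Annual outdoor exposure time, h/y (0.20 × 24 × 365.25 = 1753.2)."""
        return self.occupancy * 24.0 * 365.25

    @property
    def dose_to_effective(self) -> float:
        """µSv/y of effective dose per nGy/h of absorbed dose rate."""
        return self.hours_per_year * self.sv_per_gy


class TableFormatError(ValueError):
    """A required column is missing or the table cannot be interpreted."""


def data_path(name: str) -> Path:
    """Path to a bundled data file."""
    return Path(str(resources.files("terradose").joinpath("data", name)))


def read_activity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[ActivityRecord]:
    """Read a per-sample activity table from CSV.

    ``dialect`` maps the logical field names (``sample_id``, ``c_u``,
    ``c_th``, ``c_k``, ``u_u``, ``u_th``, ``u_k``) onto the file's column
    names; missing uncertainty columns yield zero uncertainties.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    frame = pd.read_csv(path)
    for key in _REQUIRED:
        if dialect[key] not in frame.columns:
            raise TableFormatError(
                f"missing required column {dialect[key]!r} (field {key})"
            )
    records = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sid = str(row[dialect["sample_id"]])
        if sid in seen:
            raise TableFormatError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        kwargs = {"sample_id": sid}
        for key in ("c_u", "c_th", "c_k"):
            kwargs[key] = float(row[dialect[key]])
        for key in _UNCERTAINTY:
            col = dialect[key]
            kwargs[key] = float(row[col]) if col in frame.columns else 0.0
        records.append(ActivityRecord(**kwargs))
    return records


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in the default dialect."""
    rows = [
        {
            "sample_id": r.sample_id,
            "u_bqkg": r.c_u,
            "th_bqkg": r.c_th,
            "k_bqkg": r.c_k,
            "u_sd": r.u_u,
            "th_sd": r.u_th,
            "k_sd": r.u_k,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_activity_table(records: Sequence[ActivityRecord], path: str | Path) -> None:
    """Write records back to CSV in the default dialect."""
    records_to_frame(records).to_csv(path, index=False)


def summarize_table(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Per-radionuclide minimum, maximum and mean over a table.

    Returns a DataFrame indexed by ``min``/``max``/``mean`` with columns
    ``c_u``, ``c_th``, ``c_k``.
    """
    if not records:
        raise ValueError("cannot summarize an empty table")
    frame = pd.DataFrame(
        {
            "c_u": [r.c_u for r in records],
            "c_th": [r.c_th for r in records],
            "c_k": [r.c_k for r in records],
        }
    )
    return frame.agg(["min", "max", "mean"])


def load_survey_table() -> list[ActivityRecord]:
    """The bundled 26-sample soil survey (coastal Tano basin, Ghana)."""
    return read_activity_table(data_path("table1_activities.csv"))


def _significant(x: float, sig: int = 3) -> str:
    if x == 0:
        return "0"
    return f"{x:.{sig}g}"


def write_report(
    dose_results: Sequence,
    hazard_results: Sequence,
    path: str | Path,
    fmt: str = "csv",
) -> Path:
    """Write a combined dose/hazard report with min/max/mean footer rows.

    ``fmt`` is ``"csv"`` or ``"text"`` (aligned plain text, 3 significant
    figures).  Dose and hazard results must align by ``sample_id``.
    """
    if not dose_results or not hazard_results:
        raise ValueError("cannot write a report for empty results")
    dose_ids = [d.sample_id for d in dose_results]
    haz_ids = [h.sample_id for h in hazard_results]
    if dose_ids != haz_ids:
        raise ValueError("dose and hazard results are not aligned by sample_id")

    frame = pd.DataFrame(
        {
            "sample_id": dose_ids,
            "absorbed_dose_ngy_h": [d.absorbed_dose for d in dose_results],
            "dose_sd": [d.dose_uncertainty for d in dose_results],
            "effective_dose_usv_y": [d.effective_dose for d in dose_results],
            "effective_dose_sd": [d.effective_dose_uncertainty for d in dose_results],
            "pct_u": [d.contribution_u for d in dose_results],
            "pct_th": [d.contribution_th for d in dose_results],
            "pct_k": [d.contribution_k for d in dose_results],
            "ra_eq_bq_kg": [h.ra_eq for h in hazard_results],
            "elcr": [h.elcr for h in hazard_results],
            "h_in": [h.h_in for h in hazard_results],
            "h_ex": [h.h_ex for h in hazard_results],
        }
    )
    numeric = frame.columns.drop("sample_id")
    footer = frame[numeric].agg(["min", "max", "mean"])
    footer.insert(0, "sample_id", ["Minimum", "Maximum", "Mean"])
    full = pd.concat([frame, footer], ignore_index=True)

    path = Path(path)
    if fmt == "csv":
        full.to_csv(path, index=False)
    elif fmt == "text":
        shown = full.copy()
        for col in numeric:
            shown[col] = shown[col].map(_significant)
        path.write_text(shown.to_string(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
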