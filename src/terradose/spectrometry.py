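"""Specific-activity quantification from HPGe gamma-line net counts.

A radionuclide's specific activity follows from the background-subtracted
photopeak counts N of one of its gamma lines:

    A_sp = N · exp(λ_p · T_d) / (p · T_c · η · m)        [Bq/kg]

where p is the gamma emission probability, T_c the live counting time (s),
η the absolute full-energy-peak efficiency at that energy, m the sample
mass (kg), and exp(λ_p·T_d) corrects for parent decay over the delay T_d
between sampling and counting.  For the primordial parents (²³⁸U, ²³²Th,
⁴⁰K) this correction is indistinguishable from 1 on laboratory timescales.

Under secular equilibrium, progeny lines (²¹⁴Pb/²¹⁴Bi for the ²³⁸U series;
²¹²Pb/²⁰⁸Tl/²²⁸Ac for ²³²Th) stand in for the parent, and per-line
activities within a series are combined by an unweighted mean.

Emission probabilities are not measured here; the bundled registry carries
standard evaluated decay-data values expressed per parent decay (the
Tl-208 lines already include the 35.9 % ²¹²Bi branching).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import data_path

__all__ = [
    "GammaLine",
    "CountingMeasurement",
    "specific_activity",
    "series_activity",
    "default_line_registry",
    "SECONDS_PER_YEAR",
]

#: Julian year in seconds; converts decay constants in 1/y to 1/s.
SECONDS_PER_YEAR = 365.25 * 86400.0

_SERIES = ("U-238", "Th-232", "K-40")


@dataclass(frozen=True)
class GammaLine:
    """One photopeak used for quantification."""

    nuclide: str
    energy_kev: float
    emission_probability: float
    series: str

    def __post_init__(self) -> None:
        if not 0 < self.emission_probability <= 1:
            raise ValueError("emission probability must be in (0, 1]")
        if self.energy_kev <= 0:
            raise ValueError("gamma energy must be positive")
        if self.series not in _SERIES:
            raise ValueError(f"unrecognized series {self.series!r}")


@dataclass(frozen=True)
class CountingMeasurement:
    """Net counts in one photopeak together with the counting geometry."""

    line: GammaLine
    net_counts: float
    live_time: float = 36000.0  # s
    efficiency: float = 0.05
    mass: float = 1.0  # kg
    delay_time: float = 0.0  # s
    parent_decay_constant: float = 0.0  # 1/s

    def __post_init__(self) -> None:
        if self.net_counts < 0:
            raise ValueError("net counts must be >= 0")
        if self.live_time <= 0 or self.efficiency <= 0 or self.mass <= 0:
            raise ValueError("live time, efficiency and mass must be > 0")
        if not self.efficiency < 1:
            raise ValueError("absolute efficiency must be < 1")
        if self.delay_time < 0:
            raise ValueError("delay time must be >= 0")


def specific_activity(meas: CountingMeasurement) -> tuple[float, float]:
    """Specific activity (Bq/kg) and its Poisson counting uncertainty.

    The relative counting uncertainty is 1/√N; zero counts give zero
    activity with zero uncertainty.
    """
    line = meas.line
    decay_correction = math.exp(meas.parent_decay_constant * meas.delay_time)
    denom = line.emission_probability * meas.live_time * meas.efficiency * meas.mass
    activity = meas.net_counts * decay_correction / denom
    sigma = activity / math.sqrt(meas.net_counts) if meas.net_counts > 0 else 0.0
    return activity, sigma


def series_activity(
    measurements: Sequence[CountingMeasurement],
) -> tuple[float, float]:
    """Combine per-line activities of one decay series.

    Returns the unweighted arithmetic mean of the per-line specific
    activities; the quoted uncertainty is the linear mean of the per-line
    counting uncertainties.
    """
    if not measurements:
        raise ValueError("no measurements to combine")
    series = {m.line.series for m in measurements}
    if len(series) > 1:
        raise ValueError(f"measurements mix decay series: {sorted(series)}")
    pairs = [specific_activity(m) for m in measurements]
    n = len(pairs)
    return sum(a for a, _ in pairs) / n, sum(s for _, s in pairs) / n


def default_line_registry() -> list[GammaLine]:
    """The bundled gamma-line registry.

    U-238 series: 295.2 and 351.93 keV (²¹⁴Pb), 609.31 and 1764.49 keV
    (²¹⁴Bi); Th-232 series: 238.63 keV (²¹²Pb), 583.19 and 2614.53 keV
    (²⁰⁸Tl), 911.21 keV (²²⁸Ac); ⁴⁰K: its single 1460.83 keV line.
    """
    frame = pd.read_csv(data_path("gamma_lines.csv"))
    return [
        GammaLine(
            nuclide=row.nuclide,
            energy_kev=float(row.energy_kev),
            emission_probability=float(row.emission_probability),
            series=row.series,
        )
        for row in frame.itertuples()
    ]
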