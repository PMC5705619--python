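"""Radionuclide decay: exact exponential law and a quartic approximant.

Activity decays as A(t) = A₀·e^(−λt) with λ = ln2 / half-life.  Because
the primordial half-lives (⁴⁰K 1.25×10⁹ y is the shortest) dwarf any
policy horizon, e^(−λt) is ≈ 1 for centuries; visualising or tabulating
long-horizon behaviour is what the simulation routines are for.

Alongside the exact law, the decay factor e^(−z) (z = λt) is approximated
by the degree-4 Newton forward-difference interpolation polynomial on the
equispaced nodes z ∈ {0, 1, 2, 3, 4}:

    P(z) = 0.0067·z⁴ − 0.0820·z³ + 0.3993·z² − 0.9560·z + 1   (4 d.p.)

built from the forward-difference table of y_i = e^(−z_i) with Newton
coefficients a_k = Δᵏy₀ / (k!·hᵏ).  The interpolant is exact at its nodes
and accurate to ≈6×10⁻³ on [0, 4]; it is refused outside the node span by
default because the quartic diverges there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Radionuclide",
    "U238",
    "TH232",
    "K40",
    "DEFAULT_NUCLIDES",
    "NewtonInterpolant",
    "build_interpolant",
    "decay_exact",
    "decay_approx",
    "DecayCurve",
    "simulate_table",
    "approximation_error",
]


@dataclass(frozen=True)
class Radionuclide:
    """A single-exponential decaying species."""

    name: str
    half_life: float  # years

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half-life must be > 0")

    @property
    def decay_constant(self) -> float:
        """λ = ln2 / half-life, 1/years."""
        return math.log(2.0) / self.half_life


U238 = Radionuclide("U-238", 4e9)
TH232 = Radionuclide("Th-232", 1.4e10)
K40 = Radionuclide("K-40", 1.25e9)

DEFAULT_NUCLIDES: tuple[Radionuclide, ...] = (U238, TH232, K40)


def decay_exact(a0: float, nuc: Radionuclide, t: float | np.ndarray):
    """Activity after time t (years) under the exact exponential law."""
    if a0 < 0:
        raise ValueError("initial activity must be >= 0")
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be >= 0")
    return a0 * np.exp(-nuc.decay_constant * t)


@dataclass(frozen=True)
class NewtonInterpolant:
    """Degree-4 forward-difference interpolant of e^(−z) on equispaced nodes.

    ``newton_coeffs`` are a₀…a₄ of the Newton form
    P(z) = a₀ + a₁(z−z₀) + … + a₄(z−z₀)(z−z₁)(z−z₂)(z−z₃);
    ``power_coeffs`` are (e, d, c, b, a) of the expanded quartic in
    ascending powers of z.
    """

    nodes: tuple[float, ...]
    step: float
    node_values: tuple[float, ...]
    newton_coeffs: tuple[float, ...]
    power_coeffs: tuple[float, ...]  # ascending: constant … z⁴

    @property
    def span(self) -> tuple[float, float]:
        return self.nodes[0], self.nodes[-1]

    def __call__(self, z: float | np.ndarray):
        """Evaluate the Newton form (numerically preferred)."""
        z = np.asarray(z, dtype=float)
        acc = np.full_like(z, self.newton_coeffs[0])
        basis = np.ones_like(z)
        for k in range(1, len(self.nodes)):
            basis = basis * (z - self.nodes[k - 1])
            acc = acc + self.newton_coeffs[k] * basis
        return acc if acc.shape else float(acc)

    def evaluate_power(self, z: float | np.ndarray):
        """Evaluate the expanded power-basis quartic (Horner)."""
        z = np.asarray(z, dtype=float)
        acc = np.zeros_like(z)
        for c in reversed(self.power_coeffs):
            acc = acc * z + c
        return acc if acc.shape else float(acc)


def build_interpolant(nodes: Sequence[float] | None = None) -> NewtonInterpolant:
    """Construct the interpolant of e^(−z) on 5 equispaced nodes.

    Defaults to z ∈ {0, 1, 2, 3, 4} (h = 1), for which the expanded
    coefficients round to (1, −0.9560, 0.3993, −0.0820, 0.0067).
    """
    nodes = np.asarray([0.0, 1.0, 2.0, 3.0, 4.0] if nodes is None else nodes, float)
    if nodes.shape != (5,):
        raise ValueError("exactly 5 nodes are required")
    steps = np.diff(nodes)
    h = steps[0]
    if h <= 0 or not np.allclose(steps, h, rtol=1e-12, atol=1e-12):
        raise ValueError("nodes must be strictly increasing and equispaced")

    y = np.exp(-nodes)
    diffs = y.copy()
    newton = [y[0]]
    for k in range(1, 5):
        diffs = np.diff(diffs)
        newton.append(diffs[0] / (math.factorial(k) * h**k))

    # Expand the Newton form into ascending power-basis coefficients.
    power = np.zeros(5)
    power[0] = newton[0]
    basis = np.array([1.0])
    for k in range(1, 5):
        basis = np.convolve(basis, [-nodes[k - 1], 1.0])
        power[: k + 1] += newton[k] * basis
    return NewtonInterpolant(
        nodes=tuple(nodes),
        step=float(h),
        node_values=tuple(y),
        newton_coeffs=tuple(newton),
        power_coeffs=tuple(power),
    )


def decay_approx(
    a0: float,
    nuc: Radionuclide,
    t: float | np.ndarray,
    interp: NewtonInterpolant | None = None,
    allow_extrapolation: bool = False,
) -> float | np.ndarray:
    """Activity after time t using the quartic decay-factor approximant.

    Raises outside the interpolant's node span unless
    ``allow_extrapolation`` is set (the quartic diverges beyond z₄).
    """
    interp = interp or build_interpolant()
    z = nuc.decay_constant * np.asarray(t, dtype=float)
    lo, hi = interp.span
    if not allow_extrapolation and (np.any(z < lo) or np.any(z > hi)):
        raise ValueError(
            f"z = λt leaves the interpolation span [{lo}, {hi}]; "
            "pass allow_extrapolation=True to override"
        )
    out = a0 * interp(z)
    return out if np.asarray(out).shape else float(out)


@dataclass(frozen=True)
class DecayCurve:
    """Exact and approximate activity tracks for one radionuclide."""

    radionuclide: Radionuclide
    initial_activity: float
    times: np.ndarray  # years
    exact_activity: np.ndarray
    approx_activity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nuclide": self.radionuclide.name,
                "time_y": self.times,
                "activity_exact": self.exact_activity,
                "activity_approx": self.approx_activity,
            }
        )


def simulate_table(
    initial_activities: dict[str, float],
    nuclides: Sequence[Radionuclide] = DEFAULT_NUCLIDES,
    horizon: float = 100.0,
    n_points: int = 101,
    interp: NewtonInterpolant | None = None,
) -> list[DecayCurve]:
    """Decay each nuclide's initial activity over a uniform time grid.

    ``initial_activities`` maps nuclide name → A₀ (Bq/kg), typically the
    survey-mean activities.  Both the exact exponential and the quartic
    approximant are tracked (the approximant extrapolates freely here so
    curves can be drawn over any horizon; its divergence for z > 4 is the
    point being illustrated).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    interp = interp or build_interpolant()
    times = np.linspace(0.0, horizon, n_points)
    curves = []
    for nuc in nuclides:
        a0 = initial_activities[nuc.name]
        curves.append(
            DecayCurve(
                radionuclide=nuc,
                initial_activity=a0,
                times=times,
                exact_activity=decay_exact(a0, nuc, times),
                approx_activity=np.asarray(
                    decay_approx(a0, nuc, times, interp, allow_extrapolation=True)
                ),
            )
        )
    return curves


def approximation_error(
    interp: NewtonInterpolant | None = None, grid_size: int = 1000
) -> float:
    """Dense-grid max |P(z) − e^(−z)| over the interpolant's node span."""
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    interp = interp or build_interpolant()
    z = np.linspace(*interp.span, grid_size)
    return float(np.max(np.abs(interp(z) - np.exp(-z))))
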