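"""Hydration-number bookkeeping from THz relaxation strengths.

A water molecule counts as "hydrated" when its collective (slow) rotational
relaxation is retarded out of the THz window by the solute.  The fitted
relaxation strengths are converted to molecular populations through the
Kirkwood correlation factor g of each mode (g1 = 2.9 for the slow mode,
g2 = 1.0 for the fast mode), and the hydration number per solute is the
deficit of the solution's per-water-volume populations relative to pure
water:

    n_hyd = alpha * [ 1 - (de1_sol/g1 + de2_sol/g2) / (de1_wat/g1 + de2_wat/g2) ]

where alpha is the total number of waters per solute molecule from the
composition.  Solution strengths are the per-water-volume values fitted under
the c-scaled dielectric model, so no further volume correction enters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dielectric import FitResult

__all__ = [
    "SolutionComposition",
    "KirkwoodFactors",
    "HydrationEstimate",
    "total_water_per_solute",
    "water_volume_fraction",
    "hydration_number",
    "hydration_series",
]

WATER_MOLAR_MASS = 18.015  # g/mol


@dataclass(frozen=True)
class SolutionComposition:
    """Composition of a binary solute/water solution.

    density_series maps temperature (degC) to solution density (g/mL),
    strictly increasing in temperature; densities are interpolated linearly
    inside the measured range and extrapolated linearly above it (densities
    above ~40 degC are typically not measured directly).
    partial_specific_volume is the solute's mL/g, used to convert mass
    fraction to volume fraction.
    """

    solute_wt_fraction: float
    solute_molar_mass: float
    water_molar_mass: float = WATER_MOLAR_MASS
    density_series: tuple[tuple[float, float], ...] = ()
    partial_specific_volume: float = 0.735

    def __post_init__(self):
        if not (0.0 < self.solute_wt_fraction < 1.0):
            raise ValueError("solute weight fraction must lie strictly in (0, 1)")
        if self.solute_molar_mass <= 0 or self.water_molar_mass <= 0:
            raise ValueError("molar masses must be positive")
        if self.partial_specific_volume <= 0:
            raise ValueError("partial specific volume must be positive")
        ts = [t for t, _ in self.density_series]
        if ts and not all(b > a for a, b in zip(ts, ts[1:])):
            raise ValueError("density_series temperatures must be strictly increasing")

    def density(self, temperature_c: float) -> float:
        """Solution density (g/mL) at a temperature, linear inter/extrapolation."""
        if not self.density_series:
            raise ValueError("composition has no density series")
        t = np.array([p[0] for p in self.density_series])
        rho = np.array([p[1] for p in self.density_series])
        if len(t) == 1:
            return float(rho[0])
        if temperature_c <= t[0]:
            i = 0
        elif temperature_c >= t[-1]:
            i = len(t) - 2
        else:
            i = int(np.searchsorted(t, temperature_c) - 1)
        slope = (rho[i + 1] - rho[i]) / (t[i + 1] - t[i])
        return float(rho[i] + slope * (temperature_c - t[i]))


@dataclass(frozen=True)
class KirkwoodFactors:
    """Dipole-correlation factors linking relaxation strengths to populations."""

    g1: float = 2.9  # slow (collective rotational) relaxation
    g2: float = 1.0  # fast (collisional) relaxation

    def __post_init__(self):
        if self.g1 <= 0 or self.g2 <= 0:
            raise ValueError("Kirkwood factors must be positive")


@dataclass
class HydrationEstimate:
    """Hydration waters per solute molecule with propagated 1-sigma error.

    ``negative_flag`` marks a (physically admissible but unusual) negative
    estimate, indicating faster-than-bulk water; the value is not clamped.
    """

    n_hyd: float
    n_err: float
    alpha: float
    temperature: float | None = None
    negative_flag: bool = field(default=False)

    def __post_init__(self):
        if self.n_hyd > self.alpha:
            raise ValueError("hydration number cannot exceed total waters per solute")
        if self.n_err < 0:
            raise ValueError("n_err must be >= 0")
        self.negative_flag = bool(self.n_hyd < 0)


def total_water_per_solute(comp: SolutionComposition) -> float:
    """Total waters per solute molecule, alpha = [(1-w)/M_w] / [w/M_s]."""
    w = comp.solute_wt_fraction
    return ((1.0 - w) / comp.water_molar_mass) / (w / comp.solute_molar_mass)


def water_volume_fraction(comp: SolutionComposition, temperature_c: float) -> float:
    """Water volume fraction c = 1 - w * rho_solution(T) * vbar_solute."""
    phi_solute = (comp.solute_wt_fraction * comp.density(temperature_c)
                  * comp.partial_specific_volume)
    c = 1.0 - phi_solute
    if not (0.0 < c < 1.0):
        raise ValueError(
            f"inconsistent composition: water volume fraction {c:.4f} outside (0, 1)")
    return c


def _mode_population(de1: float, de2: float, k: KirkwoodFactors) -> float:
    return de1 / k.g1 + de2 / k.g2


def hydration_number(water_fit: FitResult, solution_fit: FitResult,
                     alpha: float, c: float,
                     k: KirkwoodFactors = KirkwoodFactors(),
                     temperature: float | None = None) -> HydrationEstimate:
    """Kirkwood-corrected hydration count from paired water/solution fits.

    First-order error propagation uses the fit uncertainties of the free
    slow-relaxation strengths only (fixed parameters are treated as exact,
    mirroring error bars derived from the fitting errors of solution and
    water).
    """
    for fr, label in ((water_fit, "water"), (solution_fit, "solution")):
        if not fr.converged:
            raise ValueError(f"{label} fit did not converge")
    if abs(solution_fit.params.c - c) > 1e-9:
        raise ValueError("volume fraction c inconsistent with the solution fit")

    pw = water_fit.params
    ps = solution_fit.params
    s_wat = _mode_population(pw.delta_eps1, pw.delta_eps2, k)
    s_sol = _mode_population(ps.delta_eps1, ps.delta_eps2, k)
    if s_wat <= 0:
        raise ValueError("pure-water mode population must be positive")
    n = alpha * (1.0 - s_sol / s_wat)

    # delta method on the free strengths
    var = 0.0
    if "delta_eps1" in solution_fit.param_errors:
        var += (alpha / (k.g1 * s_wat) * solution_fit.param_errors["delta_eps1"]) ** 2
    if "delta_eps1" in water_fit.param_errors:
        var += (alpha * s_sol / (k.g1 * s_wat**2)
                * water_fit.param_errors["delta_eps1"]) ** 2
    if "delta_eps2" in water_fit.param_errors:
        var += (alpha * s_sol / (k.g2 * s_wat**2)
                * water_fit.param_errors["delta_eps2"]) ** 2

    return HydrationEstimate(n_hyd=float(n), n_err=float(np.sqrt(var)),
                             alpha=alpha, temperature=temperature)


def hydration_series(fits_by_temperature: dict[float, tuple[FitResult, FitResult]],
                     alpha: float, c_by_temperature: dict[float, float],
                     k: KirkwoodFactors = KirkwoodFactors()) -> list[HydrationEstimate]:
    """Per-temperature hydration estimates from matched water/solution fits.

    ``fits_by_temperature`` maps temperature (degC) to a
    (water_fit, solution_fit) pair.  No smoothing is applied across
    temperatures.
    """
    if not fits_by_temperature:
        raise ValueError("empty fit series")
    out = []
    for t in sorted(fits_by_temperature):
        pair = fits_by_temperature[t]
        if pair is None or pair[0] is None:
            raise ValueError(f"missing pure-water reference at {t} degC")
        if pair[1] is None:
            raise ValueError(f"missing solution fit at {t} degC")
        if t not in c_by_temperature:
            raise ValueError(f"missing volume fraction at {t} degC")
        out.append(hydration_number(pair[0], pair[1], alpha,
                                    c_by_temperature[t], k, temperature=t))
    return out
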