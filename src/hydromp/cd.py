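"""Circular dichroism: helix fraction and thermal denaturation midpoint.

The far-UV CD ellipticity at 222 nm tracks alpha-helix content.  The raw
machine reading theta (mdeg) is first normalized to the mean-residue molar
ellipticity

    [theta] = theta_mdeg / (10 * l * m * A)     [deg cm^2 dmol^-1]

with l the path length (cm), m the protein molar concentration (mol/L) and
A the number of residues.  The helix fraction is then the two-point linear
map between the reference ellipticities of a fully helical and a fully
disordered chain at 222 nm,

    f_H = ([theta]_222 - [theta]_coil) / ([theta]_helix - [theta]_coil).

The default reference constants ([theta]_helix = -32,640,
[theta]_coil = -2,340 deg cm^2 dmol^-1) follow the classic two-point
convention for helix estimation at 222 nm; they are configuration values
and results scale linearly with the choice.

The denaturation temperature is the crossing of f_H(T) with the midpoint of
the native and denatured plateaus, located by an ordinary least-squares line
through the transition region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CDSpectrum",
    "HelixSeries",
    "HelixConstants",
    "MidpointResult",
    "mean_residue_ellipticity",
    "helix_fraction",
    "extract_mre_222",
    "helix_series_from_spectra",
    "denaturation_midpoint",
]


@dataclass(frozen=True)
class HelixConstants:
    """Reference mean-residue ellipticities at 222 nm, deg cm^2 dmol^-1."""

    theta_helix: float = -32640.0
    theta_coil: float = -2340.0

    def __post_init__(self):
        if self.theta_helix == self.theta_coil:
            raise ValueError("reference ellipticities must differ")


@dataclass
class CDSpectrum:
    """Ellipticity (mdeg) vs wavelength (nm) with cell/sample metadata."""

    wavelength: np.ndarray
    ellipticity: np.ndarray
    path_length: float = 1.0        # cm
    molar_concentration: float = 2.05e-7  # mol/L
    n_residues: int = 583
    temperature: float | None = None

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelength.shape != self.ellipticity.shape or self.wavelength.ndim != 1:
            raise ValueError("wavelength and ellipticity must be equal-length 1-D arrays")
        if self.path_length <= 0 or self.molar_concentration <= 0:
            raise ValueError("path length and concentration must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


@dataclass
class HelixSeries:
    """Helix fraction vs temperature with reference plateaus.

    out_of_range_flags marks f_H values outside [0, 1]; values are kept
    unclamped so the midpoint regression stays unbiased.
    """

    temperature: np.ndarray
    f_H: np.ndarray
    f_native: float = 0.66
    f_denatured: float = 0.16
    T_mid: float | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f_H = np.asarray(self.f_H, dtype=float)
        if self.temperature.shape != self.f_H.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and f_H must be equal-length 1-D arrays")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def out_of_range_flags(self) -> np.ndarray:
        return (self.f_H < 0) | (self.f_H > 1)

    @property
    def threshold(self) -> float:
        return 0.5 * (self.f_native + self.f_denatured)


@dataclass
class MidpointResult:
    """Denaturation midpoint from the linear crossing construction."""

    T_mid: float
    threshold: float
    slope: float
    intercept: float
    extrapolated: bool


def mean_residue_ellipticity(theta_mdeg, path_length_cm: float,
                             molar_concentration: float, n_residues: int):
    """[theta] = theta_mdeg / (10 * l * m * A), in deg cm^2 dmol^-1."""
    denom = 10.0 * path_length_cm * molar_concentration * n_residues
    if denom == 0:
        raise ZeroDivisionError("zero denominator in mean-residue ellipticity")
    return np.asarray(theta_mdeg, dtype=float) / denom


def helix_fraction(mre_222, constants: HelixConstants = HelixConstants()):
    """Helix fraction from [theta]222; values outside [0,1] are NOT clamped."""
    span = constants.theta_helix - constants.theta_coil
    return (np.asarray(mre_222, dtype=float) - constants.theta_coil) / span


def extract_mre_222(spec: CDSpectrum, quadratic: bool = False) -> float:
    """[theta] at 222 nm by nearest grid point (optionally local quadratic)."""
    wl = spec.wavelength
    if not (wl.min() <= 222.0 <= wl.max()):
        raise ValueError("spectrum does not cover 222 nm")
    mre = mean_residue_ellipticity(spec.ellipticity, spec.path_length,
                                   spec.molar_concentration, spec.n_residues)
    i = int(np.argmin(np.abs(wl - 222.0)))
    if not quadratic:
        return float(mre[i])
    i0 = min(max(i, 1), len(wl) - 2)
    coef = np.polyfit(wl[i0 - 1:i0 + 2], mre[i0 - 1:i0 + 2], 2)
    return float(np.polyval(coef, 222.0))


def helix_series_from_spectra(spectra: list[CDSpectrum],
                              constants: HelixConstants = HelixConstants(),
                              f_native: float = 0.66,
                              f_denatured: float = 0.16) -> HelixSeries:
    """Per-temperature helix fractions from a set of CD spectra."""
    if not spectra:
        raise ValueError("empty spectrum series")
    pairs = sorted(
        ((s.temperature, helix_fraction(extract_mre_222(s), constants))
         for s in spectra),
        key=lambda p: p[0])
    t = np.array([p[0] for p in pairs], dtype=float)
    f = np.array([p[1] for p in pairs], dtype=float)
    return HelixSeries(t, f, f_native=f_native, f_denatured=f_denatured)


def denaturation_midpoint(series: HelixSeries,
                          fit_range: tuple[float, float] = (45.0, 85.0)
                          ) -> MidpointResult:
    """Midpoint temperature where the fitted f_H(T) line crosses the threshold.

    The threshold is (f_native + f_denatured)/2; the line is an ordinary
    least-squares fit through the points inside ``fit_range``.  A crossing
    outside the range is returned with ``extrapolated=True``.
    """
    t_lo, t_hi = fit_range
    m = (series.temperature >= t_lo) & (series.temperature <= t_hi)
    if m.sum() < 3:
        raise ValueError("need at least 3 points inside the fit range")
    T, f = series.temperature[m], series.f_H[m]
    slope, intercept = np.polyfit(T, f, 1)
    if abs(slope) < 1e-12:
        raise ValueError("no transition in range: zero slope")
    thr = series.threshold
    t_mid = (thr - intercept) / slope
    series.T_mid = float(t_mid)
    return MidpointResult(
        T_mid=float(t_mid), threshold=float(thr),
        slope=float(slope), intercept=float(intercept),
        extrapolated=not (t_lo <= t_mid <= t_hi),
    )
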