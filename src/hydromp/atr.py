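"""Attenuated-total-reflection (ATR) measurement optics.

A high-index prism (silicon, n = 3.4) under total internal reflection probes
the sample through the evanescent field at the prism/sample interface.  This
module provides the two-medium Fresnel amplitude coefficient for the
configured polarization, the evanescent penetration depth, and the numerical
inversion from a measured reflection coefficient back to the sample's complex
permittivity, which closes the simulate-then-analyze loop for synthetic THz
experiments.

Sample permittivity follows the package's loss-positive convention
eps = eps' + i*eps'' (eps'' >= 0 for passive media).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

__all__ = [
    "ATRGeometry",
    "fresnel_reflectance",
    "penetration_depth",
    "invert_reflectance",
]

_C_UM_THZ = 299.792458  # vacuum wavelength in um at 1 THz


@dataclass(frozen=True)
class ATRGeometry:
    """Prism/sample interface geometry."""

    prism_index: float = 3.4
    incidence_angle: float = 45.0  # degrees
    polarization: str = "p"

    def __post_init__(self):
        if self.prism_index <= 1.0:
            raise ValueError("prism index must exceed 1")
        if not (0.0 < self.incidence_angle < 90.0):
            raise ValueError("incidence angle must lie in (0, 90) degrees")
        if self.polarization not in ("p", "s"):
            raise ValueError("polarization must be 'p' or 's'")


def _kz(eps: complex, kx2: float) -> complex:
    """Normal wavevector component (units of k0) with decaying-branch choice."""
    kz = np.sqrt(complex(eps) - kx2)
    if kz.imag < 0:
        kz = -kz
    return kz


def _fresnel(geom: ATRGeometry, eps_sample: complex) -> complex:
    n1 = geom.prism_index
    theta = np.deg2rad(geom.incidence_angle)
    kx2 = (n1 * np.sin(theta)) ** 2
    eps1 = n1**2
    kz1 = _kz(eps1, kx2)
    kz2 = _kz(eps_sample, kx2)
    if geom.polarization == "s":
        r = (kz1 - kz2) / (kz1 + kz2)
    else:
        r = (eps1 * kz2 - eps_sample * kz1) / (eps1 * kz2 + eps_sample * kz1)
    return complex(r)


def fresnel_reflectance(geom: ATRGeometry, eps_sample: complex,
                        freq_thz: float) -> complex:
    """Amplitude reflection coefficient at the prism/sample interface.

    Sign convention: at normal incidence r -> (n1 - n2)/(n1 + n2) for both
    polarizations.  |r| <= 1 for passive (loss-positive) samples.  The
    frequency does not enter the two-medium coefficient (no dispersion is
    applied here); it is accepted for interface symmetry with the
    frequency-dependent permittivity models feeding this function.
    """
    eps_sample = complex(eps_sample)
    if not np.isfinite(eps_sample.real) or not np.isfinite(eps_sample.imag):
        raise ValueError("eps_sample must be finite")
    if eps_sample.imag < -1e-12:
        raise ValueError("eps_sample violates the loss-positive convention (eps'' < 0)")
    if freq_thz <= 0:
        raise ValueError("frequency must be positive")
    return _fresnel(geom, eps_sample)


def penetration_depth(geom: ATRGeometry, eps_sample: complex, freq_thz: float,
                      convention: str = "intensity") -> float:
    """Evanescent 1/e penetration depth into the sample, in micrometres.

    convention="field" returns the amplitude decay length
    d = lambda0 / (2*pi*sqrt(n1^2 sin^2(theta) - n2^2)) with
    n2 = Re sqrt(eps_sample); "intensity" (default) returns half of that,
    the 1/e depth of the evanescent intensity.
    """
    if convention not in ("field", "intensity"):
        raise ValueError("convention must be 'field' or 'intensity'")
    if freq_thz <= 0:
        raise ValueError("frequency must be positive")
    n1 = geom.prism_index
    theta = np.deg2rad(geom.incidence_angle)
    n2 = np.sqrt(complex(eps_sample)).real
    arg = (n1 * np.sin(theta)) ** 2 - n2**2
    if arg <= 0:
        raise ValueError(
            "below the critical angle: no evanescent decay "
            f"(n1 sin(theta) = {n1 * np.sin(theta):.3f} <= n2 = {n2:.3f})")
    lam0 = _C_UM_THZ / freq_thz
    d_field = lam0 / (2.0 * np.pi * np.sqrt(arg))
    return float(d_field / 2.0 if convention == "intensity" else d_field)


def invert_reflectance(geom: ATRGeometry, r_measured: complex, freq_thz: float,
                       eps_init: complex, tol: float = 1e-12) -> complex:
    """Recover the sample permittivity from a measured reflection coefficient.

    Solves fresnel_reflectance(geom, eps, freq) = r_measured by root-finding
    on (Re eps, Im eps) starting from ``eps_init``.
    """
    r_measured = complex(r_measured)
    if abs(r_measured) > 1.0 + 1e-9:
        raise ValueError("|r| > 1 is unphysical for a passive sample")

    def fun(x):
        r = _fresnel(geom, complex(x[0], x[1]))
        return [r.real - r_measured.real, r.imag - r_measured.imag]

    x0 = [eps_init.real, eps_init.imag]
    for _ in range(2):  # restart once to polish past hybr's trust region
        sol = root(fun, x0, method="hybr", options={"xtol": tol})
        x0 = list(sol.x)
    eps = complex(sol.x[0], sol.x[1])
    if abs(eps.imag) < 1e-10:
        eps = complex(eps.real, abs(eps.imag))
    resid = abs(_fresnel(geom, eps) - r_measured)
    if resid > 1e-10:
        raise RuntimeError(
            f"reflectance inversion did not converge (residual {resid:.3e})")
    return eps
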