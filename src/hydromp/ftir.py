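"""OH-stretch band decomposition into hydrogen-bond populations.

The OH stretching region of liquid water (2800-3800 cm^-1) is modelled as
three Gaussian components whose centers report the hydrogen-bond state of
the vibrating OH group: ~3295 cm^-1 for strongly hydrogen-bonded OH (near
four bonds per molecule), ~3460 cm^-1 for intermediate bonding (2-3 bonds),
and ~3590 cm^-1 for weak or absent bonding.  The fractional integrated
intensity of each component tracks the hydrogen-bond population as a
function of temperature.  A linear baseline is fitted simultaneously with
the Gaussians; the protein amide/CH region below ~3000 cm^-1 is excluded by
the default fit window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IRSpectrum",
    "GaussianBand",
    "BandFractions",
    "OHFitConfig",
    "DEFAULT_CENTERS",
    "fit_oh_band",
    "fractions_series",
]

#: Component centers in cm^-1: strong / intermediate / weak hydrogen bonding.
DEFAULT_CENTERS = (3295.0, 3460.0, 3590.0)


@dataclass
class IRSpectrum:
    """Absorbance vs wavenumber (cm^-1, increasing) at one temperature."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    temperature: float | None = None

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape or self.wavenumber.ndim != 1:
            raise ValueError("wavenumber and absorbance must be equal-length 1-D arrays")
        if not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass(frozen=True)
class GaussianBand:
    """One fitted component; width is the Gaussian standard deviation."""

    center: float
    width: float
    area: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def amplitude(self) -> float:
        return self.area / (self.width * np.sqrt(2.0 * np.pi))


@dataclass
class BandFractions:
    """Fractional band intensities, ordered strong / intermediate / weak.

    Fractions sum to one by construction; errors are delta-method 1-sigma
    values from the fit covariance.  degenerate_flags marks components that
    collapsed (vanishing area or centers closer than 10 cm^-1).
    """

    f_strong: float
    f_intermediate: float
    f_weak: float
    errors: tuple[float, float, float] = (0.0, 0.0, 0.0)
    degenerate_flags: tuple[bool, bool, bool] = (False, False, False)
    temperature: float | None = None

    def __post_init__(self):
        fs = self.as_tuple()
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_strong, self.f_intermediate, self.f_weak)


@dataclass(frozen=True)
class OHFitConfig:
    """Three-Gaussian fit options.

    centers are starting values; center_bound is the allowed drift (cm^-1)
    around each start (prevents component label swapping while allowing
    temperature shifts); free_centers=False pins the centers entirely.
    """

    window: tuple[float, float] = (3000.0, 3800.0)
    centers: tuple[float, float, float] = DEFAULT_CENTERS
    center_bound: float = 40.0
    width_init: tuple[float, float, float] = (115.0, 85.0, 55.0)
    width_bounds: tuple[float, float] = (10.0, 250.0)
    free_centers: bool = True
    degenerate_sep: float = 10.0


def _model(x, params):
    """baseline (a + b*x) + three amplitude-form Gaussians."""
    a, b = params[0], params[1]
    y = a + b * x
    for i in range(3):
        amp, cen, wid = params[2 + 3 * i: 5 + 3 * i]
        y = y + amp * np.exp(-0.5 * ((x - cen) / wid) ** 2)
    return y


def fit_oh_band(spec: IRSpectrum,
                config: OHFitConfig = OHFitConfig()
                ) -> tuple[tuple[GaussianBand, GaussianBand, GaussianBand], BandFractions]:
    """Decompose one OH band into three Gaussians plus a linear baseline.

    Returns the bands sorted by ascending center and the fractional
    integrated intensities f_i = area_i / sum(areas) with delta-method
    errors from the fit covariance.
    """
    lo, hi = config.window
    if spec.wavenumber.min() > lo or spec.wavenumber.max() < hi:
        raise ValueError("spectrum does not cover the fit window")
    m = (spec.wavenumber >= lo) & (spec.wavenumber <= hi)
    if m.sum() < 12:
        raise ValueError("too few points inside the fit window")
    x, y = spec.wavenumber[m], spec.absorbance[m]

    scale = max(float(np.ptp(y)), 1e-12)
    p0 = [float(y.min()), 0.0]
    for c0, w0 in zip(config.centers, config.width_init):
        p0 += [0.5 * scale, c0, w0]
    lower = [-np.inf, -np.inf]
    upper = [np.inf, np.inf]
    for c0 in config.centers:
        cb = config.center_bound if config.free_centers else 1e-9
        lower += [0.0, c0 - cb, config.width_bounds[0]]
        upper += [np.inf, c0 + cb, config.width_bounds[1]]

    # Spectral noise is predominantly multiplicative, so fit in relative
    # terms: weight each residual by 1/|y| (floored well above zero to keep
    # near-baseline points from dominating).
    w = 1.0 / np.maximum(np.abs(y), 0.05 * scale)
    sol = least_squares(lambda p: w * (_model(x, p) - y), p0,
                        bounds=(lower, upper), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"OH band fit did not converge: {sol.message}")

    amps = sol.x[2::3]
    cens = sol.x[3::3]
    wids = sol.x[4::3]
    order = np.argsort(cens)
    amps, cens, wids = amps[order], cens[order], wids[order]
    areas = amps * wids * np.sqrt(2.0 * np.pi)
    total = float(areas.sum())
    if total <= 0:
        raise RuntimeError("degenerate fit: total band area is zero")
    fracs = areas / total

    # delta method: fractions as functions of (amp_i, wid_i)
    dof = max(len(x) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    # Equilibrate before inverting: raw JTJ mixes scales (centers ~3e3,
    # amplitudes ~1e-1) and a plain pinv truncates the genuinely flat
    # overlap directions, understating the errors.
    d = np.sqrt(np.diag(jtj))
    d[d == 0] = 1.0
    try:
        corr_inv = np.linalg.inv(jtj / np.outer(d, d))
        cov = s2 * corr_inv / np.outer(d, d)
    except np.linalg.LinAlgError:
        cov = np.full((len(sol.x), len(sol.x)), np.nan)
    # gradient of f_i wrt the 11 raw parameters (area_j = amp_j*wid_j*sqrt(2pi))
    errs = []
    raw_order = list(order)
    for i in range(3):
        g = np.zeros(len(sol.x))
        for j in range(3):
            jraw = raw_order[j]
            dfi_daj = ((1.0 if i == j else 0.0) - fracs[i]) / total
            g[2 + 3 * jraw] = dfi_daj * wids[j] * np.sqrt(2.0 * np.pi)
            g[4 + 3 * jraw] = dfi_daj * amps[j] * np.sqrt(2.0 * np.pi)
        errs.append(float(np.sqrt(max(g @ cov @ g, 0.0))))

    sep_flags = [False, False, False]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(cens[i] - cens[j]) < config.degenerate_sep:
                sep_flags[i] = sep_flags[j] = True
    flags = tuple(bool(sep_flags[i] or fracs[i] < 1e-6) for i in range(3))

    bands = tuple(GaussianBand(float(c), float(w), float(a))
                  for c, w, a in zip(cens, wids, areas))
    fractions = BandFractions(
        f_strong=float(fracs[0]), f_intermediate=float(fracs[1]),
        f_weak=float(fracs[2]), errors=tuple(errs),
        degenerate_flags=flags, temperature=spec.temperature,
    )
    return bands, fractions


def fractions_series(spectra: list[IRSpectrum],
                     config: OHFitConfig = OHFitConfig(),
                     warm_start: bool = True) -> list[BandFractions]:
    """Independent three-Gaussian fits for a temperature series.

    With ``warm_start`` each fit starts from the previous temperature's
    fitted centers and widths (bounds still anchored at the configured
    centers).  Per-spectrum failures are re-raised with the temperature
    attached.
    """
    if not spectra:
        raise ValueError("empty spectrum series")
    out: list[BandFractions] = []
    cfg = config
    for spec in spectra:
        try:
            bands, fr = fit_oh_band(spec, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"OH band fit failed at T={spec.temperature} degC: {exc}") from exc
        out.append(fr)
        if warm_start:
            cfg = OHFitConfig(
                window=config.window,
                centers=config.centers,
                center_bound=config.center_bound,
                width_init=tuple(b.width for b in bands),
                width_bounds=config.width_bounds,
                free_centers=config.free_centers,
                degenerate_sep=config.degenerate_sep,
            )
    return out
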