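"""Three-mode complex dielectric model of liquid water in the THz band.

The permittivity of water between 0.3 and 2.5 THz is described by two Debye
relaxations (the collective rotational "slow" mode whose peak lies near
0.02 THz but whose high-frequency tail dominates the band, and the ~1 THz
collisional "fast" mode) plus a damped harmonic oscillator for the
intermolecular stretching vibration near 6 THz:

    eps(w) = eps_inf + c * [ de1/(1 + i w tau1)
                           + de2/(1 + i w tau2)
                           + A_s/(w_s^2 - w^2 + i gamma_s w) ]

with w = 2*pi*nu (nu in THz, tau in ps, so w*tau is dimensionless) and c the
volume fraction of water in the sample.  The package convention is
eps = eps' + i*eps'' with the loss eps'' positive; the expression above is
evaluated in the physics (e^{-iwt}) convention and the sign of the imaginary
part flipped once, here and nowhere else.

For a protein solution only the water contributes in this band (protein
absorption is negligible), so the solution spectrum is the water response
scaled by c with mode strengths altered by hydration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrequencyGrid",
    "DielectricSpectrum",
    "DielectricParameters",
    "FitResult",
    "FitConfig",
    "FIT_WINDOW_THZ",
    "eval_model",
    "fit_pure_water",
    "fit_solution",
    "restrict_to_window",
    "water_parameters",
]

#: Frequency window used for all fitting, in THz.
FIT_WINDOW_THZ = (0.3, 2.5)

_PARAM_NAMES = (
    "delta_eps1", "tau1", "delta_eps2", "tau2",
    "amp_s", "omega_s", "gamma_s", "eps_inf", "c",
)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of frequencies in THz."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if not np.all(v > 0):
            raise ValueError("frequencies must be positive (THz)")
        if not np.all(np.diff(v) > 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DielectricSpectrum:
    """Complex permittivity sampled on a frequency grid.

    ``sigma`` is the per-point 1-sigma uncertainty of ``eps_imag``
    (dimensionless); ``None`` when unknown (e.g. model evaluations).
    """

    grid: FrequencyGrid
    eps_real: np.ndarray
    eps_imag: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.grid)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if self.eps_real.shape != (n,) or self.eps_imag.shape != (n,):
            raise ValueError("eps_real/eps_imag must match grid length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != (n,):
                raise ValueError("sigma must match grid length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    @property
    def eps_complex(self) -> np.ndarray:
        """Permittivity as eps' + i*eps'' (loss positive)."""
        return self.eps_real + 1j * self.eps_imag


@dataclass(frozen=True)
class DielectricParameters:
    """Parameter vector of the three-mode model.

    Units: strengths and eps_inf dimensionless, relaxation times in ps,
    omega_s and gamma_s in rad/ps, amp_s in rad^2/ps^2 (so amp_s/omega_s^2 is
    the dimensionless oscillator strength), c the water volume fraction.
    """

    delta_eps1: float
    tau1: float
    delta_eps2: float
    tau2: float
    amp_s: float
    omega_s: float
    gamma_s: float
    eps_inf: float
    c: float = 1.0

    def __post_init__(self):
        vals = dataclasses.asdict(self)
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {k}={v!r}")
        for k in ("delta_eps1", "tau1", "delta_eps2", "tau2",
                  "amp_s", "omega_s", "gamma_s"):
            if vals[k] < 0:
                raise ValueError(f"parameter {k} must be >= 0")
        if not (0.0 < self.c <= 1.0):
            raise ValueError("water volume fraction c must lie in (0, 1]")
        if self.tau2 > 0 and self.tau1 > 0 and self.tau1 <= self.tau2:
            raise ValueError("slow relaxation must be slower: tau1 > tau2")

    def replace(self, **kw) -> "DielectricParameters":
        return dataclasses.replace(self, **kw)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_NAMES])

    @staticmethod
    def from_array(a: Sequence[float]) -> "DielectricParameters":
        return DielectricParameters(**dict(zip(_PARAM_NAMES, map(float, a))))

    def static_limit(self) -> float:
        """eps(nu -> 0) = eps_inf + c*(de1 + de2 + A_s/omega_s^2)."""
        return self.eps_inf + self.c * (
            self.delta_eps1 + self.delta_eps2 + self.amp_s / self.omega_s**2
        )


@dataclass
class FitResult:
    """Outcome of a dielectric fit."""

    params: DielectricParameters
    free_names: tuple[str, ...]
    param_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int = 0

    def error(self, name: str) -> float:
        return self.param_errors[name]


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    objective: "imag" weights only the loss eps'' (the quantity measured most
    precisely in ATR THz-TDS); "both" adds the real part with the same weights.
    """

    objective: str = "imag"
    window: tuple[float, float] = FIT_WINDOW_THZ
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self):
        if self.objective not in ("imag", "both"):
            raise ValueError("objective must be 'imag' or 'both'")


def eval_model(params: DielectricParameters, grid: FrequencyGrid) -> DielectricSpectrum:
    """Forward-evaluate the three-mode model on a frequency grid.

    Returns a spectrum with positive loss (eps'' >= 0) and ``sigma`` unset.
    """
    nu = grid.values
    w = 2.0 * np.pi * nu  # rad/ps, since THz == 1/ps
    chi = np.zeros_like(w, dtype=complex)
    if params.delta_eps1 != 0.0:
        chi += params.delta_eps1 / (1.0 + 1j * w * params.tau1)
    if params.delta_eps2 != 0.0:
        chi += params.delta_eps2 / (1.0 + 1j * w * params.tau2)
    if params.amp_s != 0.0:
        chi += params.amp_s / (params.omega_s**2 - w**2 + 1j * params.gamma_s * w)
    eps = params.eps_inf + params.c * chi
    # e^{-iwt} convention gives eps' - i*eps''; flip once to loss-positive.
    return DielectricSpectrum(grid, eps.real, -eps.imag)


def restrict_to_window(spec: DielectricSpectrum,
                       window: tuple[float, float] = FIT_WINDOW_THZ) -> DielectricSpectrum:
    """Return the sub-spectrum with frequencies inside [window[0], window[1]]."""
    lo, hi = window
    m = (spec.grid.values >= lo) & (spec.grid.values <= hi)
    if not np.any(m):
        raise ValueError(f"no data points inside fit window [{lo}, {hi}] THz")
    return DielectricSpectrum(
        FrequencyGrid(spec.grid.values[m]),
        spec.eps_real[m],
        spec.eps_imag[m],
        None if spec.sigma is None else spec.sigma[m],
    )


def _fit(spec: DielectricSpectrum, fixed: DielectricParameters,
         free_names: Sequence[str], config: FitConfig) -> FitResult:
    spec = restrict_to_window(spec, config.window)
    if not np.any(spec.eps_imag != 0.0):
        raise ValueError("degenerate spectrum: eps_imag identically zero")
    free_names = tuple(free_names)
    for nm in free_names:
        if nm not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter {nm!r}")

    sigma = spec.sigma if spec.sigma is not None else np.ones_like(spec.eps_imag)
    x0 = np.array([getattr(fixed, nm) for nm in free_names])
    lower = np.zeros(len(free_names))
    upper = np.full(len(free_names), np.inf)
    for i, nm in enumerate(free_names):
        if nm == "c":
            lower[i], upper[i] = 1e-12, 1.0

    def make_params(x: np.ndarray) -> DielectricParameters:
        return fixed.replace(**dict(zip(free_names, map(float, x))))

    def resid(x: np.ndarray) -> np.ndarray:
        model = eval_model(make_params(x), spec.grid)
        r = (model.eps_imag - spec.eps_imag) / sigma
        if config.objective == "both":
            r = np.concatenate([r, (model.eps_real - spec.eps_real) / sigma])
        return r

    sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                        xtol=config.xtol, ftol=config.ftol, gtol=config.gtol)
    if not sol.success:
        raise RuntimeError(f"dielectric fit did not converge: {sol.message}")

    # Covariance of the weighted LS estimator: (J^T J)^-1 when sigma is the
    # true per-point standard deviation.
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
        errs = {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(free_names)}
    except np.linalg.LinAlgError:
        errs = {nm: float("nan") for nm in free_names}

    return FitResult(
        params=make_params(sol.x),
        free_names=free_names,
        param_errors=errs,
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        n_points=len(spec.grid),
    )


def fit_pure_water(spec: DielectricSpectrum, fixed: DielectricParameters,
                   config: FitConfig | None = None) -> FitResult:
    """Fit a pure-water spectrum with {delta_eps1, delta_eps2} free.

    ``fixed`` supplies tau1, tau2, the oscillator triple, eps_inf and c = 1;
    its delta_eps values seed the optimizer.
    """
    if fixed.c != 1.0:
        raise ValueError("pure water requires c = 1")
    return _fit(spec, fixed, ("delta_eps1", "delta_eps2"), config or FitConfig())


def fit_solution(spec: DielectricSpectrum, c: float, fixed: DielectricParameters,
                 config: FitConfig | None = None,
                 delta_eps2: float = 2.37) -> FitResult:
    """Fit a protein-solution spectrum with only delta_eps1 free.

    The fast-relaxation strength is held at ``delta_eps2`` (default 2.37, the
    value obtained by fitting the solution at 25 degC with both strengths
    free); all other parameters are taken from the pure-water table and c is
    the water volume fraction of the solution.
    """
    if not (0.0 < c < 1.0):
        raise ValueError("solution water volume fraction must lie in (0, 1)")
    fixed = fixed.replace(c=c, delta_eps2=delta_eps2)
    return _fit(spec, fixed, ("delta_eps1",), config or FitConfig())


# ---------------------------------------------------------------------------
# Default pure-water parameter table
# ---------------------------------------------------------------------------

#: Reference values at 25 degC.  The slow-relaxation strength decreases
#: linearly with temperature; the slow relaxation time shortens roughly
#: exponentially (thermal activation); the fast mode and the 6 THz stretching
#: oscillator are kept temperature-independent over 25-75 degC.  These are
#: package defaults (static limit ~77 at 25 degC, eps(1 THz) ~ 4.1 + 2.5i),
#: fully overridable by the caller.
WATER_TABLE_25C = DielectricParameters(
    delta_eps1=72.0,
    tau1=8.3,
    delta_eps2=2.0,
    tau2=0.18,
    amp_s=1421.0,
    omega_s=2.0 * np.pi * 6.0,
    gamma_s=30.0,
    eps_inf=2.2,
    c=1.0,
)

#: d(delta_eps1)/dT in 1/degC and tau1 activation slope in 1/degC.
_DE1_SLOPE = -0.35
_TAU1_RATE = -0.019

WATER_TABLE_RANGE_C = (25.0, 75.0)


def water_parameters(temperature_c: float) -> DielectricParameters:
    """Default pure-water model parameters at a temperature in degC.

    Supported over 25-75 degC (the range of the underlying table).
    """
    lo, hi = WATER_TABLE_RANGE_C
    if not (lo <= temperature_c <= hi):
        raise ValueError(
            f"temperature {temperature_c} degC outside supported table range {lo}-{hi}")
    dT = temperature_c - 25.0
    return WATER_TABLE_25C.replace(
        delta_eps1=WATER_TABLE_25C.delta_eps1 + _DE1_SLOPE * dT,
        tau1=WATER_TABLE_25C.tau1 * float(np.exp(_TAU1_RATE * dT)),
    )
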