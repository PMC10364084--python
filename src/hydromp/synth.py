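"""Synthetic four-modality data with known ground truth.

Every generator is a deterministic function of its parameters and an explicit
integer seed, and is built by inverting the corresponding analysis: the THz
generator computes the solution slow-relaxation strength that encodes a given
hydration number, the DSC generator sizes the ice-melting endotherm from the
unfreezable-water count, the IR generator places three Gaussians with the
requested area fractions, and the CD generator mixes helix/coil basis spectra
so the 222 nm inversion is exact.  Analysis of noiseless output therefore
recovers every ground-truth quantity to machine precision, and parameter
recovery at realistic noise is a meaningful calibration of the whole chain.

The default scenario, :func:`bsa13`, emulates a 13 wt % serum-albumin
solution heated through its denaturation temperature (~60 degC): ~3300
hydration waters per protein at 25 degC declining to ~2200 just below the
transition then jumping up at 60 degC; ~2000 unfreezable waters dropping
after denaturation; an OH-band strong-HB fraction that departs from the
pure-water trend at 55 degC; and a helix fraction falling from 0.66 to 0.16
with midpoint 59 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cd import CDSpectrum, HelixConstants
from .dielectric import (DielectricParameters, DielectricSpectrum,
                         FrequencyGrid, eval_model, water_parameters)
from .dsc import CycleProtocol, DH_FUS_ICE, Thermogram
from .ftir import DEFAULT_CENTERS, IRSpectrum
from .hydration import (KirkwoodFactors, SolutionComposition,
                        total_water_per_solute, water_volume_fraction)

__all__ = [
    "GroundTruth",
    "bsa13",
    "default_thz_grid",
    "gen_water_dielectric",
    "gen_solution_dielectric",
    "gen_dsc_cycles",
    "gen_oh_band",
    "gen_cd_series",
    "cd_basis_curves",
]


@dataclass
class GroundTruth:
    """The scenario a synthetic experiment encodes.

    helix_series_true is (f_native, f_denatured, T_mid degC, slope per degC);
    noise maps modality -> level ("thz"/"ftir": relative sigma on the signal,
    "dsc": relative sigma on heat flow, "cd_f": absolute sigma on the helix
    fraction scale).
    """

    temperatures: np.ndarray
    n_hyd_true: np.ndarray
    n_unfreezable_true: np.ndarray
    oh_fractions_true: np.ndarray  # (n_T, 3), rows sum to 1
    helix_series_true: tuple[float, float, float, float]
    composition: SolutionComposition
    noise: dict = field(default_factory=lambda: {
        "thz": 0.01, "dsc": 0.005, "ftir": 0.01, "cd_f": 0.01})
    seed: int = 0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.n_hyd_true = np.asarray(self.n_hyd_true, dtype=float)
        self.n_unfreezable_true = np.asarray(self.n_unfreezable_true, dtype=float)
        self.oh_fractions_true = np.asarray(self.oh_fractions_true, dtype=float)
        n = len(self.temperatures)
        if self.n_hyd_true.shape != (n,) or self.n_unfreezable_true.shape != (n,):
            raise ValueError("truth series must match the temperature grid")
        if self.oh_fractions_true.shape != (n, 3):
            raise ValueError("oh_fractions_true must be (n_T, 3)")
        alpha = self.alpha
        if np.any(self.n_hyd_true > alpha) or np.any(self.n_unfreezable_true > alpha):
            raise ValueError("truth hydration counts cannot exceed alpha")
        if np.any(self.oh_fractions_true < 0) or \
                np.any(np.abs(self.oh_fractions_true.sum(axis=1) - 1) > 1e-9):
            raise ValueError("OH fractions must be nonnegative and sum to 1")
        f_nat, f_den, _, _ = self.helix_series_true
        if not (0 <= f_den < f_nat <= 1):
            raise ValueError("need 0 <= f_denatured < f_native <= 1")

    @property
    def alpha(self) -> float:
        return total_water_per_solute(self.composition)

    def _at(self, series: np.ndarray, T: float) -> float:
        i = np.argmin(np.abs(self.temperatures - T))
        if abs(self.temperatures[i] - T) > 1e-6:
            raise ValueError(f"temperature {T} degC not on the truth grid")
        return float(series[i])

    def n_hyd_at(self, T: float) -> float:
        return self._at(self.n_hyd_true, T)

    def n_unfreezable_at(self, T: float) -> float:
        return self._at(self.n_unfreezable_true, T)

    def oh_fractions_at(self, T: float) -> np.ndarray:
        i = np.argmin(np.abs(self.temperatures - T))
        if abs(self.temperatures[i] - T) > 1e-6:
            raise ValueError(f"temperature {T} degC not on the truth grid")
        return self.oh_fractions_true[i].copy()

    def helix_fraction_at(self, T: float) -> float:
        """Two-state line through the midpoint, clipped at the plateaus."""
        f_nat, f_den, t_mid, slope = self.helix_series_true
        thr = 0.5 * (f_nat + f_den)
        return float(np.clip(thr + slope * (T - t_mid), f_den, f_nat))


def bsa13(seed: int = 0) -> GroundTruth:
    """Default scenario: 13 wt % BSA in water, 25-75 degC in 5 degC steps."""
    T = np.arange(25.0, 80.0, 5.0)
    # weakly+strongly bound (THz) count: 3300 at 25 degC falling to 2200 at
    # 55 degC, then jumping up at the 60 degC denaturation
    n_thz = np.where(T < 60.0, 3300.0 - (3300.0 - 2200.0) / 30.0 * (T - 25.0), 3300.0)
    # strongly bound (DSC) count: drops on denaturation
    n_dsc = np.where(T < 60.0, 2000.0, 1700.0)
    # OH band: strong-HB fraction decreases with T for water-like behaviour,
    # with a +0.02 departure from 55 degC (denatured protein strengthens HBs)
    boost = np.where(T >= 55.0, 0.02, 0.0)
    f_s = 0.80 - 0.002 * (T - 25.0) + boost
    f_i = 0.15 + 0.0015 * (T - 25.0) - 0.75 * boost
    f_w = 1.0 - f_s - f_i
    comp = SolutionComposition(
        solute_wt_fraction=0.13,
        solute_molar_mass=66000.0,
        density_series=((10.0, 1.0365), (20.0, 1.0345),
                        (30.0, 1.0318), (40.0, 1.0285)),
        partial_specific_volume=0.735,
    )
    return GroundTruth(
        temperatures=T,
        n_hyd_true=n_thz,
        n_unfreezable_true=n_dsc,
        oh_fractions_true=np.column_stack([f_s, f_i, f_w]),
        helix_series_true=(0.66, 0.16, 59.0, -0.0125),
        composition=comp,
        seed=seed,
    )


def default_thz_grid(n: int = 30) -> FrequencyGrid:
    """n-point linear grid spanning the 0.3-2.5 THz fit window."""
    return FrequencyGrid(np.linspace(0.3, 2.5, n))


# -- THz ---------------------------------------------------------------------

def gen_water_dielectric(T: float, grid: FrequencyGrid | None = None,
                         noise: float = 0.01, seed: int = 0) -> DielectricSpectrum:
    """Pure-water spectrum from the default temperature table plus noise.

    Multiplicative Gaussian noise of relative size ``noise`` is applied
    independently to the real and imaginary parts; ``sigma`` is set to the
    true per-point standard deviation of eps_imag.
    """
    grid = grid or default_thz_grid()
    model = eval_model(water_parameters(T), grid)
    rng = np.random.default_rng(seed)
    sigma = np.abs(noise * model.eps_imag)
    if noise == 0:
        return DielectricSpectrum(grid, model.eps_real, model.eps_imag,
                                  None if noise == 0 else sigma)
    er = model.eps_real * (1.0 + noise * rng.standard_normal(len(grid)))
    ei = model.eps_imag * (1.0 + noise * rng.standard_normal(len(grid)))
    return DielectricSpectrum(grid, er, np.abs(ei), sigma)


def solution_delta_eps1(truth: GroundTruth, T: float,
                        k: KirkwoodFactors = KirkwoodFactors(),
                        delta_eps2_sol: float = 2.37) -> float:
    """Slow-relaxation strength that encodes n_hyd_true(T) for the solution.

    Inverts the Kirkwood bookkeeping: the solution's per-water-volume mode
    populations must be (1 - n/alpha) times the pure-water populations.
    """
    pw = water_parameters(T)
    s_wat = pw.delta_eps1 / k.g1 + pw.delta_eps2 / k.g2
    n = truth.n_hyd_at(T)
    de1 = k.g1 * ((1.0 - n / truth.alpha) * s_wat - delta_eps2_sol / k.g2)
    if de1 < 0:
        raise ValueError(
            f"hydration number {n} at {T} degC is not encodable with "
            f"delta_eps2 = {delta_eps2_sol} (implied delta_eps1 < 0)")
    return de1


def gen_solution_dielectric(T: float, truth: GroundTruth,
                            grid: FrequencyGrid | None = None,
                            noise: float = 0.01, seed: int = 0,
                            k: KirkwoodFactors = KirkwoodFactors(),
                            delta_eps2_sol: float | None = 2.37) -> DielectricSpectrum:
    """Protein-solution spectrum encoding the ground-truth hydration number.

    ``delta_eps2_sol`` is the fast-relaxation strength of the solution
    (default the fixed fitting value 2.37); pass the pure-water value to make
    a zero-hydration solution exactly the c-scaled water spectrum.
    """
    grid = grid or default_thz_grid()
    pw = water_parameters(T)
    if delta_eps2_sol is None:
        delta_eps2_sol = pw.delta_eps2
    de1 = solution_delta_eps1(truth, T, k, delta_eps2_sol)
    c = water_volume_fraction(truth.composition, T)
    params = pw.replace(delta_eps1=de1, delta_eps2=delta_eps2_sol, c=c)
    model = eval_model(params, grid)
    rng = np.random.default_rng(seed)
    sigma = np.abs(noise * model.eps_imag) if noise > 0 else None
    if noise == 0:
        return DielectricSpectrum(grid, model.eps_real, model.eps_imag, sigma)
    er = model.eps_real * (1.0 + noise * rng.standard_normal(len(grid)))
    ei = model.eps_imag * (1.0 + noise * rng.standard_normal(len(grid)))
    return DielectricSpectrum(grid, er, np.abs(ei), sigma)


# -- DSC ---------------------------------------------------------------------

def _gauss(x, center, sd):
    return np.exp(-0.5 * ((x - center) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def gen_dsc_cycles(truth: GroundTruth,
                   protocol: CycleProtocol | None = None,
                   seed: int = 0,
                   sample_mass_mg: float = 10.0,
                   noise: float | None = None,
                   melt_center_c: float = 0.5,
                   melt_width_c: float = 1.2,
                   denaturation_temp_c: float = 61.0,
                   denaturation_width_c: float = 8.0,
                   denaturation_enthalpy_j: float = 0.0157,
                   second_melt_scale: float | None = None,
                   dT: float = 0.1) -> list[Thermogram]:
    """Synthetic four-step freeze/thaw cycles at 2 degC/min.

    Heating segments carry an ice-melting endotherm whose area encodes the
    freezable water mass dH_fus * m_water * (1 - n/alpha): the first heating
    uses the native unfreezable count (the truth value at the coldest grid
    temperature), later heatings the truth value at T0 (the state after
    heating to T0).  ``second_melt_scale`` overrides that by scaling the
    second melt area directly (to emulate a measured enthalpy ratio).  The
    first heating above ~45 degC additionally contains a broad denaturation
    endotherm centered at ``denaturation_temp_c`` (absent from subsequent
    heatings: denaturation is irreversible).  Noise is multiplicative
    Gaussian of relative size ``noise`` plus a 0.005 mW additive floor and a
    slow sinusoidal baseline drift.
    """
    protocol = protocol or CycleProtocol.default()
    if noise is None:
        noise = truth.noise.get("dsc", 0.005)
    rng = np.random.default_rng(seed)
    ramp = 2.0  # degC/min
    rate_per_s = ramp / 60.0
    m_water_g = sample_mass_mg * 1e-3 * (1.0 - truth.composition.solute_wt_fraction)
    alpha = truth.alpha

    n_native = truth.n_unfreezable_at(float(truth.temperatures.min()))
    out: list[Thermogram] = []
    heating_count = 0
    for idx, (direction, t_a, t_b) in enumerate(protocol.steps):
        n_pts = max(int(round(abs(t_b - t_a) / dT)) + 1, 16)
        T = np.linspace(t_a, t_b, n_pts)
        hf = np.zeros_like(T)
        if direction == "heating":
            heating_count += 1
            if heating_count == 1:
                n_unf = n_native
            else:
                try:
                    n_unf = truth.n_unfreezable_at(protocol.T0)
                except ValueError:
                    n_unf = n_native
            area_j = DH_FUS_ICE * m_water_g * (1.0 - n_unf / alpha)
            if heating_count >= 2 and second_melt_scale is not None:
                area_first = DH_FUS_ICE * m_water_g * (1.0 - n_native / alpha)
                area_j = second_melt_scale * area_first
            # J * (1/degC) * (degC/s) * 1000 -> mW
            hf += area_j * _gauss(T, melt_center_c, melt_width_c) * rate_per_s * 1e3
            if heating_count == 1 and t_b > 45.0:
                hf += (denaturation_enthalpy_j
                       * _gauss(T, denaturation_temp_c, denaturation_width_c)
                       * rate_per_s * 1e3)
        if noise > 0:
            drift = 0.01 * np.sin(2.0 * np.pi * (T - t_a) / 150.0
                                  + rng.uniform(0, 2 * np.pi))
            hf = hf * (1.0 + noise * rng.standard_normal(n_pts)) \
                + 0.005 * rng.standard_normal(n_pts) + drift
        out.append(Thermogram(
            temperature=T, heat_flow=hf, ramp_rate=ramp, direction=direction,
            cycle_label=f"step{idx + 1}_{direction}", sample_mass=sample_mass_mg))
    return out


# -- FTIR --------------------------------------------------------------------

def gen_oh_band(fractions_true, T: float | None = None,
                noise: float = 0.01, seed: int = 0,
                total_area: float = 100.0,
                centers: tuple[float, float, float] = DEFAULT_CENTERS,
                widths: tuple[float, float, float] = (115.0, 85.0, 55.0),
                baseline: tuple[float, float] = (0.05, 2e-5),
                grid: np.ndarray | None = None) -> IRSpectrum:
    """OH band as three Gaussians with areas proportional to the fractions.

    ``baseline`` is (offset, slope-per-cm^-1 about 3400); the total
    integrated band area is held at ``total_area`` absorbance*cm^-1 whatever
    the fractions, so fraction changes conserve total intensity.
    """
    fr = np.asarray(fractions_true, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0):
        raise ValueError("fractions_true must be three nonnegative numbers")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    x = grid if grid is not None else np.arange(2800.0, 3801.0, 2.0)
    y = baseline[0] + baseline[1] * (x - 3400.0)
    for f, c, w in zip(fr, centers, widths):
        y = y + total_area * f * _gauss(x, c, w)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise * rng.standard_normal(len(x)))
    return IRSpectrum(x, y, temperature=T)


# -- CD ----------------------------------------------------------------------

def cd_basis_curves(wavelength: np.ndarray,
                    constants: HelixConstants = HelixConstants()
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-residue-ellipticity basis curves for pure helix and pure coil.

    Shapes are stylized far-UV curves (helix: double minimum near 208/222 nm
    and a positive band near 192 nm; coil: single minimum near 198 nm); a
    narrow correction Gaussian pins each curve's 222 nm value exactly to the
    configured reference constant, so the two-point inversion of a mixed
    spectrum is exact by construction.
    """
    wl = np.asarray(wavelength, dtype=float)

    def g(center, sd):
        return np.exp(-0.5 * ((wl - center) / sd) ** 2)

    helix = -31000.0 * g(222.0, 9.5) - 33000.0 * g(208.0, 8.5) + 65000.0 * g(192.0, 7.0)
    coil = -18000.0 * g(198.0, 9.0) + 1500.0 * g(225.0, 25.0)

    def pin(curve, target):
        at222 = np.interp(222.0, wl, curve)
        return curve + (target - at222) * g(222.0, 10.0)

    return pin(helix, constants.theta_helix), pin(coil, constants.theta_coil)


def gen_cd_series(truth: GroundTruth, seed: int = 0,
                  temperatures: np.ndarray | None = None,
                  noise_f: float | None = None,
                  constants: HelixConstants = HelixConstants(),
                  wavelength: np.ndarray | None = None,
                  path_length: float = 1.0,
                  molar_concentration: float = 2.05e-7,
                  n_residues: int = 583) -> list[CDSpectrum]:
    """Per-temperature CD spectra encoding the ground-truth helix series.

    Each spectrum is the f_H-weighted mix of the helix and coil basis
    curves converted to machine ellipticity (mdeg).  ``noise_f`` is the
    noise amplitude expressed on the helix-fraction scale (default the
    truth's "cd_f" level); it is converted to mdeg through the same
    constants the analysis inverts, so the recovered f_H carries exactly
    that sigma.
    """
    if temperatures is None:
        temperatures = np.arange(25.0, 87.0, 2.0)
    if noise_f is None:
        noise_f = truth.noise.get("cd_f", 0.01)
    wl = wavelength if wavelength is not None else np.arange(190.0, 251.0, 1.0)
    if not np.any(np.abs(wl - 222.0) < 1e-9):
        raise ValueError("wavelength grid must contain 222 nm exactly")
    helix_b, coil_b = cd_basis_curves(wl, constants)
    conv = 10.0 * path_length * molar_concentration * n_residues  # [theta]->mdeg
    sigma_mdeg = noise_f * abs(constants.theta_helix - constants.theta_coil) * conv
    rng = np.random.default_rng(seed)
    out = []
    for T in np.asarray(temperatures, dtype=float):
        f = truth.helix_fraction_at(T)
        mre = f * helix_b + (1.0 - f) * coil_b
        theta = mre * conv
        if noise_f > 0:
            theta = theta + sigma_mdeg * rng.standard_normal(len(wl))
        out.append(CDSpectrum(wl, theta, path_length=path_length,
                              molar_concentration=molar_concentration,
                              n_residues=n_residues, temperature=float(T)))
    return out
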