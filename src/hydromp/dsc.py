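"""Differential scanning calorimetry: unfreezable water and denaturation.

Water that remains unfrozen after cooling a protein solution below 0 degC
("unfreezable" or "nonfreezing" water) produces no ice-melting endotherm on
reheating.  Its amount is therefore the deficit between the total water mass
and the freezable mass inferred from the melting enthalpy:

    m_freezable = H_melt / dH_fus          (dH_fus = 333.55 J/g for ice)
    n_unfreezable = alpha * (m_water - m_freezable) / m_water

Heat flow follows the endotherm-positive sign convention.  The standard
measurement protocol is a four-step temperature cycle (cool to -25 degC,
heat to an upper temperature T0, cool again, heat again) at 2 degC/min;
comparing the melt enthalpies of the two heating segments isolates
irreversible changes such as denaturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .hydration import SolutionComposition, total_water_per_solute

__all__ = [
    "Thermogram",
    "CycleProtocol",
    "PeakIntegration",
    "EnthalpyRatio",
    "DH_FUS_ICE",
    "integrate_endotherm",
    "unfreezable_water",
    "enthalpy_ratio",
    "detect_denaturation_peak",
    "has_anomaly_below_zero",
]

#: Specific melting enthalpy of ice, J/g (6.01 kJ/mol).
DH_FUS_ICE = 333.55


@dataclass
class Thermogram:
    """Heat-flow trace over one temperature segment.

    heat_flow is in mW (endotherm positive); ramp_rate in degC/min;
    sample_mass in mg.
    """

    temperature: np.ndarray
    heat_flow: np.ndarray
    ramp_rate: float
    direction: str
    cycle_label: str = ""
    sample_mass: float | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.temperature.shape != self.heat_flow.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and heat_flow must be equal-length 1-D arrays")
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")
        d = np.diff(self.temperature)
        if self.direction == "heating" and not np.all(d > 0):
            raise ValueError("heating trace must have strictly increasing temperature")
        if self.direction == "cooling" and not np.all(d < 0):
            raise ValueError("cooling trace must have strictly decreasing temperature")
        if self.ramp_rate <= 0:
            raise ValueError("ramp rate must be positive")


@dataclass(frozen=True)
class CycleProtocol:
    """Ordered temperature program; directions must alternate.

    The default emulates the four-step freeze/thaw protocol: cool from room
    temperature to -25 degC, heat to T0, cool to -25 degC, heat to T0.
    """

    steps: tuple[tuple[str, float, float], ...]
    T0: float = 75.0

    def __post_init__(self):
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        for direction, a, b in self.steps:
            if direction == "heating" and b <= a:
                raise ValueError("heating step must increase temperature")
            if direction == "cooling" and b >= a:
                raise ValueError("cooling step must decrease temperature")
            if direction not in ("heating", "cooling"):
                raise ValueError(f"bad direction {direction!r}")
        dirs = [s[0] for s in self.steps]
        if any(a == b for a, b in zip(dirs, dirs[1:])):
            raise ValueError("consecutive steps must alternate direction")

    @staticmethod
    def default(T0: float = 75.0, room: float = 22.0) -> "CycleProtocol":
        return CycleProtocol(
            steps=(
                ("cooling", room, -25.0),
                ("heating", -25.0, T0),
                ("cooling", T0, -25.0),
                ("heating", -25.0, T0),
            ),
            T0=T0,
        )


@dataclass
class PeakIntegration:
    """Integrated transition with a linear baseline over the window.

    enthalpy is in J, endotherm-positive; baseline holds the (intercept,
    slope) of the subtracted line in mW vs degC.
    """

    T_onset: float
    T_peak: float
    T_end: float
    enthalpy: float
    baseline: tuple[float, float]
    flat_warning: bool = False

    def __post_init__(self):
        if not (self.T_onset <= self.T_peak <= self.T_end):
            raise ValueError("require T_onset <= T_peak <= T_end")


class EnthalpyRatio(NamedTuple):
    """Both orientations of the two-heating melt-enthalpy ratio."""

    second_over_first: float
    first_over_second: float


def _baseline_line(tg: Thermogram, t_lo: float, t_hi: float,
                   flank: float = 1.0) -> tuple[float, float, bool]:
    """Straight baseline through the mean heat flow of 1-degC window-edge
    flanks; returns (intercept, slope, nonflat_flag).

    The nonflat flag is raised when either flank departs from the fitted
    line by more than 5 % of the window's signal span — the anchors are then
    sitting on a peak shoulder rather than quiet baseline.
    """
    T, P = tg.temperature, tg.heat_flow
    m_lo = (T >= t_lo) & (T <= t_lo + flank)
    m_hi = (T >= t_hi - flank) & (T <= t_hi)
    if not m_lo.any() or not m_hi.any():
        raise ValueError("integration window too narrow for baseline anchors")
    y_lo, y_hi = float(P[m_lo].mean()), float(P[m_hi].mean())
    x_lo, x_hi = float(T[m_lo].mean()), float(T[m_hi].mean())
    slope = (y_hi - y_lo) / (x_hi - x_lo)
    intercept = y_lo - slope * x_lo
    span = max(np.ptp(P[(T >= t_lo) & (T <= t_hi)]), 1e-30)
    dev = max(np.ptp(P[m_lo] - (intercept + slope * T[m_lo])),
              np.ptp(P[m_hi] - (intercept + slope * T[m_hi])))
    return intercept, slope, dev > 0.05 * span


def integrate_endotherm(tg: Thermogram,
                        window: tuple[float, float]) -> PeakIntegration:
    """Integrate a melting/transition endotherm over a temperature window.

    The enthalpy is the trapezoidal integral of the baseline-subtracted heat
    flow converted from (mW, degC, ramp) to joules via time = dT/ramp_rate;
    the baseline is a straight line through the mean heat flow of 1-degC
    flanks just inside the window edges.
    """
    if tg.direction != "heating":
        raise ValueError("endotherm integration requires a heating segment")
    t_lo, t_hi = window
    T, P = tg.temperature, tg.heat_flow
    if t_lo < T[0] or t_hi > T[-1]:
        raise ValueError("window outside the trace temperature range")

    intercept, slope, nonflat = _baseline_line(tg, t_lo, t_hi)
    if nonflat:
        warnings.warn("baseline anchors sit on a non-flat region; "
                      "consider widening the window", stacklevel=2)

    m = (T >= t_lo) & (T <= t_hi)
    Tm, net = T[m], P[m] - (intercept + slope * T[m])
    # mW -> W, degC / (degC/s) -> s
    rate_per_s = tg.ramp_rate / 60.0
    enthalpy = float(np.trapezoid(net, Tm) / 1000.0 / rate_per_s)

    i_peak = int(np.argmax(net))
    peak_val = net[i_peak]
    thr = 0.05 * peak_val if peak_val > 0 else 0.0
    above = np.nonzero(net > thr)[0] if peak_val > 0 else np.array([i_peak])
    return PeakIntegration(
        T_onset=float(Tm[above[0]]),
        T_peak=float(Tm[i_peak]),
        T_end=float(Tm[above[-1]]),
        enthalpy=enthalpy,
        baseline=(float(intercept), float(slope)),
        flat_warning=nonflat,
    )


def unfreezable_water(melt: PeakIntegration, comp: SolutionComposition,
                      sample_mass_mg: float,
                      dH_fus: float = DH_FUS_ICE) -> tuple[float, bool]:
    """Unfreezable waters per solute molecule from a melt endotherm.

    Returns (n_unfreezable, clamped_flag); the flag marks a raw negative
    value (melt enthalpy slightly exceeding the total water capacity) that
    was clamped to zero.
    """
    if dH_fus <= 0:
        raise ValueError("dH_fus must be positive")
    if sample_mass_mg <= 0:
        raise ValueError("sample mass must be positive")
    m_water_g = sample_mass_mg * 1e-3 * (1.0 - comp.solute_wt_fraction)
    m_freezable_g = melt.enthalpy / dH_fus
    if m_freezable_g > 1.02 * m_water_g:
        raise ValueError(
            "freezable water exceeds total water by more than 2%: "
            "calibration inconsistency")
    m_unfrozen = m_water_g - m_freezable_g
    clamped = m_unfrozen < 0
    m_unfrozen = max(m_unfrozen, 0.0)
    alpha = total_water_per_solute(comp)
    return alpha * m_unfrozen / m_water_g, clamped


def enthalpy_ratio(first: PeakIntegration, second: PeakIntegration) -> EnthalpyRatio:
    """Melt-enthalpy ratio between the two heating segments, both orientations."""
    if first.enthalpy == 0 or second.enthalpy == 0:
        raise ZeroDivisionError("zero melt enthalpy in ratio")
    return EnthalpyRatio(
        second_over_first=second.enthalpy / first.enthalpy,
        first_over_second=first.enthalpy / second.enthalpy,
    )


def detect_denaturation_peak(tg: Thermogram,
                             search_window: tuple[float, float],
                             snr_threshold: float = 8.0) -> PeakIntegration | None:
    """Locate a broad transition endotherm inside a search window.

    The baseline-subtracted heat flow is smoothed with a ~2 degC moving
    average; a peak is accepted when its smoothed height exceeds
    ``snr_threshold`` times the noise of the smoothed trace (noise estimated
    robustly from the high-frequency residual).  Returns ``None`` when no
    transition rises above the noise — absence of a peak is a result, not an
    error.
    """
    if tg.direction != "heating":
        raise ValueError("peak detection requires a heating segment")
    t_lo, t_hi = search_window
    T = tg.temperature
    if t_lo < T[0] or t_hi > T[-1]:
        raise ValueError("search window outside the trace range")

    intercept, slope, _ = _baseline_line(tg, t_lo, t_hi)
    m = (T >= t_lo) & (T <= t_hi)
    Tm = T[m]
    net = tg.heat_flow[m] - (intercept + slope * Tm)

    dT = np.median(np.diff(Tm))
    win = max(3, int(round(2.0 / dT)) | 1)  # odd window spanning ~2 degC
    kernel = np.ones(win) / win
    smooth = np.convolve(net, kernel, mode="same")
    resid = net - smooth
    sigma_pt = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    sigma_smooth = max(sigma_pt / np.sqrt(win), 1e-30)

    i_peak = int(np.argmax(smooth))
    if smooth[i_peak] < snr_threshold * sigma_smooth:
        return None
    peak_val = smooth[i_peak]
    # refine the location of a broad peak: quadratic vertex through the
    # region above 80 % of the smoothed maximum
    top = np.nonzero(smooth > 0.8 * peak_val)[0]
    runs_top = np.split(top, np.nonzero(np.diff(top) > 1)[0] + 1)
    top = next(r for r in runs_top if i_peak in r)
    t_peak = float(Tm[i_peak])
    if len(top) >= 5:
        a, b, _ = np.polyfit(Tm[top], smooth[top], 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            if Tm[top[0]] <= vertex <= Tm[top[-1]]:
                t_peak = float(vertex)
    above = np.nonzero(smooth > 0.05 * peak_val)[0]
    # restrict to the contiguous run containing the peak
    runs = np.split(above, np.nonzero(np.diff(above) > 1)[0] + 1)
    run = next(r for r in runs if i_peak in r)
    rate_per_s = tg.ramp_rate / 60.0
    enthalpy = float(np.trapezoid(net[run[0]:run[-1] + 1],
                                  Tm[run[0]:run[-1] + 1]) / 1000.0 / rate_per_s)
    return PeakIntegration(
        T_onset=min(float(Tm[run[0]]), t_peak),
        T_peak=t_peak,
        T_end=max(float(Tm[run[-1]]), t_peak),
        enthalpy=enthalpy,
        baseline=(float(intercept), float(slope)),
    )


def has_anomaly_below_zero(tg: Thermogram, t_range: tuple[float, float] = (-75.0, -1.0),
                           snr_threshold: float = 8.0) -> bool:
    """Screen for "intermediate water": any thermal anomaly below 0 degC.

    Returns True when a peak is detected in ``t_range`` — a well-behaved
    protein solution shows none (all non-bulk water is either freezable near
    0 degC or unfreezable).
    """
    t_lo = max(t_range[0], float(tg.temperature.min()))
    t_hi = min(t_range[1], float(tg.temperature.max()))
    if t_hi - t_lo < 3.0:
        return False
    return detect_denaturation_peak(tg, (t_lo, t_hi), snr_threshold) is not None
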