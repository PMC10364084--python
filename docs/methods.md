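# Methods

This note documents the models, the defaults and why they were chosen, the
synthetic-data generators and what passing tests do and do not show, and
the numerical choices and known limitations.

## THz dielectric model

The permittivity of liquid water between 0.3 and 2.5 THz is modelled as

    eps(w) = eps_inf + c * [ de1/(1 + i w t1) + de2/(1 + i w t2)
                           + A_s/(w_s^2 - w^2 + i g_s w) ]

with w = 2*pi*nu, nu in THz and relaxation times in ps (THz = 1/ps, so w*t
is dimensionless). The first term is the high-frequency tail of the slow,
collective rotational relaxation of the hydrogen-bonded network (its peak
lies near 0.02 THz, far below the window); the second is the ~1 THz
collisional relaxation of transiently free water molecules; the third is
the intermolecular O···O stretching vibration near 6 THz, as a damped
harmonic oscillator. The weak ~4 THz bending mode and the protein's own
absorption are neglected — both are insignificant in this band. `c` is the
volume fraction of water: only water contributes, so a solution spectrum is
the water susceptibility scaled by `c` with altered mode strengths.

**Sign convention.** All public spectra use eps = eps' + i*eps'' with the
loss eps'' positive. The model is evaluated once in the e^{-iwt} convention
and the imaginary part flipped in `eval_model`; nothing else in the package
touches the convention.

**Default pure-water parameter table** (25 °C): de1 = 72.0, t1 = 8.3 ps,
de2 = 2.0, t2 = 0.18 ps, A_s = 1421 rad²/ps² (dimensionless oscillator
strength A_s/w_s² ≈ 1.0), w_s = 2π·6 rad/ps, g_s = 30 rad/ps,
eps_inf = 2.2. The slow strength decreases linearly with temperature
(−0.35/°C) and the slow time shortens exponentially (−1.9 %/°C), both over
25–75 °C; the fast mode and the oscillator are held constant. These values
were fixed once so that three independent observables come out right
simultaneously: the static limit eps_inf + c(de1 + de2 + A_s/w_s²) ≈ 77,
the 1 THz permittivity ≈ 4.1 + 2.5i (hence Re sqrt(eps) ≈ 2.11, consistent
with the ~20 μm evanescent depth below), and the stretching resonance at
6 THz. They are package defaults, overridable everywhere a
`DielectricParameters` is accepted.

**Fitting.** Trust-region-reflective least squares
(`scipy.optimize.least_squares`) on the sigma-weighted imaginary part
(optionally joint real+imaginary), bounds at the physical invariants,
starting values from the fixed table, tolerances 1e-12. Pure water frees
{de1, de2}; solutions free only de1 with de2 held at 2.37 (the value from
releasing both strengths at 25 °C) and all other parameters at the
pure-water values. Parameter covariance is (JᵀJ)⁻¹ of the weighted
Jacobian, which the suite verifies by coverage calibration (3-sigma
coverage ≥ 95 % over 100 noisy replicates).

## Hydration counting

A water molecule counts as hydration water when its slow relaxation is
retarded out of the THz window. Relaxation strengths are proportional to
mode populations through the Kirkwood dipole-correlation factor g of each
mode (g1 = 2.9 slow, g2 = 1.0 fast), so the per-water-volume populations
of the solution relative to pure water give

    n_hyd = alpha * [1 - (de1_sol/g1 + de2_sol/g2)/(de1_wat/g1 + de2_wat/g2)]

with alpha = [(1-w)/M_water]/[w/M_solute] the total waters per solute
(24,518 for 13 wt % at 66 kDa). Because the solution strengths are fitted
under the c-scaled model they are already per unit water volume; no second
volume correction is applied. The error is first-order propagation from
the fitted strengths only, treating fixed parameters as exact; the suite
checks the propagated error against the empirical replicate scatter
(within 50 %). Negative estimates (faster-than-bulk water) are flagged,
never clamped, to keep the estimator unbiased near zero.

The water volume fraction comes from the composition:
c = 1 − w·ρ(T)·v̄ with the solution density interpolated linearly in the
measured series and extrapolated linearly above its last point (densities
above 40 °C are typically not measured directly). Defaults: solute molar
mass 66,000 g/mol, partial specific volume 0.735 mL/g — standard values
for serum albumin, both configurable.

## ATR optics

Two-medium (prism/sample) Fresnel model: silicon prism n = 3.4, default
incidence 45° (a standard Dove-prism geometry; the angle is configurable),
p-polarization. The amplitude coefficient is computed in the wavevector
form with the decaying-branch choice Im k_z ≥ 0; the sign convention is
fixed so the normal-incidence limit is (n1−n2)/(n1+n2) for both
polarizations. Penetration depth d = λ0/(2π·sqrt(n1²sin²θ − n2²)) with
n2 = Re sqrt(eps); both the field (1/e amplitude) and intensity (half
that) conventions are implemented, with intensity as the default — it is
the convention under which the default geometry reproduces the ~20 μm
depth at 1 THz for water. Inversion from a measured reflection
coefficient to permittivity is 2-D root finding (Powell hybrid, restarted
once, residual tolerance 1e-10). At exactly 45° the p-pol coefficient is
quadratically flat around index matching, so inversion of r ≈ 0 resolves
the loss only to ~sqrt(tolerance); this is a property of the optics, not
the solver. No air gap, film layer, or beam-divergence correction is
modelled.

## DSC

Heat flow is endotherm-positive, in mW; enthalpies are converted via
time = ΔT/ramp (default ramp 2 °C/min). The melting endotherm is
integrated with a straight baseline anchored at the mean heat flow of
1 °C flanks just inside the window edges; a warning is issued when a
flank departs from the fitted line by more than 5 % of the window's
signal span (anchor on a peak shoulder). Unfreezable water:
freezable mass = H/ΔH_fus with ΔH_fus = 333.55 J/g (6.01 kJ/mol);
unfreezable = total water − freezable, converted to waters per solute
via alpha. Freezable mass exceeding the total water by > 2 % raises a
calibration error; small negative counts are clamped to zero with a flag.

The broad denaturation endotherm is located on the baseline-subtracted
trace smoothed by a ~2 °C moving average; a peak is accepted at 8× the
smoothed noise level (estimated robustly from the high-frequency
residual), and its position is refined by a quadratic vertex fit through
the region above 80 % of the maximum — necessary because the peak is
~25 μW high and tens of °C wide. Absence of a peak is returned as `None`,
not an error. The melt-enthalpy ratio between the two heating segments is
returned in both orientations (second/first and first/second): the
direction convention in reports of this quantity is ambiguous, and the
two published statements it summarizes (a smaller anomaly after
denaturation vs. a decreased unfreezable count) are not reconcilable
under a single convention, so the package computes both and leaves the
interpretation to the caller.

## FTIR

Three Gaussians (amplitude form) plus a linear baseline, fitted over
3000–3800 cm⁻¹ by default (the lower bound excludes protein amide/CH
contributions; all three water bands lie at 3295 cm⁻¹ and above). Centers
start at 3295/3460/3590 cm⁻¹ and may drift ±40 cm⁻¹ (free-with-bounds
default; fully pinned centers are available) — the bounds prevent label
swapping while allowing thermal shifts, and components are re-sorted by
center after the fit. Because spectral noise is predominantly
multiplicative, residuals are weighted by 1/|y| (floored at 5 % of the
signal span). Fractions are areas normalized by the total area, so they
sum to one exactly; their errors come from the delta method on the fit
covariance, with the normal matrix equilibrated before inversion (the raw
matrix mixes scales of centers ~3e3 and amplitudes ~1e-1, and a plain
pseudo-inverse truncates precisely the flat overlap directions that
dominate the uncertainty). The three components overlap strongly, so the
single-spectrum fraction uncertainty at 1 % noise is ~2.5 percentage
points — the suite verifies that the reported errors match this scatter.

## CD

Mean-residue molar ellipticity [θ] = θ_mdeg/(10·l·m·A) with l in cm, m in
mol/L, A the residue count (defaults 1 cm, 2.05e-7 M, 583). Helix
fraction is the two-point linear map between reference 222 nm
ellipticities of a complete helix and a complete coil; defaults
[θ]_helix = −32,640 and [θ]_coil = −2,340 deg·cm²/dmol follow the classic
two-point convention for 222 nm helix estimation. These references are
configuration values; absolute f_H values scale with them, while the
midpoint temperature is invariant under any affine rescaling applied
consistently (property-tested). The denaturation midpoint is the crossing
of an ordinary least-squares line through f_H(T) over 45–85 °C with the
threshold (f_native + f_denatured)/2 = 0.41 for the 66 %/16 % defaults;
out-of-range f_H values are flagged but not clamped so the regression
stays unbiased, and a crossing outside the fit range is flagged as
extrapolated.

## Synthetic generators and the default scenario

Every generator is a deterministic function of (parameters, seed) with an
explicit `numpy.random.default_rng` seed, and is constructed by inverting
its analysis, so analysis∘generation is the identity at zero noise
(machine precision; verified for all four modalities). The default
`bsa13()` scenario encodes a 13 wt % serum-albumin solution on a
25–75 °C grid: THz hydration number 3300 at 25 °C declining linearly to
2200 at 55 °C then jumping back to 3300 at the 60 °C denaturation;
unfreezable count 2000 (native) dropping to 1700 (denatured; the
magnitude of the drop is a representative choice — only the native value
and the direction of the change are constrained); OH fractions starting
at 80/15/5 % with the pure-water trend (strong-HB fraction −0.002/°C) and
a +0.02 departure of the strong fraction from 55 °C; helix fraction from
0.66 to 0.16 as a two-state line of slope −0.0125/°C through a 59 °C
midpoint, clipped at the plateaus.

Noise models are minimal: multiplicative Gaussian for THz and IR spectra
(default 1 %), multiplicative 0.5 % plus a 5 μW additive floor and a slow
sinusoidal baseline drift (10 μW amplitude, 150 °C period) for DSC, and
additive Gaussian for CD parametrized on the helix-fraction scale
(σ = 0.01 by default, converted to mdeg through the same constants the
analysis inverts). The DSC denaturation endotherm defaults to 15.7 mJ for
a 10 mg sample (≈ 800 kJ/mol, a typical calorimetric unfolding enthalpy
for serum albumin). The CD basis curves are stylized helix/coil shapes
pinned exactly to the reference ellipticities at 222 nm, which makes the
two-point inversion exact by construction.

What the generators do *not* emulate: instrument response functions and
raw interferograms/time-domain pulses, correlated (pink) noise, ATR
penetration-depth dispersion across the IR band, cold crystallization or
freezing-point depression in DSC, and β-sheet/turn contributions to CD.
Passing round trips therefore validate the estimators under the stated
noise models, not robustness to every instrumental artifact.

## Problem sizes

The calibration tests and the reproduction script use 100 replicates for
the THz, DSC, and FTIR round trips and 200 for CD, with 30-point THz
grids, 0.1 °C DSC sampling, 2 cm⁻¹ IR sampling, and 1 nm CD sampling —
sizes chosen to match the scale of the corresponding experiments while
keeping a full run in seconds.

## Known limitations

- The Kirkwood factors are fixed inputs, not fitted; errors in g1/g2
  propagate linearly into n_hyd.
- With de2 fixed at 2.37 for solutions, the fast-relaxation "increase"
  enters the bookkeeping only through that constant; the estimator cannot
  separate fast-mode changes from slow-mode depletion.
- The two-medium ATR model treats the prism/sample interface as ideal.
- The DSC number attributed to T0 assumes the state after heating to T0
  is preserved through the subsequent cooling; partial refolding below
  the denaturation temperature would blur this attribution.
- Helix fractions depend linearly on the configurable reference
  ellipticities; only midpoint temperatures are convention-independent.
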