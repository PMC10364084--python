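"""Count hydration waters per protein from THz dielectric spectra.

Generates a pure-water and a 13 wt % protein-solution permittivity spectrum
at 25 degC with 1 % noise, fits the three-mode dielectric model to each
(water: both relaxation strengths free; solution: slow strength only, fast
strength fixed at 2.37), and converts the strength deficit into a hydration
number through the Kirkwood factors g1 = 2.9, g2 = 1.0.
"""

from hydromp import (fit_pure_water, fit_solution, hydration_number,
                     water_parameters, water_volume_fraction)
from hydromp.synth import bsa13, gen_solution_dielectric, gen_water_dielectric

truth = bsa13()
T = 25.0
p_water = water_parameters(T)
c = water_volume_fraction(truth.composition, T)

water_spec = gen_water_dielectric(T, noise=0.01, seed=1)
solution_spec = gen_solution_dielectric(T, truth, noise=0.01, seed=2)

water_fit = fit_pure_water(water_spec, p_water)
solution_fit = fit_solution(solution_spec, c, p_water)
est = hydration_number(water_fit, solution_fit, truth.alpha, c, temperature=T)

print(f"water fit:    d_eps1 = {water_fit.params.delta_eps1:.2f} "
      f"+- {water_fit.param_errors['delta_eps1']:.2f}, "
      f"d_eps2 = {water_fit.params.delta_eps2:.3f}")
print(f"solution fit: d_eps1 = {solution_fit.params.delta_eps1:.2f} "
      f"+- {solution_fit.param_errors['delta_eps1']:.2f} (d_eps2 fixed 2.37)")
print(f"alpha = {est.alpha:.0f} waters/protein, c = {c:.4f}")
print(f"n_hyd = {est.n_hyd:.0f} +- {est.n_err:.0f} waters/protein "
      f"(generator truth {truth.n_hyd_at(T):.0f})")
# n_hyd counts the waters whose slow rotational relaxation the protein has
# removed from the THz window -- strongly plus weakly bound hydration water.
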