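"""Decompose the OH stretching band into hydrogen-bond populations.

Generates a pure-water-like OH band (2800-3800 cm^-1) with the canonical
80/15/5 % split between strongly, intermediately, and weakly hydrogen-bonded
OH oscillators, adds 1 % noise, and fits three Gaussians plus a linear
baseline to recover the fractional band intensities.
"""

import numpy as np

from hydromp.ftir import fit_oh_band
from hydromp.synth import gen_oh_band

spec = gen_oh_band(np.array([0.80, 0.15, 0.05]), T=25.0, noise=0.01, seed=5)
bands, fractions = fit_oh_band(spec)

for label, band, frac, err in zip(("strong", "intermediate", "weak"),
                                  bands, fractions.as_tuple(),
                                  fractions.errors):
    print(f"{label:13s} center = {band.center:7.1f} cm^-1, "
          f"width = {band.width:5.1f} cm^-1, "
          f"fraction = {100 * frac:5.1f} +- {100 * err:.1f} %")
# The 3295 cm^-1 component reports OH groups with ~4 hydrogen bonds, the
# 3460 cm^-1 component 2-3 bonds, the 3590 cm^-1 component free OH; their
# area fractions track how a solute restructures the water network.
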