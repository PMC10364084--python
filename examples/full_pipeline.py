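"""Run the full four-modality analysis over the default scenario.

Generates THz, DSC, FTIR, and CD data for the 13 wt % protein scenario at
every temperature on its 25-75 degC grid, analyzes each modality, and
prints the joint per-temperature summary table (hydration numbers from THz,
unfreezable counts from DSC, strong-HB fraction from FTIR, helix fraction
from CD).
"""

from hydromp.pipeline import RunConfig, run_all
from hydromp.synth import bsa13

result = run_all(RunConfig(truth=bsa13(), seed=0, output_dir="scratch/run"))

cols = ["temperature_C", "n_thz", "n_err", "n_dsc", "f_strong", "f_H"]
print(result.joint[cols].to_string(index=False, float_format="%.3g"))
print(f"\nCD denaturation midpoint: {result.provenance['T_mid']:.1f} degC")
print(f"config hash: {result.provenance['config_hash']}, "
      f"failures: {len(result.provenance['failures'])}")
# Note the opposite responses at the 60 degC denaturation: n_thz (strong +
# weak hydration) jumps up while n_dsc (strongly bound only) drops, and the
# strong-HB OH fraction rises -- the three probes see different water.
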