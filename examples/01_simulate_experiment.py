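"""Generate a synthetic fungal-lipogenesis screening experiment.

Builds the full factorial design (3 species x 2 temperatures x 12 days x
3 biological x 3 technical replicates), prints its dimensions and the key
ground-truth ranges.  Every table carries its own ground truth, so the
downstream analyses can be validated against what was planted.
"""

import ftirlip as fl

exp = fl.generate_experiment(seed=42)

print(f"raw technical spectra : {exp.spectra.n_samples}")
print(f"wavenumber grid       : {exp.spectra.wavenumbers.max():.0f} -> "
      f"{exp.spectra.wavenumbers.min():.0f} cm^-1, {exp.spectra.n_wavenumbers} points")
print(f"GC table rows         : {len(exp.fatty_acids.data)} (one per species/temperature/day)")
print(f"glucose measurements  : {len(exp.glucose)}")

params = fl.summed_parameters(exp.fatty_acids)
print(f"\ntotal lipid  : {params.total_lipid.min():.1f} - {params.total_lipid.max():.1f} % of CDW")
print(f"unsaturation : {params.unsaturation_index.min():.2f} - "
      f"{params.unsaturation_index.max():.2f} double bonds per chain")
print(f"PUFA         : {params.PUFA.min():.1f} - {params.PUFA.max():.1f} % of total fatty acids")
# The ranges mirror an oleaginous screening: lipid climbs from a lean
# growth-phase baseline to a 26-37% plateau, while the oil shifts from
# PUFA-rich to MUFA-rich after the growth-to-stationary transition.
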