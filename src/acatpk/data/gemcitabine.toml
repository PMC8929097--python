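# Gemcitabine parameter set for the packaged oral-vs-IV study.
# Units: molecular_weight g/mol; solubility mg/mL; mean_precipitation_time s;
# particle_density g/mL; particle_radius µm; diffusion_coefficient cm²/s;
# peff_jejunal cm/s; vc_per_kg L/kg; clearance L/h.
[drug]
name = "gemcitabine"
molecular_weight = 263.2
logP = -1.32
solubility = 5.01
solubility_ph = 7.92
mean_precipitation_time = 900.0
particle_density = 1.2
particle_radius = 25.0
diffusion_coefficient = 0.93e-5
blood_plasma_ratio = 1.12
peff_jejunal = 0.59e-4
fup = 0.846
vc_per_kg = 1.45
clearance = 120.0
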