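# 1000 mg immediate-release tablet, once daily, 250 mL dose volume.
[regimen]
route = "oral_tablet_ir"
dose = 1000.0
n_doses = 1
dose_volume = 250.0
sim_duration = 24.0
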