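# 1500 mg immediate-release tablet, three times daily (every 8 h).
[regimen]
route = "oral_tablet_ir"
dose = 1500.0
n_doses = 3
interval = 8.0
dose_volume = 250.0
sim_duration = 24.0
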