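# Reference IV regimen: 1800 mg over a 30-minute infusion, 24 h horizon.
[regimen]
route = "iv_infusion"
dose = 1800.0
n_doses = 1
infusion_duration = 0.5
sim_duration = 24.0
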