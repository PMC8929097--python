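{
  "generator": "acatpk.synthetic.generate_caco2_assay",
  "synthetic": true,
  "seed": 20210,
  "true_papp_cm_per_s": 5.8e-06,
  "noise_cv": 0.05,
  "protocol": "default (60 \u00b5M donor, 0.4/1.2 mL, 0.6 mL samples q30min x 2 h, n=4)"
}
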