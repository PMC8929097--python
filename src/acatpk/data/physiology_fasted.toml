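# Fasted-state human GI physiology (nine compartments, stomach first).
# volume mL, radius cm, mean_transit_time h. absorption_scale_factor
# multiplies the intrinsic 2·Peff/R absorption rate constant.
[physiology]
small_intestine = ["duodenum", "jejunum1", "jejunum2", "ileum1", "ileum2", "ileum3"]

[[physiology.compartment]]
name = "stomach"
volume = 47.0
radius = 9.67
mean_transit_time = 0.25
ph = 1.3
absorption_scale_factor = 0.0

[[physiology.compartment]]
name = "duodenum"
volume = 42.0
radius = 1.6
mean_transit_time = 0.26
ph = 6.0
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "jejunum1"
volume = 154.0
radius = 1.53
mean_transit_time = 0.95
ph = 6.2
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "jejunum2"
volume = 122.0
radius = 1.45
mean_transit_time = 0.76
ph = 6.4
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "ileum1"
volume = 94.0
radius = 1.33
mean_transit_time = 0.59
ph = 6.6
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "ileum2"
volume = 71.0
radius = 1.21
mean_transit_time = 0.43
ph = 6.9
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "ileum3"
volume = 49.0
radius = 1.08
mean_transit_time = 0.31
ph = 7.4
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "caecum"
volume = 47.0
radius = 3.39
mean_transit_time = 4.5
ph = 6.4
absorption_scale_factor = 1.0

[[physiology.compartment]]
name = "asc_colon"
volume = 50.0
radius = 2.41
mean_transit_time = 13.5
ph = 6.8
absorption_scale_factor = 1.0
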