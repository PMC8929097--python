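replicate,time_min,receiver_conc_uM
1,0,0
1,30,0.561535
1,60,0.883702
1,90,0.995713
1,120,1.00056
2,0,0
2,30,0.523899
2,60,0.891581
2,90,1.0286
2,120,1.01411
3,0,0
3,30,0.576662
3,60,0.940038
3,90,0.955629
3,120,0.889898
4,0,0
4,30,0.556844
4,60,0.882946
4,90,0.974909
4,120,0.988017
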