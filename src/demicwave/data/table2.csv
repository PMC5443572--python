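model,code,r,slope,se_slope,speed,se_speed,range_lo,range_hi
Geissenklosterle,GEISSE,0.657,1.5068,0.4191,0.6637,0.1816,0.48,0.85
Krems-Hundssteig,KRE-H,0.568,0.9834,0.3683,1.0168,0.3808,0.64,1.40
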