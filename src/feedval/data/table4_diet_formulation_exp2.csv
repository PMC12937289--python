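ingredient,esbm_diet_pct
Enzymolytic soybean meal,40.00
Cornstarch,44.45
Sucrose,10.00
Soybean oil,3.00
Dicalcium phosphate,1.10
Limestone,0.70
Sodium chloride,0.30
Titanium dioxide,0.20
Vitamin-mineral premix,0.25
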