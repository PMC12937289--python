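ingredient,corn_basal_pct,esbm_diet_pct
Corn,97.00,67.90
Enzymolytic soybean meal,0.00,29.10
Dicalcium phosphate,1.20,1.20
Limestone,1.00,1.00
Sodium chloride,0.30,0.30
Vitamin-mineral premix,0.50,0.50
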