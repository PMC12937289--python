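ingredient_id,basis,Ca,P,Cu,Zn,Fe,Mn,Na,Mg,K
ESBM 1,as_fed,0.31,0.75,8.22,38.92,226.36,45.03,1.48,0.36,1.97
ESBM 2,as_fed,0.32,0.67,11.90,53.97,280.93,40.08,0.04,0.32,2.22
ESBM 3,as_fed,0.37,0.63,13.10,50.18,262.05,37.27,0.05,0.31,2.13
ESBM 4,as_fed,0.34,0.64,11.32,48.20,208.14,114.63,0.10,0.35,2.15
ESBM 5,as_fed,0.37,0.54,9.94,57.15,212.60,42.68,0.04,0.19,0.99
ESBM 6,as_fed,0.30,0.61,11.12,45.21,335.90,31.78,0.62,0.35,2.08
ESBM 7,as_fed,0.31,0.60,12.84,47.17,400.96,38.54,0.07,0.27,2.05
ESBM 8,as_fed,0.47,0.72,11.33,53.82,256.53,35.63,0.01,0.50,2.43
ESBM 9,as_fed,0.27,0.51,10.46,40.90,198.56,26.31,1.60,0.27,1.78
ESBM 10,as_fed,0.27,0.54,10.32,40.52,231.85,27.30,0.99,0.28,1.87
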