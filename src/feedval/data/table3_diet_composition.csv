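diet_id,basis,DM,GE,CP,Ash,EE,Ca,P
corn basal,as_fed,86.94,14.96,7.35,3.41,3.04,0.73,0.43
ESBM 1,as_fed,89.61,15.78,21.65,5.45,2.31,0.83,0.60
ESBM 2,as_fed,88.82,15.70,20.35,5.03,2.27,0.83,0.57
ESBM 3,as_fed,88.88,15.85,19.15,5.04,2.32,0.88,0.55
ESBM 4,as_fed,88.16,15.92,19.62,4.98,2.33,0.88,0.57
ESBM 5,as_fed,89.01,16.43,21.58,4.16,2.14,0.85,0.53
ESBM 6,as_fed,89.15,15.96,19.30,5.19,2.34,0.86,0.56
ESBM 7,as_fed,89.22,15.85,19.21,4.70,2.86,0.83,0.54
ESBM 8,as_fed,88.98,15.54,20.41,5.69,2.44,0.90,0.58
ESBM 9,as_fed,87.73,15.42,16.91,5.55,2.18,0.84,0.53
ESBM 10,as_fed,87.55,15.34,17.44,5.10,2.21,0.81,0.52
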