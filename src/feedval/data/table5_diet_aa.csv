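diet_id,basis,DM,Lys,Met,Thr,Trp,Val,Ile,Leu,Arg,His,Phe,Ala,Asp,Cys,Glu,Gly,Pro,Ser,Tyr,TAA
ESBM 1,as_fed,92.14,1.32,0.22,0.85,0.12,1.05,0.96,1.73,1.64,0.55,1.23,1.01,2.43,0.15,4.29,0.95,1.00,1.06,0.72,21.28
ESBM 2,as_fed,91.15,1.08,0.16,0.81,0.10,0.98,0.91,1.61,1.36,0.50,1.08,0.97,2.32,0.20,3.75,0.98,0.98,1.04,0.64,19.46
ESBM 3,as_fed,91.73,0.98,0.17,0.76,0.09,0.92,0.85,1.49,1.24,0.47,1.02,0.88,2.19,0.21,3.58,0.82,0.86,0.96,0.67,18.16
ESBM 4,as_fed,90.42,1.05,0.16,0.74,0.09,0.92,0.87,1.50,1.24,0.48,0.98,0.90,2.17,0.17,3.41,0.83,0.89,0.93,0.61,17.96
ESBM 5,as_fed,91.03,1.44,0.20,0.93,0.12,1.13,1.05,1.84,1.51,0.58,1.19,1.05,2.54,0.24,3.93,1.00,1.05,1.17,0.74,21.70
ESBM 6,as_fed,91.58,1.08,0.16,0.75,0.11,0.89,0.85,1.49,1.24,0.49,1.00,0.85,2.17,0.10,3.64,0.81,0.84,0.95,0.64,18.08
ESBM 7,as_fed,91.85,1.25,0.16,0.78,0.10,0.92,0.87,1.52,1.31,0.50,1.03,0.87,2.21,0.17,3.58,0.84,0.82,1.00,0.67,18.59
ESBM 8,as_fed,91.30,1.19,0.23,0.79,0.09,1.13,1.05,1.71,0.58,0.50,0.94,1.18,2.47,0.27,3.86,0.97,0.94,1.02,0.69,19.61
ESBM 9,as_fed,91.10,0.97,0.16,0.64,0.09,0.80,0.74,1.30,1.10,0.41,0.89,0.77,1.84,0.10,3.04,0.73,0.74,0.83,0.56,15.71
ESBM 10,as_fed,89.63,1.06,0.13,0.67,0.10,0.83,0.77,1.36,1.18,0.43,0.96,0.78,1.86,0.16,3.11,0.75,0.77,0.86,0.67,16.46
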