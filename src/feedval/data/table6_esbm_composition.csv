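ingredient_id,basis,DM,GE,CP,EE,CF,NDF,ADF,Ash,Starch,IDF,SDF,TDF,Lys,Met,Thr,Trp,Val,Ile,Leu,Arg,His,Phe,Ala,Asp,Cys,Glu,Gly,Pro,Ser,Tyr,TAA
ESBM 1,as_fed,95.82,18.16,58.60,0.56,4.42,10.07,8.83,9.26,1.40,5.85,18.45,24.30,3.42,0.56,2.16,0.55,2.73,2.53,4.33,4.30,1.40,3.05,2.57,6.26,0.43,10.95,2.41,2.39,2.65,1.94,54.62
ESBM 2,as_fed,92.79,18.07,52.21,0.70,4.60,14.34,7.21,6.42,2.34,3.95,17.95,21.90,2.74,0.40,2.01,0.57,2.45,2.33,3.98,3.50,1.26,2.64,2.35,5.80,0.57,9.36,2.41,2.39,2.53,1.74,49.02
ESBM 3,as_fed,93.53,17.74,49.01,0.84,6.09,12.97,10.72,6.63,2.04,4.30,17.45,21.75,2.43,0.33,1.79,0.62,2.13,2.07,3.54,2.95,1.12,2.39,1.95,5.23,0.43,8.37,1.89,2.18,2.23,1.60,43.27
ESBM 4,as_fed,90.53,17.54,48.30,1.30,5.84,12.97,9.98,6.59,1.78,3.55,18.60,22.15,2.70,0.39,1.86,0.63,2.29,2.19,3.74,3.12,1.20,2.44,2.19,5.36,0.45,8.70,2.05,2.22,2.36,1.61,45.49
ESBM 5,as_fed,93.13,18.76,55.78,0.81,8.87,17.72,13.67,3.89,1.90,5.25,29.45,34.70,3.59,0.39,2.24,0.61,2.74,2.57,4.43,3.70,1.40,2.91,2.51,5.97,0.63,9.52,2.41,2.47,2.84,1.94,52.86
ESBM 6,as_fed,93.62,17.79,48.19,0.92,4.70,14.94,7.66,7.63,3.91,11.40,10.50,21.90,2.72,0.35,1.75,0.47,2.19,2.13,3.64,3.06,1.17,2.61,1.99,5.06,0.24,8.53,1.91,2.13,2.19,1.88,44.01
ESBM 7,as_fed,94.45,18.20,47.73,3.05,5.13,11.98,7.34,6.14,6.63,4.10,18.05,22.15,2.98,0.27,1.77,0.64,2.23,2.06,3.55,3.07,1.16,2.37,1.99,4.98,0.48,8.10,1.93,2.11,2.21,1.58,43.49
ESBM 8,as_fed,93.13,17.27,52.93,0.70,5.20,11.37,9.67,8.54,0.82,2.95,8.80,11.75,2.80,0.44,1.77,0.42,2.58,2.47,3.92,2.90,1.13,2.07,2.56,5.61,0.72,8.58,2.18,2.14,2.26,1.63,46.15
ESBM 9,as_fed,89.48,16.06,40.29,0.50,7.07,12.33,10.33,8.66,10.24,7.20,16.60,23.80,2.35,0.32,1.45,0.51,1.91,1.79,3.11,2.58,0.93,2.22,1.70,4.17,0.25,6.91,1.68,1.82,1.86,1.58,37.13
ESBM 10,as_fed,88.32,16.22,43.12,0.21,5.80,10.62,9.52,7.46,6.28,3.70,17.15,20.85,2.69,0.29,1.63,0.56,2.07,1.99,3.33,2.96,1.05,2.22,1.94,4.87,0.41,7.72,1.82,1.90,2.07,1.50,41.00
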