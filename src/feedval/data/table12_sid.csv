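amino_acid,ESBM 1,ESBM 2,ESBM 3,ESBM 4,ESBM 5,ESBM 6,ESBM 7,ESBM 8,ESBM 9,ESBM 10,mean,sem,p_value,iaa_g_per_kg_dmi
Lys,76.43,78.40,72.11,81.80,92.12,73.87,95.64,71.19,88.03,87.61,81.72,2.11,0.01,5.09
Met,72.75,86.54,79.12,87.75,95.02,77.48,87.57,45.59,95.76,85.99,81.36,4.26,0.01,0.60
Thr,67.43,79.53,69.31,79.67,88.68,68.71,90.40,59.67,82.23,76.29,76.19,2.63,0.01,6.19
Trp,42.30,52.10,33.91,52.77,74.13,40.13,71.95,15.40,65.01,58.40,50.61,4.66,0.01,0.63
Val,72.20,83.92,76.22,84.42,90.79,70.45,92.99,69.39,88.23,83.65,81.23,1.83,0.01,5.09
Phe,79.16,87.63,80.44,88.20,92.26,81.20,94.55,67.25,90.23,87.93,84.89,1.89,0.01,3.48
Ile,74.27,86.68,78.29,87.19,92.34,73.65,94.56,70.50,88.89,84.74,83.11,1.71,0.01,4.36
Leu,75.94,86.38,78.76,86.97,91.49,73.33,93.63,71.74,89.39,85.49,83.31,1.61,0.01,6.38
Arg,89.30,95.65,91.60,96.54,99.88,89.37,100.80,68.38,97.50,96.71,92.57,1.83,0.01,7.49
His,75.68,86.92,79.14,86.56,93.26,77.11,95.61,64.27,88.61,85.12,83.23,2.14,0.01,2.19
Ala,69.46,78.91,73.90,82.17,89.40,68.49,92.75,70.44,86.59,80.60,79.27,2.32,0.01,8.23
Asp,62.56,82.84,71.88,79.70,91.25,62.20,91.91,53.27,81.17,79.24,75.60,3.24,0.01,9.69
Cys,57.36,79.42,69.98,73.32,89.54,47.48,92.03,64.28,86.24,82.21,74.19,3.78,0.01,1.20
Glu,72.24,83.55,73.75,79.25,90.76,75.96,94.11,63.54,84.81,80.22,79.82,2.65,0.01,12.90
Gly,73.58,79.89,73.84,86.55,93.25,68.20,98.71,64.75,92.45,84.12,81.53,4.20,0.01,21.04
Pro,146.51,140.12,143.16,155.95,146.14,114.86,165.99,119.87,163.27,163.93,145.98,12.59,0.08,84.34
Ser,74.12,86.97,77.41,84.87,92.84,73.89,94.10,67.68,84.57,83.01,81.95,2.09,0.01,6.65
Tyr,79.47,85.85,80.02,88.03,94.17,78.11,94.03,67.54,90.55,89.12,84.69,1.57,0.01,2.95
TAA,76.90,87.06,79.25,87.41,94.67,75.19,96.56,67.36,90.91,87.57,84.29,2.37,0.01,192.18
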