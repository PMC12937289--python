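ingredient_id,basis,Phytic acid,Glycinin,beta-Conglycinin,Trypsin inhibitor,Lectin
ESBM 1,as_fed,0.25,49.19,19.85,16.17,8.83
ESBM 2,as_fed,0.18,108.48,122.70,11.48,9.65
ESBM 3,as_fed,0.19,78.59,20.26,14.87,8.77
ESBM 4,as_fed,0.02,18.52,1.21,14.37,9.13
ESBM 5,as_fed,0.14,159.30,163.04,15.57,10.87
ESBM 6,as_fed,0.14,40.59,2.59,17.05,8.45
ESBM 7,as_fed,0.27,173.50,140.45,16.66,12.90
ESBM 8,as_fed,0.26,16.11,1.65,14.27,9.42
ESBM 9,as_fed,0.25,53.83,27.26,7.00,10.71
ESBM 10,as_fed,0.25,28.97,0.99,6.74,9.23
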