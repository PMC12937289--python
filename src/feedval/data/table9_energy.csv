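level,basis,quantity,ESBM 1,ESBM 2,ESBM 3,ESBM 4,ESBM 5,ESBM 6,ESBM 7,ESBM 8,ESBM 9,ESBM 10,mean,sem,p_value
diet,as_fed,DE,14.16,14.26,14.18,14.68,15.02,14.47,14.42,13.53,13.95,13.74,14.24,0.11,0.01
diet,as_fed,ME,13.78,13.82,13.72,14.35,14.75,13.98,14.07,13.08,13.60,13.52,13.87,0.12,0.01
diet,dry_matter,DE,14.78,15.37,15.16,16.22,16.13,15.46,15.00,14.53,15.59,15.56,15.38,0.11,0.01
diet,dry_matter,ME,14.38,14.90,14.66,15.85,15.84,14.94,14.63,14.04,15.20,15.31,14.98,0.13,0.01
diet,dry_matter,ME_DE_pct,97.32,96.93,96.76,97.76,98.22,96.63,97.56,96.62,97.51,98.38,97.37,0.47,0.11
ingredient,as_fed,DE,14.96,15.29,15.01,16.69,17.81,15.99,15.82,12.87,14.26,13.55,15.22,0.35,0.01
ingredient,as_fed,ME,14.25,14.39,14.03,16.15,17.48,14.93,15.21,11.91,13.66,13.37,14.54,0.40,0.01
ingredient,dry_matter,DE,15.61,16.48,16.04,18.43,19.13,17.08,16.75,13.82,15.94,15.34,16.46,0.38,0.01
ingredient,dry_matter,ME,14.88,15.51,15.01,17.84,18.77,15.94,16.10,12.79,15.27,15.14,15.73,0.43,0.01
ingredient,dry_matter,ME_DE_pct,95.30,94.14,93.53,96.81,98.16,93.38,96.15,92.44,95.84,98.68,95.44,1.54,0.11
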