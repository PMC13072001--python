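ingredient_id,dig_dm,dig_om,dig_ge,dig_cp,dig_ndf,dig_adf,de_mj_kg_dm,me_mj_kg_dm,ne_mj_kg_dm,me_de_pct,ne_me_pct
Barley-1,73.58,90.82,80.50,79.28,46.19,8.25,15.62,14.28,9.22,91.45,63.43
Barley-2,75.65,90.75,71.91,70.48,47.09,6.99,12.08,11.74,7.85,97.12,67.21
Barley-3,74.27,90.78,76.16,73.79,41.77,4.67,13.25,13.03,8.88,98.59,68.11
Barley-4,75.15,90.77,77.17,75.22,34.77,10.88,16.83,15.39,9.66,91.09,62.23
Barley-5,71.35,90.78,75.62,74.90,51.21,7.92,17.28,16.12,11.61,92.88,69.08
Barley-6,73.43,90.98,72.37,52.68,36.31,5.47,14.66,13.13,8.49,88.13,62.25
Barley-7,73.92,91.02,74.29,62.33,37.56,4.02,15.78,14.14,11.18,89.41,78.83
Barley-8,71.60,90.99,72.20,65.52,39.42,6.47,14.70,12.66,9.95,86.75,74.27
Barley-9,72.76,91.00,73.44,66.91,38.07,5.63,14.68,13.94,10.95,95.09,77.93
Barley-10,77.88,91.05,77.77,71.89,71.63,4.91,15.29,14.36,11.85,93.55,80.81
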