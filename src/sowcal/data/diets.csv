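diet_id,corn,soybean_meal,barley_id,barley_incl,dicalcium_phosphate,limestone,salt,premix,ge_mj_kg_dm,cp,ee,starch,ndf,adf,ash
Basal,81.43,15.62,,0.00,1.05,1.00,0.40,0.50,15.99,13.74,3.24,45.85,9.50,3.52,3.88
BL-1,57.18,10.97,Barley-1,28.90,1.05,1.00,0.40,0.50,15.95,14.10,2.87,42.98,12.60,4.03,3.81
BL-2,57.18,10.97,Barley-2,28.90,1.05,1.00,0.40,0.50,15.99,14.06,2.90,47.50,13.33,3.96,3.95
BL-3,57.18,10.97,Barley-3,28.90,1.05,1.00,0.40,0.50,15.91,14.78,2.70,45.38,12.74,3.64,4.22
BL-4,57.18,10.97,Barley-4,28.90,1.05,1.00,0.40,0.50,16.55,14.20,2.59,47.27,13.14,3.94,4.13
BL-5,57.18,10.97,Barley-5,28.90,1.05,1.00,0.40,0.50,15.84,13.83,2.65,47.09,13.92,4.52,3.77
BL-6,57.18,10.97,Barley-6,28.90,1.05,1.00,0.40,0.50,16.13,14.35,2.80,45.81,12.03,3.66,3.88
BL-7,57.18,10.97,Barley-7,28.90,1.05,1.00,0.40,0.50,16.08,14.83,2.87,45.52,11.15,3.25,3.99
BL-8,57.18,10.97,Barley-8,28.90,1.05,1.00,0.40,0.50,15.85,14.34,3.00,47.33,13.50,3.92,4.00
BL-9,57.18,10.97,Barley-9,28.90,1.05,1.00,0.40,0.50,15.89,14.26,2.77,45.67,13.11,3.80,4.13
BL-10,57.18,10.97,Barley-10,28.90,1.05,1.00,0.40,0.50,15.80,13.99,2.36,48.79,12.83,3.85,3.28
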