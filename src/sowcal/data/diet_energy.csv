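diet_id,bw_kg,dmi_kg_d,me_intake,thp,fhp,rep,rel,re,rq_fed,rq_fasted,de_mj_kg_dm,me_mj_kg_dm,ne_mj_kg_dm,ue_pct_de,ch4_pct_de,me_de_pct,ne_me_pct
Basal,215.78,2.11,540,438,348,73,39,111,0.99,0.81,15.62,14.37,12.23,7.12,0.93,91.95,84.79
BL-1,235.13,2.21,528,445,357,72,-35,37,0.93,0.76,15.53,14.35,11.98,6.90,0.70,92.40,83.36
BL-2,235.13,2.30,519,450,368,55,-25,30,0.93,0.77,14.50,13.56,11.42,5.53,0.98,93.49,84.23
BL-3,226.83,2.22,530,470,369,65,-33,32,0.93,0.76,14.84,13.96,11.84,4.97,0.98,94.05,84.80
BL-4,227.07,2.08,523,476,349,72,-30,42,1.00,0.83,15.88,14.69,12.16,6.56,0.96,92.48,82.72
BL-5,221.80,2.13,512,463,356,73,-44,29,1.00,0.83,15.13,13.78,11.50,8.14,0.78,91.08,83.23
BL-6,188.13,1.86,509,464,361,79,-11,68,0.97,0.80,15.00,13.85,11.65,6.78,0.98,92.24,83.91
BL-7,194.30,1.90,518,408,356,81,57,138,0.98,0.78,15.32,14.16,12.75,6.61,0.96,92.42,89.92
BL-8,192.17,1.91,507,423,362,76,35,111,0.96,0.78,15.01,13.71,12.24,7.74,0.89,91.37,88.82
BL-9,202.20,1.99,524,415,361,73,37,109,1.00,0.81,15.00,14.10,12.65,4.96,1.04,93.99,89.63
BL-10,199.53,1.98,531,425,380,72,56,128,0.99,0.81,15.18,14.23,13.02,5.56,0.73,93.71,91.26
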