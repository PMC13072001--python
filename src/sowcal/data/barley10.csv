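sample_id,dm,cp,ndf,adf,ash,ee,starch,idf,sdf,tdf,ca,p,lys,met,thr,val,ile,leu,trp,phe,his,arg,pro,tyr,ser,gly,asp,ala,cys,glu
Barley-1,89.30,10.87,21.79,4.30,2.15,2.34,57.69,12.99,5.09,18.09,0.04,0.34,0.36,0.13,0.30,0.47,0.32,0.60,0.14,0.56,0.19,0.46,0.92,0.33,0.36,0.36,0.53,0.37,0.15,1.87
Barley-2,91.22,14.07,29.38,6.07,2.63,2.13,57.71,16.97,5.08,22.06,0.04,0.32,0.50,0.11,0.46,0.70,0.47,0.97,0.17,0.87,0.30,0.66,1.59,0.54,0.57,0.55,0.70,0.56,0.20,3.09
Barley-3,89.90,12.32,23.16,4.79,2.78,2.16,48.60,13.23,4.95,18.18,0.05,0.38,0.43,0.17,0.39,0.64,0.44,0.85,0.17,0.64,0.29,0.55,1.37,0.25,0.49,0.47,0.69,0.50,0.21,3.04
Barley-4,89.70,9.29,39.54,4.73,2.59,1.54,48.87,13.54,6.03,19.57,0.04,0.26,0.31,0.12,0.42,0.61,0.43,0.84,0.16,0.69,0.29,0.36,1.35,0.33,0.50,0.47,0.71,0.52,0.19,2.80
Barley-5,89.70,10.84,22.48,4.62,2.48,1.61,56.02,14.05,5.77,19.82,0.04,0.26,0.36,0.16,0.27,0.39,0.25,0.53,0.11,0.40,0.17,0.46,0.79,0.22,0.31,0.33,0.51,0.35,0.16,1.56
Barley-6,89.30,13.06,26.75,4.80,2.54,2.03,50.60,14.98,4.77,19.75,0.05,0.36,0.37,0.15,0.31,0.50,0.34,0.65,0.16,0.51,0.21,0.48,1.11,0.24,0.39,0.38,0.47,0.39,0.19,2.10
Barley-7,91.22,12.98,27.38,4.31,2.73,2.22,55.93,14.11,5.23,19.33,0.05,0.31,0.45,0.13,0.29,0.44,0.32,0.63,0.14,0.57,0.20,0.58,0.93,0.34,0.35,0.38,0.53,0.38,0.20,1.76
Barley-8,89.90,10.88,36.59,4.92,2.10,2.32,52.26,14.45,5.66,20.11,0.08,0.30,0.36,0.09,0.34,0.50,0.35,0.66,0.14,0.53,0.21,0.44,1.12,0.25,0.41,0.40,0.60,0.40,0.16,2.19
Barley-9,88.70,14.26,38.36,5.93,3.62,2.12,44.01,17.35,6.12,23.46,0.05,0.25,0.47,0.19,0.44,0.65,0.45,0.93,0.17,0.80,0.28,0.61,1.50,0.46,0.53,0.53,0.68,0.52,0.24,3.06
Barley-10,88.70,12.62,27.87,3.65,2.47,2.20,55.82,12.02,4.80,16.82,0.04,0.22,0.37,0.15,0.31,0.50,0.36,0.68,0.15,0.72,0.72,0.48,1.09,0.49,0.39,0.38,0.51,0.40,0.19,2.10
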