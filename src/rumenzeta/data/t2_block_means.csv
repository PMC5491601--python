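ssa_m2_per_g,st_mN_per_m,replicate,t2_h,c2,c3,c4,ic4,c5,ic5
3.37,53.95,1,6,5.06,3.50,2.78,0.71,0.71,0.74
3.37,46.09,1,6,6.94,3.90,3.37,0.59,0.59,0.93
3.37,42.78,1,6,6.98,3.76,3.23,0.56,0.56,0.91
3.37,36.07,1,6,6.29,4.10,3.58,0.62,0.62,1.05
3.73,53.95,1,6,4.25,3.45,2.79,0.58,0.58,0.81
3.73,46.09,1,6,6.24,3.84,3.25,0.60,0.60,0.90
3.73,42.78,1,6,4.96,3.50,3.30,0.59,0.59,0.96
3.73,36.07,1,6,5.60,4.03,3.69,0.63,0.63,1.12
4.44,53.95,1,6,5.12,3.64,3.20,0.40,0.40,0.88
4.44,46.09,1,6,5.94,4.00,3.63,0.57,0.57,0.99
4.44,42.78,1,6,4.30,3.69,3.57,0.50,0.50,1.00
4.44,36.07,1,6,5.86,4.16,3.85,0.59,0.59,1.11
3.37,53.95,1,12,6.57,4.56,3.58,0.41,0.41,0.96
3.37,46.09,1,12,7.37,4.76,4.21,0.72,0.72,1.24
3.37,42.78,1,12,8.80,5.06,4.43,0.70,0.70,1.27
3.37,36.07,1,12,9.70,5.27,4.52,0.72,0.72,1.44
3.73,53.95,1,12,6.12,4.26,3.33,0.40,0.40,0.90
3.73,46.09,1,12,5.49,4.30,3.70,0.64,0.64,1.10
3.73,42.78,1,12,6.77,4.61,4.32,0.69,0.69,1.25
3.73,36.07,1,12,9.49,5.30,4.60,0.72,0.72,1.40
4.44,53.95,1,12,5.07,3.91,3.02,0.51,0.51,0.83
4.44,46.09,1,12,6.49,4.52,3.81,0.63,0.63,1.09
4.44,42.78,1,12,7.85,4.71,4.02,0.65,0.65,1.14
4.44,36.07,1,12,6.73,4.65,4.12,0.67,0.67,1.30
3.37,53.95,1,24,18.69,10.03,9.15,1.05,1.05,1.54
3.37,46.09,1,24,17.97,9.68,9.68,1.20,1.20,1.73
3.37,42.78,1,24,19.99,10.61,11.03,1.35,1.35,2.08
3.37,36.07,1,24,17.38,8.68,9.30,1.25,1.25,2.24
3.73,53.95,1,24,17.74,9.93,8.92,1.20,1.20,1.55
3.73,46.09,1,24,16.57,9.23,8.57,1.05,1.05,1.50
3.73,42.78,1,24,22.18,12.13,12.07,1.47,1.47,2.22
3.73,36.07,1,24,20.88,11.00,11.94,1.65,1.65,2.75
4.44,53.95,1,24,17.55,10.88,9.17,1.13,1.13,1.46
4.44,46.09,1,24,20.38,11.18,9.33,1.18,1.18,1.57
4.44,42.78,1,24,20.23,10.76,9.48,1.18,1.18,1.70
4.44,36.07,1,24,18.43,9.14,8.54,1.21,1.21,1.77
3.37,53.95,1,48,13.18,8.10,6.48,1.05,1.05,1.69
3.37,46.09,1,48,14.70,7.83,6.66,1.10,1.10,1.73
3.37,42.78,1,48,14.91,8.76,7.80,1.25,1.25,2.05
3.37,36.07,1,48,14.07,8.95,8.34,1.31,1.31,2.28
3.73,53.95,1,48,14.36,9.90,8.23,1.34,1.34,2.15
3.73,46.09,1,48,11.74,8.57,7.29,1.15,1.15,1.86
3.73,42.78,1,48,14.50,10.20,8.73,1.41,1.41,2.24
3.73,36.07,1,48,12.70,8.71,6.97,1.10,1.10,1.77
4.44,53.95,1,48,14.24,9.96,7.27,1.11,1.11,1.77
4.44,46.09,1,48,12.35,9.85,8.05,1.32,1.32,2.04
4.44,42.78,1,48,17.22,11.78,10.04,1.59,1.59,2.52
4.44,36.07,1,48,15.81,10.87,9.05,1.39,1.39,2.27
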