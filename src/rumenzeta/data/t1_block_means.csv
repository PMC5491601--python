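ssa_m2_per_g,st_mN_per_m,replicate,t1_h,mobility,mobility_std,zeta_mV,zeta_std,gamma_mN_per_m
3.37,53.95,1,6,-3.12,-0.05,-31.92,-0.04,48.93
3.37,46.09,1,6,-3.35,-0.67,-34.44,-0.66,49.41
3.37,42.78,1,6,-3.44,-0.81,-35.29,-0.81,46.25
3.37,36.07,1,6,-3.14,-0.39,-32.20,-0.38,39.87
3.73,53.95,1,6,-3.21,-0.61,-32.94,-0.60,47.53
3.73,46.09,1,6,-3.06,-0.31,-31.41,-0.31,46.38
3.73,42.78,1,6,-3.27,-0.51,-33.58,-0.51,46.58
3.73,36.07,1,6,-3.44,-0.70,-35.27,-0.69,44.72
4.44,53.95,1,6,-3.22,-0.34,-33.02,-0.34,49.32
4.44,46.09,1,6,-3.32,-1.01,-32.92,-0.76,48.91
4.44,42.78,1,6,-3.48,-0.90,-35.71,-0.90,49.18
4.44,36.07,1,6,-3.37,-0.62,-34.56,-0.62,44.43
3.37,53.95,1,12,-3.21,-0.29,-32.98,-0.30,52.01
3.37,46.09,1,12,-3.25,-0.44,-33.40,-0.41,50.09
3.37,42.78,1,12,-3.33,-0.54,-34.17,-0.54,47.59
3.37,36.07,1,12,-3.22,-0.60,-33.12,-0.61,47.74
3.73,53.95,1,12,-2.94,0.06,-30.19,0.06,53.88
3.73,46.09,1,12,-2.99,-0.13,-30.69,-0.13,49.52
3.73,42.78,1,12,-3.20,-0.32,-32.80,-0.32,50.05
3.73,36.07,1,12,-3.13,0.06,-32.18,0.06,45.05
4.44,53.95,1,12,-3.35,-0.66,-34.36,-0.66,51.21
4.44,46.09,1,12,-3.09,-0.45,-31.77,-0.48,51.94
4.44,42.78,1,12,-3.49,-0.93,-35.82,-0.93,49.04
4.44,36.07,1,12,-3.13,-0.03,-32.10,-0.02,46.65
3.37,53.95,1,24,-2.70,0.98,-27.68,0.98,49.02
3.37,46.09,1,24,-2.48,1.49,-25.47,1.50,46.44
3.37,42.78,1,24,-2.41,1.74,-24.79,1.73,44.92
3.37,36.07,1,24,-2.38,1.49,-24.48,1.48,44.03
3.73,53.95,1,24,-2.95,0.05,-30.26,0.05,50.16
3.73,46.09,1,24,-2.67,0.66,-27.41,0.66,47.68
3.73,42.78,1,24,-3.07,-0.01,-31.54,-0.01,46.01
3.73,36.07,1,24,-3.06,0.24,-31.39,0.24,44.18
4.44,53.95,1,24,-2.79,0.73,-28.62,0.72,49.98
4.44,46.09,1,24,-2.85,0.15,-29.61,0.04,47.20
4.44,42.78,1,24,-2.97,0.36,-30.51,0.35,45.17
4.44,36.07,1,24,-3.15,-0.08,-32.31,-0.07,45.21
3.37,53.95,1,36,-2.38,1.79,-24.26,1.81,51.69
3.37,46.09,1,36,-2.55,1.31,-26.23,1.32,50.39
3.37,42.78,1,36,-2.72,0.98,-27.88,0.98,47.87
3.37,36.07,1,36,-2.84,0.35,-29.13,0.36,45.02
3.73,53.95,1,36,-2.52,1.12,-25.86,1.11,50.20
3.73,46.09,1,36,-2.70,0.59,-27.72,0.58,47.55
3.73,42.78,1,36,-2.77,0.74,-28.42,0.74,47.85
3.73,36.07,1,36,-2.94,0.53,-30.22,0.53,45.27
4.44,53.95,1,36,-2.72,0.89,-27.92,0.89,49.70
4.44,46.09,1,36,-2.31,1.49,-23.76,1.45,48.48
4.44,42.78,1,36,-2.54,1.44,-26.04,1.43,46.55
4.44,36.07,1,36,-2.61,1.27,-26.82,1.25,44.71
3.37,53.95,1,48,-3.85,-1.88,-39.67,-1.91,47.25
3.37,46.09,1,48,-3.81,-1.82,-38.90,-1.74,44.89
3.37,42.78,1,48,-3.72,-1.50,-38.14,-1.50,44.06
3.37,36.07,1,48,-3.67,-1.70,-37.61,-1.69,43.98
3.73,53.95,1,48,-3.23,-0.66,-33.19,-0.66,48.11
3.73,46.09,1,48,-3.20,-0.66,-32.86,-0.66,46.40
3.73,42.78,1,48,-3.32,-0.62,-34.09,-0.63,43.18
3.73,36.07,1,48,-3.85,-1.72,-39.51,-1.71,41.96
4.44,53.95,1,48,-3.10,-0.05,-31.83,-0.05,46.33
4.44,46.09,1,48,-2.92,-0.01,-29.94,-0.04,45.21
4.44,42.78,1,48,-3.26,-0.37,-33.47,-0.36,43.56
4.44,36.07,1,48,-3.37,-0.63,-34.62,-0.63,42.30
3.37,53.95,1,72,-3.31,-0.54,-34.01,-0.55,46.95
3.37,46.09,1,72,-3.03,0.12,-31.71,0.00,45.34
3.37,42.78,1,72,-3.06,0.14,-31.39,0.13,44.44
3.37,36.07,1,72,-2.64,0.85,-27.11,0.85,44.18
3.73,53.95,1,72,-2.95,0.05,-30.25,0.05,45.17
3.73,46.09,1,72,-2.99,-0.14,-30.71,-0.14,44.97
3.73,42.78,1,72,-2.78,0.72,-28.47,0.73,44.21
3.73,36.07,1,72,-2.52,1.58,-25.87,1.58,42.71
4.44,53.95,1,72,-3.31,-0.58,-33.99,-0.57,45.78
4.44,46.09,1,72,-2.98,-0.16,-30.59,-0.20,45.65
4.44,42.78,1,72,-2.96,0.40,-30.32,0.40,44.97
4.44,36.07,1,72,-3.08,0.09,-31.64,0.09,44.60
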