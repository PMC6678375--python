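sample,lai_mean,lai_sd,lai_e_mean,lai_e_sd,canopy_cover_mean,canopy_cover_sd,crown_cover_mean,crown_cover_sd,phi_mean,phi_sd,omega0_mean,omega0_sd
B1C15A,3.08,0.68,2.79,0.76,0.836,0.094,0.962,0.061,0.134,0.050,0.951,0.067
B1C16A,2.78,0.96,2.55,1.12,0.755,0.116,0.879,0.107,0.142,0.050,0.851,0.131
B1C17A,3.60,0.69,3.19,0.36,0.868,0.063,0.957,0.060,0.094,0.035,0.904,0.122
B1C18A,3.47,0.82,3.18,1.08,0.843,0.094,0.932,0.077,0.097,0.036,0.887,0.127
B1C1A,3.62,0.68,3.32,0.98,0.863,0.069,0.945,0.050,0.088,0.032,0.888,0.100
B1C25A,4.56,0.73,4.08,0.73,0.939,0.037,0.994,0.014,0.056,0.026,0.986,0.034
B1C26B,2.55,0.47,2.33,0.69,0.730,0.074,0.863,0.086,0.153,0.050,0.814,0.112
B1C27A,3.31,0.70,3.04,0.97,0.834,0.105,0.928,0.087,0.104,0.030,0.894,0.121
B1C2A,3.50,1.16,3.20,1.33,0.827,0.129,0.915,0.111,0.099,0.051,0.875,0.146
B1C36A,3.68,0.20,3.32,0.56,0.867,0.046,0.946,0.054,0.080,0.011,0.872,0.117
B1C3A,4.29,1.20,3.92,1.43,0.881,0.139,0.935,0.141,0.059,0.031,0.905,0.195
B1C45A,2.65,0.45,2.41,0.67,0.772,0.079,0.913,0.070,0.156,0.030,0.886,0.092
B1C4A,2.40,0.29,2.18,0.51,0.668,0.085,0.775,0.112,0.135,0.036,0.723,0.116
B2C12A,3.06,0.48,2.84,0.75,0.847,0.061,0.980,0.041,0.136,0.035,0.972,0.056
B2C13A,3.33,0.49,3.03,0.56,0.875,0.046,0.991,0.017,0.117,0.035,0.986,0.028
B2C14A,2.61,0.98,2.46,1.13,0.727,0.196,0.853,0.209,0.152,0.053,0.863,0.158
B2C15A,2.30,0.29,2.12,0.48,0.720,0.059,0.888,0.068,0.188,0.035,0.864,0.073
B2C16A,2.81,0.51,2.59,0.66,0.791,0.114,0.919,0.122,0.140,0.021,0.902,0.132
B2C17A,2.88,0.89,2.63,0.89,0.770,0.145,0.885,0.126,0.134,0.053,0.871,0.139
B2C1A,3.27,0.49,2.99,0.55,0.867,0.048,0.984,0.031,0.119,0.028,0.974,0.052
B2C22A,2.91,0.36,2.69,0.60,0.816,0.059,0.947,0.058,0.138,0.027,0.913,0.085
B2C24A,2.56,0.76,2.36,0.81,0.719,0.150,0.849,0.159,0.153,0.063,0.828,0.154
B2C25A,3.02,0.63,2.80,0.83,0.796,0.120,0.901,0.122,0.118,0.030,0.865,0.140
B2C27A,3.13,0.64,3.13,0.64,0.849,0.060,0.976,0.036,0.131,0.038,0.962,0.055
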