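label,set,H,C,N,O,Na,Mg,P,S,Cl,Ar,K,Ca,density
HU-950,training,0,0,0.755,0.232,0,0,0,0,0,0.013,0,0,0.0279
HU-120,training,0.103,0.105,0.031,0.749,0.002,0,0.002,0.003,0.003,0,0.002,0,0.4810
HU-83,training,0.116,0.681,0.002,0.198,0.001,0,0,0.001,0.001,0,0,0,0.9572
HU-53,training,0.113,0.567,0.009,0.308,0.001,0,0,0.001,0.001,0,0,0,0.9581
HU7,training,0.108,0.356,0.022,0.509,0.000,0,0.001,0.002,0.002,0,0,0,1.0108
HU18,training,0.106,0.284,0.026,0.578,0.000,0,0.001,0.002,0.002,0,0.001,0,1.0030
HU80,training,0.103,0.134,0.030,0.723,0.002,0,0.002,0.002,0.002,0,0.002,0,1.0591
HU120,training,0.094,0.207,0.062,0.622,0.006,0,0.000,0.006,0.003,0,0.000,0,1.1187
HU200,training,0.095,0.455,0.025,0.355,0.001,0,0.021,0.001,0.001,0,0.001,0.045,1.1111
HU300,training,0.089,0.423,0.027,0.363,0.001,0,0.030,0.001,0.001,0,0.001,0.064,1.1644
HU400,training,0.082,0.391,0.029,0.372,0.001,0,0.039,0.001,0.001,0,0.001,0.083,1.2236
HU500,training,0.076,0.361,0.030,0.380,0.001,0.001,0.047,0.002,0.001,0,0,0.101,1.2828
HU600,training,0.071,0.335,0.032,0.387,0.001,0.001,0.054,0.002,0,0,0,0.117,1.3420
HU700,training,0.066,0.310,0.033,0.394,0.001,0.001,0.061,0.002,0,0,0,0.132,1.4012
HU800,training,0.061,0.287,0.035,0.400,0.001,0.001,0.067,0.002,0,0,0,0.146,1.4604
HU900,training,0.056,0.265,0.036,0.405,0.001,0.002,0.073,0.003,0,0,0,0.159,1.5196
HU1000,training,0.052,0.246,0.037,0.411,0.001,0.002,0.078,0.003,0,0,0,0.170,1.5788
HU1100,training,0.049,0.227,0.038,0.416,0.001,0.002,0.083,0.003,0,0,0,0.181,1.6380
HU1200,training,0.045,0.210,0.039,0.420,0.001,0.002,0.088,0.003,0,0,0,0.192,1.6972
HU1300,training,0.042,0.194,0.040,0.425,0.001,0.002,0.092,0.003,0,0,0,0.201,1.7564
HU1400,training,0.039,0.179,0.041,0.429,0.001,0.002,0.096,0.003,0,0,0,0.210,1.8156
HU1500,training,0.036,0.165,0.042,0.432,0.001,0.002,0.100,0.003,0,0,0,0.219,1.8748
HU1600,training,0.034,0.155,0.042,0.435,0.001,0.002,0.103,0.003,0,0,0,0.225,1.9340
Air,testing,0,0.0001,0.755,0.231,0,0,0,0,0,0.012,0,0,0.0012
Lung,testing,0.101,0.102,0.028,0.757,0.001,0.0007,0.0008,0.002,0.002,0,0.001,0.00009,1.05
Soft Tissue,testing,0.104,0.232,0.024,0.630,0.001,0.0001,0.001,0.002,0.001,0,0.002,0.0002,1.00
Cortical Bone,testing,0.047,0.144,0.042,0.446,0,0.002,0.105,0.003,0,0,0,0.209,1.85
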