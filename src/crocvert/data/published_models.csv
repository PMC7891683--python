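response,predictor_id,coefficient,elevation,slope,r_squared,p_value_max,slope_ci_low,slope_ci_high,n
SVL,C2,,1.472,0.999,0.972,0.001,0.936,1.066,30
SVL,C3-7ave,,1.710,0.961,0.980,0.001,0.909,1.015,30
SVL,C8-D2ave,,1.735,0.953,0.985,0.001,0.909,0.999,30
SVL,D3-10ave,,1.626,0.990,0.981,0.001,0.939,1.043,30
SVL,D11-14ave,,1.640,0.974,0.980,0.001,0.922,1.029,30
SVL,D15,,1.717,0.956,0.978,0.001,0.903,1.011,30
SVL,S1-2ave,,1.630,0.950,0.978,0.001,0.898,1.006,30
SVL,Ca1,,1.681,1.001,0.968,0.001,0.934,1.072,30
SVL,Ca2-4ave,,1.591,1.011,0.975,0.001,0.951,1.075,30
SVL,Ca5-10ave,,1.589,0.984,0.974,0.001,0.924,1.047,30
SVL,C2-9sum,,0.810,0.966,0.981,0.001,0.916,1.018,30
SVL,D1-15sum,,0.495,0.980,0.983,0.001,0.931,1.031,30
SVL,C2-D15sum,,0.329,0.976,0.984,0.001,0.929,1.025,30
SVL,C2-Ca10sum,1.329,,0.980,,0.001,,,30
TL,C2,,1.751,1.002,0.955,0.001,0.923,1.087,30
TL,C3-7ave,,1.990,0.963,0.962,0.001,0.894,1.039,30
TL,C8-D2ave,,2.015,0.956,0.970,0.001,0.894,1.022,30
TL,D3-10ave,,1.906,0.993,0.972,0.001,0.930,1.059,30
TL,D11-14ave,,1.920,0.976,0.977,0.001,0.920,1.036,30
TL,D15,,1.997,0.958,0.971,0.001,0.897,1.024,30
TL,S1-2ave,,1.910,0.953,0.972,0.001,0.893,1.017,30
TL,Ca1,,1.961,1.003,0.953,0.001,0.923,1.091,30
TL,Ca2-4ave,,1.871,1.014,0.960,0.001,0.939,1.095,30
TL,Ca5-10ave,,1.868,0.987,0.959,0.001,0.912,1.067,30
TL,C2-9sum,,1.088,0.969,0.964,0.001,0.900,1.042,30
TL,D1-15sum,,0.771,0.982,0.974,0.001,0.923,1.045,30
TL,C2-D15sum,,0.605,0.978,0.973,0.001,0.918,1.043,30
TL,C2-Ca10sum,2.504,,0.983,,0.001,,,30
MAXTL,C2,,1.649,1.220,0.835,0.001,0.935,1.592,13
MAXTL,C3-7ave,,1.879,1.215,0.886,0.001,0.972,1.517,13
MAXTL,C8-D2ave,,1.937,1.190,0.878,0.001,0.946,1.497,13
MAXTL,D3-10ave,,1.991,1.103,0.847,0.001,0.853,1.427,13
MAXTL,D11-14ave,,1.936,1.134,0.863,0.001,0.889,1.446,13
MAXTL,D15,,1.859,1.236,0.848,0.001,0.957,1.597,13
MAXTL,S1-2ave,,1.726,1.243,0.832,0.001,0.951,1.626,13
MAXTL,Ca1,,1.853,1.255,0.870,0.001,0.990,1.590,13
MAXTL,Ca2-4ave,,1.761,1.255,0.880,0.001,1.000,1.576,13
MAXTL,Ca5-10ave,,1.678,1.275,0.860,0.001,0.997,1.631,13
MAXTL,C2-9sum,,0.749,1.218,0.882,0.001,0.972,1.527,13
MAXTL,D1-15sum,,0.633,1.129,0.858,0.001,0.881,1.446,13
MAXTL,C2-D15sum,,0.344,1.159,0.868,0.001,0.913,1.472,13
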