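{
 "sha256": "9de4d05eef77b13a47d753a24351f6022fda02a3e2885244a9032c01918e5af8",
 "models": [
  {
   "cultivar": "C. dactylon",
   "degree": 2,
   "backend": "quadratic",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.5856,
    0.06925,
    -0.006143,
    -0.0008586,
    0.0006574,
    -0.0007847
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.8177
  },
  {
   "cultivar": "C. dactylon",
   "degree": 5,
   "backend": "quintic_bisquare",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    0.4026,
    0.02444,
    -0.133,
    -0.0291,
    0.05145,
    -0.01535,
    0.002361,
    -0.002139,
    -0.002076,
    0.001802,
    -6.199e-05,
    -7.613e-06,
    0.0002068,
    -0.0001705,
    2.974e-05,
    5.357e-07,
    5.886e-07,
    -2.712e-06,
    1.219e-06,
    1.018e-06,
    -5.966e-07
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9166
  },
  {
   "cultivar": "C. dactylon",
   "degree": 5,
   "backend": "quintic_bpann",
   "normalizer": 40.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.2789,
    15.74,
    -11.43,
    -88.16,
    31.27,
    34.83,
    180.4,
    0.5264,
    -128.8,
    -3.322,
    -139.0,
    -163.4,
    510.2,
    -462.2,
    206.5,
    32.55,
    124.5,
    -312.5,
    248.7,
    -16.93,
    -59.17
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9813
  },
  {
   "cultivar": "Savannah",
   "degree": 2,
   "backend": "quadratic",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.5168,
    0.06924,
    -0.01989,
    -0.000934,
    0.001138,
    -0.0007981
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.7617
  },
  {
   "cultivar": "Savannah",
   "degree": 5,
   "backend": "quintic_bisquare",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    0.3523,
    0.04868,
    -0.1349,
    -0.0311,
    0.04712,
    -0.01236,
    0.002363,
    -0.001472,
    -0.002595,
    0.001872,
    -6.187e-05,
    -9.422e-06,
    0.0001502,
    -7.953e-05,
    -9.526e-06,
    5.348e-07,
    5.833e-07,
    -2.575e-06,
    2.423e-06,
    -1.543e-06,
    7.051e-07
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9301
  },
  {
   "cultivar": "Savannah",
   "degree": 5,
   "backend": "quintic_bpann",
   "normalizer": 40.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.1454,
    6.803,
    -3.249,
    -67.57,
    66.13,
    -26.76,
    192.9,
    -132.7,
    -75.01,
    99.66,
    -198.7,
    -14.87,
    537.8,
    -577.8,
    155.0,
    67.97,
    78.26,
    -403.7,
    414.8,
    -104.4,
    -13.94
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9507
  },
  {
   "cultivar": "Princess VII",
   "degree": 2,
   "backend": "quadratic",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.5152,
    0.0604,
    -0.01284,
    -0.0008349,
    0.001594,
    -0.001628
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.694
  },
  {
   "cultivar": "Princess VII",
   "degree": 5,
   "backend": "quintic_bisquare",
   "normalizer": 1.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.4047,
    0.5009,
    -0.3331,
    -0.08726,
    0.06563,
    -0.002549,
    0.004956,
    -0.001118,
    -0.00565,
    0.003324,
    -0.0001053,
    -0.0001238,
    0.0005272,
    -0.000455,
    0.0001159,
    7.324e-07,
    2.591e-06,
    -8.149e-06,
    6.436e-06,
    -4.407e-07,
    -7.708e-07
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9191
  },
  {
   "cultivar": "Princess VII",
   "degree": 5,
   "backend": "quintic_bpann",
   "normalizer": 40.0,
   "orientation": "warm_as_t1",
   "coefficients": [
    -0.6384,
    24.43,
    -13.54,
    -155.9,
    87.77,
    6.161,
    356.5,
    -117.0,
    -165.9,
    75.58,
    -322.3,
    -109.2,
    725.6,
    -663.2,
    212.7,
    99.58,
    134.6,
    -482.2,
    432.9,
    -94.28,
    -31.4
   ],
   "response_scale": 1.0,
   "r_squared_printed": 0.9439
  }
 ]
}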