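dmu,Z1,Z2,Z3,Z4,Z5,Z6,Z7,D1,D2,D3
H01,3.007,0,0.236,0.009,52.358,74.825,5.216,0,0,0
H02,2.333,0,0.212,0.005,51.553,76.480,5.415,0,0,0
H03,1.684,0,0.206,0.008,30.408,66.133,7.938,0,0,1
H04,2.829,0,0.226,0.009,46.499,59.338,4.658,0,1,0
H05,1.505,0,0.267,0.006,40.110,89.797,8.171,0,1,0
H06,2.890,0,0.233,0.009,43.147,78.426,6.634,0,0,0
H07,3.381,0,0.220,0.009,29.169,46.589,5.830,0,0,1
H08,1.593,0,0.206,0.008,58.652,58.667,3.651,0,0,1
H09,1.099,0,0.283,0.007,35.038,77.193,8.041,0,0,0
H10,3.589,0,0.312,0.006,30.440,44.220,5.302,0,0,0
H11,2.730,0,0.203,0.010,62.265,66.368,3.891,0,1,0
H12,1.756,1,0.239,0.007,44.046,70.901,5.875,1,0,0
H13,1.931,1,0.214,0.008,30.409,46.185,5.544,1,0,0
H14,2.338,0,0.203,0.009,51.453,58.712,4.165,0,1,0
H15,2.231,0,0.229,0.007,26.250,44.435,6.179,0,0,0
H16,2.280,0,0.298,0.006,27.962,51.014,6.659,0,0,1
H17,2.471,0,0.203,0.008,66.948,50.595,2.758,1,0,0
H18,3.968,0,0.223,0.007,43.168,48.638,4.112,0,0,1
H19,2.432,0,0.263,0.007,59.587,46.589,2.854,0,0,0
H20,1.616,1,0.258,0.007,64.705,63.834,3.601,0,0,1
H21,2.131,0,0.243,0.008,33.879,49.890,5.375,0,1,0
H22,1.972,0,0.242,0.007,31.600,59.487,6.871,0,0,0
H23,1.467,0,0.195,0.010,36.227,73.496,7.405,0,0,0
H24,1.845,1,0.230,0.009,34.946,64.599,6.747,0,0,1
H25,1.066,0,0.206,0.009,36.228,116.666,11.754,0,1,0
H26,1.386,0,0.211,0.008,38.796,55.184,5.192,0,0,1
H27,3.925,0,0.204,0.009,31.115,55.346,6.492,0,0,1
H28,1.606,0,0.235,0.006,38.880,84.011,7.887,0,0,1
H29,2.258,1,0.201,0.009,75.647,65.982,3.184,0,1,0
H30,1.342,1,0.221,0.008,23.079,56.569,8.946,1,0,0
H31,1.774,1,0.198,0.009,41.531,57.691,5.070,1,0,0
H32,3.842,0,0.195,0.009,5.930,8.383,5.160,1,0,0
H33,1.663,0,0.219,0.009,32.767,54.227,6.040,1,0,0
H34,1.803,1,0.220,0.008,34.837,68.048,7.130,1,0,0
H35,2.418,0,0.153,0.010,35.580,67.276,6.901,0,1,0
H36,1.995,0,0.190,0.010,67.119,61.997,3.371,0,0,1
H37,1.669,0,0.204,0.009,41.545,80.282,7.053,0,0,1
H38,0.337,0,0.275,0.006,35.637,35.361,3.622,0,1,0
H39,3.078,1,0.206,0.009,61.937,48.620,2.865,0,1,0
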