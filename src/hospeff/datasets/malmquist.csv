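dmu,tfpch,tech,ech,pech,sech
H01,1.027,1.027,1.000,1.000,1.000
H02,1.044,1.040,1.004,1.013,0.991
H03,0.989,1.027,0.964,0.964,1.000
H04,1.011,1.056,0.958,0.974,0.983
H05,1.000,1.063,0.941,0.933,1.009
H06,1.030,1.030,1.000,1.000,1.000
H07,0.978,1.018,0.961,0.956,1.004
H08,1.126,1.140,0.988,1.003,0.985
H09,1.034,1.089,0.949,0.959,0.989
H10,0.956,0.991,0.965,0.967,0.998
H11,1.065,1.062,1.002,1.000,1.002
H12,1.043,1.104,0.945,0.916,1.031
H13,0.988,1.071,0.923,0.881,1.047
H14,1.050,1.078,0.974,0.975,1.000
H15,1.180,1.083,1.089,1.000,1.089
H16,1.040,1.057,0.984,0.980,1.004
H17,1.244,1.162,1.071,1.055,1.015
H18,0.951,0.969,0.982,0.982,1.000
H19,1.111,1.059,1.049,1.051,0.998
H20,1.157,1.075,1.076,1.093,0.984
H21,1.020,1.098,0.929,0.922,1.007
H22,1.003,1.014,0.989,0.990,0.999
H23,0.988,1.051,0.940,0.974,0.964
H24,0.992,1.057,0.938,0.935,1.003
H25,0.983,1.063,0.925,0.920,1.005
H26,1.023,1.161,0.882,0.910,0.968
H27,1.015,1.015,1.000,1.000,1.000
H28,1.028,1.052,0.977,0.977,1.000
H29,1.009,1.167,0.864,0.870,0.993
H30,1.140,1.115,1.022,1.000,1.022
H31,1.023,1.153,0.887,0.890,0.997
H32,0.946,1.052,0.899,0.948,0.948
H33,1.065,1.088,0.979,0.967,1.012
H34,1.027,1.073,0.957,0.950,1.008
H35,0.988,1.038,0.951,0.957,0.994
H36,1.221,1.096,1.114,1.119,0.996
H37,1.048,1.062,0.987,0.981,1.006
H38,1.013,1.124,0.902,0.919,0.982
H39,1.099,1.082,1.016,1.004,1.011
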