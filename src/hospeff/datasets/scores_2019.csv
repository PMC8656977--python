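dmu,crs,vrs,se,lambda_sum,rts,peers
H01,1.0000,1.0000,1.0000,1.000,constant,H01
H02,0.8757,0.9355,0.9361,0.757,increasing,H01;H29
H03,0.5788,0.5809,0.9964,1.066,decreasing,H01;H06;H17
H04,0.8335,0.9008,0.9253,2.606,decreasing,H01;H06;H17
H05,0.6937,0.7193,0.9644,1.784,decreasing,H01;H17;H29
H06,1.0000,1.0000,1.0000,1.000,constant,H06
H07,0.7610,0.7611,0.9999,0.899,increasing,H06;H17;H27
H08,0.7998,0.8616,0.9284,0.488,increasing,H17;H29
H09,0.5032,0.6916,0.7276,0.257,increasing,H01;H29
H10,0.7005,0.8097,0.8651,0.628,increasing,H01;H06
H11,0.9711,1.0000,0.9711,2.503,decreasing,H01;H29
H12,0.6841,0.7041,0.9717,1.853,decreasing,H01;H17;H29
H13,0.4919,0.5164,0.9526,1.704,decreasing,H01;H17;H29
H14,0.8044,0.8316,0.9674,1.543,decreasing,H01;H17;H29
H15,0.5978,1.0000,0.5978,0.148,increasing,H01;H17
H16,0.6116,0.6566,0.9316,0.424,increasing,H01;H06;H17;H27
H17,1.0000,1.0000,1.0000,1.000,constant,H17
H18,0.9283,0.9284,0.9999,0.952,increasing,H01;H06;H17;H27
H19,0.7877,1.0000,0.7877,0.198,increasing,H29
H20,0.8554,0.9130,0.9368,0.496,increasing,H29
H21,0.5859,0.6049,0.9686,1.625,decreasing,H01;H06;H17
H22,0.5568,0.7902,0.7046,0.384,increasing,H01;H29
H23,0.5710,0.7293,0.7830,0.402,increasing,H01;H29
H24,0.6150,0.6200,0.9920,1.192,decreasing,H01;H06;H17
H25,0.6449,0.6773,0.9522,1.992,decreasing,H01;H06;H17
H26,0.5402,0.6522,0.8283,0.271,increasing,H01;H17;H29
H27,1.0000,1.0000,1.0000,1.000,constant,H27
H28,0.6864,0.6904,0.9942,1.162,decreasing,H01;H17;H29
H29,1.0000,1.0000,1.0000,1.000,constant,H29
H30,0.4230,0.4347,0.9732,1.326,decreasing,H01;H06;H17;H27
H31,0.6190,0.6268,0.9876,1.374,decreasing,H01;H17;H29
H32,0.6528,0.8069,0.8090,0.262,increasing,H17
H33,0.5172,0.5314,0.9733,1.819,decreasing,H01;H17;H29
H34,0.6240,0.6634,0.9406,2.401,decreasing,H01;H06;H17
H35,0.7885,0.8321,0.9476,2.195,decreasing,H01;H17;H27
H36,0.8954,0.9664,0.9266,0.474,increasing,H17;H29
H37,0.6928,0.6945,0.9975,1.045,decreasing,H01;H17;H29
H38,0.4905,0.5426,0.9039,0.408,increasing,H17;H29
H39,0.9009,0.9189,0.9804,1.692,decreasing,H01;H17;H29
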