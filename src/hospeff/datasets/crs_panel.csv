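dmu,2015,2016,2017,2018,2019,times_on_frontier
H01,1.0000,1.0000,1.0000,1.0000,1.0000,5
H02,0.8609,0.8171,0.9483,0.8566,0.8757,0
H03,0.6710,0.5200,0.6061,0.6387,0.5788,0
H04,0.9892,0.9467,1.0000,0.8697,0.8335,1
H05,0.8847,0.9104,0.7989,0.6869,0.6937,0
H06,1.0000,1.0000,1.0000,0.9949,1.0000,4
H07,0.8937,0.8655,1.0000,0.7976,0.7610,1
H08,0.8387,0.7920,0.8342,1.0000,0.7998,1
H09,0.6207,0.5978,0.4597,0.5405,0.5032,0
H10,0.8094,0.5673,0.7193,0.6834,0.7005,0
H11,0.9636,0.9703,0.8758,0.8404,0.9711,0
H12,0.8590,1.0000,0.8286,0.8046,0.6841,1
H13,0.6788,0.7282,0.8021,0.6283,0.4919,0
H14,0.8924,0.9118,0.8571,0.8816,0.8044,0
H15,0.4250,0.4168,0.5696,0.5120,0.5978,0
H16,0.6529,0.5120,0.6622,0.6916,0.6117,0
H17,0.7614,0.8100,0.7845,0.7383,1.0000,1
H18,1.0000,1.0000,1.0000,1.0000,0.9283,4
H19,0.6506,0.5587,0.5787,0.8754,0.7877,0
H20,0.6372,0.6950,0.6883,0.6357,0.8554,0
H21,0.7878,0.8121,0.8194,0.6458,0.5859,0
H22,0.5813,0.5952,0.5410,0.5941,0.5568,0
H23,0.7324,0.7477,0.7354,0.6090,0.5710,0
H24,0.7942,0.7042,0.7619,0.6534,0.6150,0
H25,0.8819,0.8364,0.8639,0.7498,0.6449,0
H26,0.8947,0.9689,0.9546,0.7677,0.5402,0
H27,1.0000,0.8351,1.0000,1.0000,1.0000,4
H28,0.7522,1.0000,0.7759,0.7087,0.6864,1
H29,0.9149,1.0000,1.0000,1.0000,1.0000,4
H30,0.7576,0.7841,0.8742,0.6742,0.4230,0
H31,1.0000,1.0000,0.9858,0.7607,0.6190,2
H32,1.0000,0.9215,0.9002,0.7568,0.6528,1
H33,0.5627,0.6035,0.6748,0.6207,0.5172,0
H34,0.7433,0.7831,0.8782,0.6837,0.6240,0
H35,0.9633,0.8248,0.9432,0.8768,0.7885,0
H36,0.5815,0.6057,1.0000,1.0000,0.8954,2
H37,0.7305,0.7879,0.6297,0.7137,0.6928,0
H38,0.7414,0.7510,0.6762,0.6281,0.4905,0
H39,0.8460,0.8598,0.8752,0.7652,0.9009,0
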