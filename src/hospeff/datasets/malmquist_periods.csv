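period,tfpch,tech,ech,pech,sech
2015-2016,1.015,1.030,0.985,0.989,0.997
2016-2017,1.099,1.065,1.032,1.013,1.019
2017-2018,0.952,1.014,0.939,0.950,0.988
2018-2019,1.103,1.178,0.936,0.936,1.001
2015-2019,1.042,1.072,0.973,0.972,1.001
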