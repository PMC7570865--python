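year,res_250m,res_300m,res_500m
2000,,,4.885
2001,1.670,,4.940
2002,0.824,,2.527
2003,1.341,,4.026
2004,0.656,,1.909
2005,1.066,1.333,3.191
2006,2.171,2.810,6.480
2007,2.125,2.767,6.724
2008,4.818,6.249,14.610
2009,0.931,1.149,2.714
2010,2.257,2.891,7.106
2011,2.810,3.680,9.056
2012,2.715,,8.642
2013,1.534,,4.723
2014,0.778,,2.192
2015,1.470,,4.356
2016,4.120,,12.685
2017,2.733,,8.253
all,1.195,1.625,3.612
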