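year,product,CE,OE,TE
2000,MCD45A1_C5.1,0.037,0.935,0.938
2000,MCD64A1_C6,0.000,1.000,1.000
2001,Fire_CCI_5.1,0.303,0.991,0.995
2001,MCD45A1_C5.1,1.000,1.000,1.004
2001,MCD64A1_C6,1.000,1.000,1.066
2002,Fire_CCI_5.1,0.095,0.402,0.465
2002,MCD45A1_C5.1,0.071,0.886,0.895
2002,MCD64A1_C6,0.166,0.446,0.556
2003,Fire_CCI_5.1,0.093,0.311,0.382
2003,MCD45A1_C5.1,0.113,0.558,0.614
2003,MCD64A1_C6,0.386,0.488,0.810
2004,Fire_CCI_5.1,0.064,0.335,0.380
2004,MCD45A1_C5.1,0.053,0.698,0.715
2004,MCD64A1_C6,0.174,0.383,0.513
2005,Fire_CCI_4.1,0.056,0.790,0.802
2005,Fire_CCI_5.1,0.089,0.470,0.522
2005,MCD45A1_C5.1,0.069,0.717,0.738
2005,MCD64A1_C6,0.151,0.345,0.461
2006,Fire_CCI_4.1,0.097,0.527,0.578
2006,Fire_CCI_5.1,0.147,0.609,0.676
2006,MCD45A1_C5.1,0.232,0.784,0.849
2006,MCD64A1_C6,0.424,0.830,0.956
2007,Fire_CCI_4.1,0.188,0.665,0.743
2007,Fire_CCI_5.1,0.155,0.303,0.431
2007,MCD45A1_C5.1,0.107,0.811,0.834
2007,MCD64A1_C6,0.316,0.476,0.718
2008,Fire_CCI_4.1,0.124,0.525,0.592
2008,Fire_CCI_5.1,0.292,0.438,0.670
2008,MCD45A1_C5.1,0.234,0.818,0.874
2008,MCD64A1_C6,0.573,0.712,1.099
2009,Fire_CCI_4.1,0.034,0.438,0.458
2009,Fire_CCI_5.1,0.062,0.247,0.297
2009,MCD45A1_C5.1,0.075,0.725,0.747
2009,MCD64A1_C6,0.094,0.491,0.544
2010,Fire_CCI_4.1,0.077,0.795,0.812
2010,Fire_CCI_5.1,0.110,0.454,0.521
2010,MCD45A1_C5.1,0.125,0.736,0.774
2010,MCD64A1_C6,0.214,0.697,0.779
2011,Fire_CCI_4.1,0.079,0.964,0.967
2011,Fire_CCI_5.1,0.230,0.543,0.679
2011,MCD45A1_C5.1,0.116,0.895,0.909
2011,MCD64A1_C6,0.221,0.901,0.929
2012,Fire_CCI_5.1,0.118,0.480,0.550
2012,MCD45A1_C5.1,0.113,0.759,0.790
2012,MCD64A1_C6,0.516,0.574,1.029
2013,Fire_CCI_5.1,0.055,0.398,0.433
2013,MCD45A1_C5.1,0.049,0.578,0.600
2013,MCD64A1_C6,0.219,0.631,0.734
2014,Fire_CCI_5.1,0.065,0.350,0.395
2014,MCD45A1_C5.1,0.065,0.549,0.580
2014,MCD64A1_C6,0.238,0.611,0.732
2015,Fire_CCI_5.1,0.041,0.415,0.440
2015,MCD45A1_C5.1,0.038,0.766,0.775
2015,MCD64A1_C6,0.155,0.478,0.574
2016,Fire_CCI_5.1,0.101,0.470,0.530
2016,MCD45A1_C5.1,0.055,0.709,0.726
2016,MCD64A1_C6,0.203,0.558,0.671
2017,Fire_CCI_5.1,0.073,0.396,0.444
2017,MCD64A1_C6,0.111,0.529,0.588
all,Fire_CCI_4.1,0.059,0.675,0.695
all,Fire_CCI_5.1,0.075,0.390,0.439
all,MCD45A1_C5.1,0.066,0.737,0.756
all,MCD64A1_C6,0.178,0.480,0.593
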