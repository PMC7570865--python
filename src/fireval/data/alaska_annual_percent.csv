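year,AFS_ha,Fire_CCI_4.1,Fire_CCI_5.1,MCD45A1_C5.1,MCD64A1_C6
2000,304631.50,,,6.79,0.00
2001,88658.25,,1.23,0.40,6.64
2002,856081.50,,66.06,12.30,66.44
2003,241061.25,,75.92,49.76,83.36
2004,2712368.00,,71.02,31.88,74.73
2005,1896684.75,22.23,58.17,30.40,77.11
2006,108509.00,52.42,45.83,28.18,29.60
2007,263894.00,41.26,82.46,21.12,76.64
2008,39164.50,54.20,79.43,23.74,67.49
2009,1198139.50,58.17,80.36,29.78,56.17
2010,46494.00,22.22,61.34,30.19,38.51
2011,122486.75,3.91,59.29,11.85,12.71
2012,111290.25,,58.97,27.14,88.14
2013,532279.00,,63.72,44.37,47.23
2014,117193.00,,69.59,48.26,51.04
2015,2073041.25,,61.02,24.38,61.69
2016,201944.75,,58.92,30.75,55.52
2017,292026.50,,65.17,,52.91
all,11623847.75,34.53,65.89,28.11,63.22
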