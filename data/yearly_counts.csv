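year,papers,ratio_pct,ranking
1996,5713,3.36,19
1997,5549,3.26,20
1998,5853,3.44,18
1999,5877,3.46,17
2000,5947,3.5,16
2001,6199,3.64,14
2002,6456,3.8,13
2003,6668,3.92,12
2004,7564,4.45,11
2005,8545,5.02,10
2006,9845,5.79,9
2007,10112,5.94,8
2008,10352,6.09,7
2009,10868,6.39,6
2010,11031,6.49,5
2011,11518,6.77,4
2012,11986,7.05,2
2013,11695,6.88,3
2014,12251,7.2,1
2015,6070,3.57,15
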