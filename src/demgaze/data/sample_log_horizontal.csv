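# source: sample interval log, horizontal test (excerpt; serials 6-37 and 43-75 elided)
Serial No.,Character No.,Rest Time(s),Transfer Time(s)
1,2,0.03,0.07
2,5,0.03,0.11
3,9,0.03,1.09
4,4,0.07,0.04
5,3,0.06,0.29
38,4,0.04,0.05
39,6,0.06,0.38
40,3,0.10,0.51
41,6,0.14,1.15
42,3,0.05,0.21
76,3,0.03,0.47
77,7,0.07,0.43
78,5,0.03,0.45
79,9,0.17,1.86
80,8,-,-
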