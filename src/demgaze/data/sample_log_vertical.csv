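# source: sample interval log, vertical test (excerpt; serials 6-37 and 43-75 elided)
Serial No.,Character No.,Rest Time(s),Transfer Time(s)
1,3,0.10,0.53
2,7,0.03,0.20
3,5,0.10,0.10
4,9,0.19,0.03
5,8,0.19,0.20
38,3,0.28,0.09
39,6,0.12,0.07
40,4,-,-
41,6,0.09,0.06
42,3,0.12,0.03
76,3,0.37,0.49
77,7,0.25,0.18
78,5,0.46,0.19
79,9,0.44,0.03
80,8,-,-
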