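instrument,column,PQ-1,PQ-2,PQ-3,PQ-4,PQ-5
Agilent 1100,1#,2.162,1.335,0.737,0.654,0.974
Agilent 1100,2#,2.182,1.353,0.745,0.663,0.990
Agilent 1100,3#,2.143,1.325,0.729,0.647,0.969
Shimadzu LC-20AT,1#,2.165,1.337,0.740,0.655,0.972
Shimadzu LC-20AT,2#,2.186,1.352,0.751,0.659,0.987
Shimadzu LC-20AT,3#,2.146,1.325,0.730,0.649,0.967
Agilent 1260,1#,2.160,1.340,0.740,0.655,0.980
Agilent 1260,2#,2.185,1.357,0.746,0.660,1.001
Agilent 1260,3#,2.144,1.329,0.730,0.651,0.976
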