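level,PQ-1,PQ-2,PQ-3,PQ-4,PQ-5
C1,2.174,1.296,0.735,0.651,1.009
C2,2.141,1.317,0.720,0.635,1.024
C3,2.204,1.326,0.731,0.653,0.975
C4,2.221,1.382,0.752,0.671,0.975
C5,2.146,1.368,0.753,0.664,0.955
C6,2.084,1.322,0.732,0.648,0.939
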