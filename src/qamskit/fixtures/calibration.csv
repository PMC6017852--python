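analyte,slope,intercept,r,lod_ug_ml,loq_ug_ml,range_low_ug_ml,range_high_ug_ml
PQ-1,42.681,-59.049,0.9990,0.110,0.404,10.9,40.9
PQ-2,65.376,-5.5050,0.9997,0.066,0.241,2.0,9.8
PQ-3,119.41,-110.70,0.9998,0.039,0.139,20.6,62.0
PQ-4,133.80,-38.727,0.9997,0.033,0.122,5.2,31.3
PQ-5,96.928,-45.405,0.9991,0.058,0.188,1.5,14.1
PQ-6,86.712,-2.3510,0.9999,0.051,0.186,2.0,100.0
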