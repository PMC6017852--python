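key,item,value,note
rcf_mean,PQ-1,2.162,
rcf_mean,PQ-2,1.335,
rcf_mean,PQ-3,0.737,
rcf_mean,PQ-4,0.654,
rcf_mean,PQ-5,0.980,published value 0.974 is inconsistent with its own column; recomputed column mean used
rcf_rsd,PQ-1,2.3,
rcf_rsd,PQ-2,2.5,
rcf_rsd,PQ-3,1.8,
rcf_rsd,PQ-4,1.9,
rcf_rsd,PQ-5,3.3,
robustness_mean,PQ-1,2.164,
robustness_mean,PQ-2,1.339,
robustness_mean,PQ-3,0.739,
robustness_mean,PQ-4,0.655,
robustness_mean,PQ-5,0.980,
batch_mean,PQ-6,15.89,
batch_mean,PQ-1,21.34,
batch_mean,PQ-2,4.01,
batch_mean,PQ-3,31.15,
batch_mean,PQ-4,13.80,
batch_mean,PQ-5,6.51,
batch_rsd,PQ-6,15.4,
batch_rsd,PQ-1,22.7,
batch_rsd,PQ-2,25.0,published value 24.9 is inconsistent with both printed columns; recomputed column RSD used
batch_rsd,PQ-3,13.3,
batch_rsd,PQ-4,18.7,
batch_rsd,PQ-5,12.1,
total_mean,,92.71,
total_rsd,,13.2,
pc1_pct,,56.8,tolerance 1.0
pc12_pct,,85.5,tolerance 1.0
hca_group,S1,1,
hca_group,S2,1,
hca_group,S3,1,
hca_group,S4,1,
hca_group,S5,1,
hca_group,S6,1,
hca_group,S7,2,
hca_group,S8,2,
hca_group,S9,2,
hca_group,S10,2,
hca_group,S11,2,
hca_group,S12,2,
hca_group,S13,2,
hca_group,S14,2,
hca_group,S15,3,
hca_group,S16,3,
hca_group,S17,3,
hca_group,S18,3,
hca_group,S19,3,
hca_group,S20,3,
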