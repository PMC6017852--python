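sample,PQ-6_esm,PQ-1_esm,PQ-1_qams,PQ-1_pair_sd,PQ-2_esm,PQ-2_qams,PQ-2_pair_sd,PQ-3_esm,PQ-3_qams,PQ-3_pair_sd,PQ-4_esm,PQ-4_qams,PQ-4_pair_sd,PQ-5_esm,PQ-5_qams,PQ-5_pair_sd,total
S1,15.54,19.45,19.46,0.01,2.77,2.77,0.00,32.81,32.82,0.01,10.51,10.50,0.01,5.07,5.08,0.01,86.18
S2,17.67,21.30,21.31,0.01,2.95,2.95,0.00,36.25,36.27,0.01,11.19,11.18,0.01,5.42,5.44,0.01,94.82
S3,18.93,21.74,21.74,0.01,2.97,2.97,0.00,36.70,36.72,0.01,11.51,11.50,0.01,5.55,5.57,0.01,97.44
S4,19.61,27.19,27.20,0.01,3.91,3.91,0.00,35.95,35.97,0.01,12.51,12.50,0.01,7.05,7.07,0.01,106.27
S5,21.31,24.51,24.52,0.01,4.00,4.00,0.00,35.87,35.89,0.01,12.41,12.40,0.01,6.97,6.98,0.01,105.11
S6,16.38,18.92,18.90,0.02,3.73,3.73,0.00,35.02,35.00,0.01,12.41,12.44,0.02,6.80,6.78,0.01,93.22
S7,14.62,12.49,12.47,0.01,3.27,3.27,0.00,29.20,29.18,0.01,13.12,13.15,0.02,6.93,6.92,0.01,79.60
S8,12.15,12.19,12.21,0.01,2.98,2.98,0.00,28.21,28.19,0.01,12.36,12.36,0.00,6.59,6.59,0.00,74.48
S9,15.71,14.75,14.76,0.00,2.79,2.79,0.00,26.47,26.48,0.01,12.19,12.18,0.01,6.37,6.38,0.01,78.30
S10,11.93,21.11,21.08,0.02,3.61,3.61,0.00,26.22,26.20,0.01,12.39,12.41,0.02,5.90,5.89,0.01,81.12
S11,12.67,19.77,19.74,0.02,3.75,3.75,0.00,25.58,25.56,0.01,12.38,12.40,0.02,5.94,5.92,0.01,80.04
S12,14.00,19.43,19.41,0.02,3.67,3.66,0.00,24.60,24.58,0.01,11.85,11.87,0.02,5.83,5.81,0.01,79.34
S13,13.95,17.89,17.86,0.02,3.89,3.89,0.00,25.31,25.30,0.01,12.83,12.86,0.02,6.18,6.17,0.01,80.02
S14,13.76,18.16,18.19,0.02,4.34,4.34,0.00,27.65,27.64,0.01,14.07,14.07,0.00,6.48,6.48,0.00,84.47
S15,16.83,25.06,25.09,0.02,6.04,6.04,0.00,34.53,34.51,0.01,18.49,18.50,0.00,7.58,7.58,0.00,108.56
S16,15.83,25.23,25.26,0.02,5.73,5.73,0.00,34.24,34.22,0.01,18.96,18.96,0.00,7.71,7.71,0.00,107.73
S17,15.90,27.85,27.86,0.01,5.26,5.27,0.00,31.36,31.38,0.01,17.56,17.55,0.01,8.00,8.02,0.01,105.98
S18,16.98,25.17,25.18,0.01,5.64,5.65,0.00,32.62,32.63,0.01,17.08,17.07,0.01,7.29,7.31,0.01,104.81
S19,17.19,26.89,26.90,0.01,4.47,4.48,0.00,32.22,32.24,0.01,16.33,16.32,0.01,6.39,6.40,0.01,103.53
S20,16.82,27.63,27.65,0.01,4.40,4.41,0.00,32.24,32.26,0.01,15.85,15.84,0.01,6.12,6.14,0.01,103.10
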