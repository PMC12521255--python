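indicator_code,mean,sd
smart_devices,3.08,0.77
S_1,3.25,0.65
S_2,3.21,0.67
S_3,2.97,0.72
S_4,3.10,0.68
S_5,2.88,0.75
online_software,2.87,0.81
S_6,3.14,0.68
S_7,2.98,0.75
S_8,2.95,0.77
S_9,2.56,0.80
S_10,2.37,0.93
S_11,3.23,0.64
offline_services,2.55,0.85
S_12,2.83,0.65
S_13,2.76,0.67
S_14,2.31,1.02
S_15,2.44,0.74
S_16,2.45,0.74
S_17,2.39,0.93
S_18,2.68,0.67
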