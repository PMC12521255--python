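indicator_code,C1,C2,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12
S_1,2.81,-1.37,1.36,-2.65,1.8,-2.13,2.57,-1.21,1.05,-2.79,2.02,-0.9
S_2,2.95,-0.5,1.27,-2.88,-1.68,0.05,1.75,1.34,-0.08,-0.1,-0.05,-2.86
S_3,-0.86,0.05,-1.95,0.77,1.64,-0.33,-0.05,-1.02,0.2,0.12,-0.75,0.67
S_4,1.75,1.54,-2.05,-0.15,-1.66,0.29,-0.05,-1.05,-0.05,0.13,-0.86,2.95
S_5,1.83,-0.67,0.05,-2.25,2.5,-0.25,1.55,-1.75,1.1,-1.48,-1.01,-0.33
S_6,3.15,-0.28,1.88,-2.85,-1.79,0.15,2.36,0.03,-0.01,-0.02,2.05,-2.05
S_7,0.89,1.85,-3.11,-0.04,-1.33,-0.08,1.25,-0.6,-0.06,-0.8,-0.01,2.55
S_8,0.22,2.35,-1.15,0.89,-0.17,-0.25,0.04,0.2,-0.03,0.32,-1.18,2.31
S_9,-1.7,0.09,-1.88,1.61,1.72,-0.31,0.09,-1.03,0.22,0.8,-0.76,1.05
S_10,-1.35,-3.55,-0.39,-0.16,-0.06,-0.07,-2.68,-1.65,-0.42,-0.03,-0.14,1.56
S_11,2.92,-1.97,2.27,-3.03,-0.15,0.11,2.18,-1.66,-0.06,-0.25,0.2,-2.85
S_12,3.11,-0.35,1.95,-2.76,-1.58,0.09,2.58,1.27,-0.16,-0.19,0.01,-2.45
S_13,1.6,1.45,-2.34,-0.12,-1.77,0.22,-0.17,-0.95,-0.15,0.02,-0.9,2.9
S_14,-0.95,-2.19,-0.66,2.15,0.55,-0.11,0.62,-1.05,1.02,1.58,-2.14,2.57
S_15,-3.06,-0.06,2.85,1.05,1.01,-0.12,-2.28,-1.44,-1.15,1.95,2.13,-1.28
S_16,-1.78,0.04,-1.89,1.45,1.77,-0.34,0.15,-1.12,0.27,1.02,-0.86,0.82
S_17,0.25,2.55,-1.15,0.91,-0.23,-0.29,0.01,0.09,-0.08,1.44,-1.26,2.15
S_18,1.66,1.25,-2.12,-0.2,-1.96,0.4,-0.11,-0.95,-0.08,0.08,-0.9,2.74
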