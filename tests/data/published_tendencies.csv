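code,P,A,D,dist_Joy,dist_Relaxation,dist_Surprise,dist_Reliance,dist_Boredom,dist_Fear,dist_Anxiety,dist_Anger,tendency
S_1,2.705,1.6,1.36,0.3999,2.3386,1.5106,4.3855,4.8402,4.1597,4.354,4.7725,Joy
S_2,1.92,-0.6425,1.0,2.081,0.2751,2.4865,2.9188,3.1236,3.8191,3.4381,4.2903,Relaxation
S_3,-0.45,0.465,-0.5225,3.8336,3.2723,2.6096,1.8022,1.746,1.6172,0.5316,2.001,Anxiety
S_4,0.43,-0.7525,-1.335,4.113,2.9655,3.1853,0.161,1.1892,2.5584,1.8846,3.6033,Reliance
S_5,1.7775,0.9775,0.4325,1.4192,1.798,0.7649,2.9628,3.4504,2.93,3.0001,3.7632,Surprise
S_6,2.095,0.1275,0.9425,1.3621,0.8005,1.7796,3.1072,3.4591,3.6097,3.4325,4.2034,Relaxation
S_7,0.745,-0.6475,-1.41,3.9446,2.853,3.0274,0.3967,1.521,2.6817,2.1018,3.8104,Reliance
S_8,-0.2375,-0.975,-0.81,4.335,3.0743,3.4788,0.9327,0.4026,2.3841,1.489,3.0545,Boredom
S_9,-1.005,0.475,-0.6,4.3441,3.7708,3.1021,2.0908,1.8052,0.8294,0.1672,1.6677,Anxiety
S_10,-0.96,1.25,-0.575,4.2302,4.0263,2.833,2.624,2.5505,0.0873,0.9317,1.5632,Fear
S_11,2.095,0.92,1.2375,0.757,1.8817,1.3417,3.6448,3.9894,3.5805,3.6221,4.1285,Joy
S_12,2.16,-0.6225,1.0375,1.9689,0.8189,2.5105,3.0832,3.3399,4.0073,3.6525,4.5053,Relaxation
S_13,0.3825,-0.7925,-1.4025,4.2044,3.0495,3.2686,0.0798,1.1655,2.5851,1.9,3.6295,Reliance
S_14,-1.015,0.4125,-0.525,4.3296,3.7287,3.1175,2.093,1.7602,0.8989,0.1543,1.6339,Anxiety
S_15,-2.085,1.16,0.775,4.8979,4.6544,3.8844,3.8848,3.2916,1.8319,1.9919,0.2127,Anger
S_16,-1.025,0.4975,-0.525,4.3235,3.7625,3.092,2.0656,1.8434,0.8162,0.2194,1.5939,Anxiety
S_17,-0.5225,-1.0325,-0.7725,4.5471,3.289,3.679,1.1759,0.2279,2.3715,1.4256,2.925,Boredom
S_18,0.4175,-0.79,-1.335,4.1381,2.9744,3.2194,0.1489,1.1638,2.582,1.8972,3.6145,Reliance
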