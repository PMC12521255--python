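no,name,P,A,D,polarity
01,Joy,2.77,1.21,1.42,positive
02,Relaxation,2.19,-0.66,1.05,positive
03,Surprise,1.72,1.71,0.22,positive
04,Reliance,0.39,-0.81,-1.48,positive
05,Boredom,-0.53,-1.25,-0.84,negative
06,Fear,-0.93,1.3,-0.64,negative
07,Anxiety,-0.95,0.32,-0.63,negative
08,Anger,-1.98,1.1,0.6,negative
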