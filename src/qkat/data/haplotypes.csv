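name,frequency,3DL3,2DS2,2DL2,2DL3,2DP1,2DL1,3DP1,2DL4,3DL1ex4,3DL1ex9,3DS1,2DL5,2DS3,2DS5,2DS1,2DS4Total,2DS4FL,2DS4Del,3DL2ex4,3DL2ex9
A-2DS4FL,0.4,1,0,0,1,1,1,1,1,1,1,0,0,0,0,0,1,1,0,1,1
A-2DS4Del,0.27,1,0,0,1,1,1,1,1,1,1,0,0,0,0,0,1,0,1,1,1
B-01,0.1,1,1,1,0,1,1,1,1,1,1,0,1,1,0,0,1,0,1,1,1
B-02,0.07,1,1,1,0,1,1,1,1,0,0,1,2,1,1,1,0,0,0,1,1
B-03,0.11,1,0,0,1,1,1,1,1,0,0,1,1,1,0,1,0,0,0,1,1
B-del,0.05,1,1,1,0,0,0,1,1,1,1,0,0,0,0,0,1,0,1,1,1
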