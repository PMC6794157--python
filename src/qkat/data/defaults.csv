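locus,most_frequent_cn
3DL3,2
2DS2,1
2DL2,1
2DL3,2
2DP1,2
2DL1,2
3DP1,2
2DL4,2
3DL1ex4,2
3DL1ex9,2
3DS1,1
2DL5,1
2DS3,1
2DS5,1
2DS1,1
2DS4Total,2
2DS4FL,1
2DS4Del,1
3DL2ex4,2
3DL2ex9,2
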