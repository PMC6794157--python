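reaction,locus,role,forward_primers,forward_nM,reverse_primer,reverse_nM,probe,probe_nM,channel
1,3DP1,kir_a,A4F,250,A5R,250,P4a,150,465-510
1,2DL2,kir_b,2DL2F4,400,C3R2,600,P5b,150,618-660
1,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
2,2DS2,kir_a,A2F,400,A6R,400,P4a,200,465-510
2,2DL3,kir_b,D1F,400,D1R,400,P9,150,618-660
2,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
3,3DL3,kir_a,A8Fa|A8Fb,500,A8R,500,P4a,150,465-510
3,2DS4Del,kir_b,2DS4Del,250,2DS4R2,250,P5b,150,618-660
3,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
4,3DL1ex4,kir_a,B1F,250,B1R,125,P4b,150,465-510
4,3DL1ex9,kir_b,D4F,250,D4R2,500,P9,150,618-660
4,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
5,3DS1,kir_a,B2F,250,B1R,250,P4b,150,465-510
5,2DL4,kir_b,C1F,200,C1R,200,P5b-2DL4,150,618-660
5,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
6,2DL1,kir_a,B3F,500,B3R,125,P4b,150,465-510
6,2DP1,kir_b,D3F,250,D3R,500,P9,150,618-660
6,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
7,2DS1,kir_a,B4F,500,B4R,250,P4b,150,465-510
7,2DL5,kir_b,D2F,500,D2R,500,P9,150,618-660
7,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
8,2DS3,kir_a,B5F,250,B5R,250,P4b,150,465-510
8,3DL2ex9,kir_b,D4F,250,D5R,125,P9,150,618-660
8,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
9,3DL2ex4,kir_a,A1F,200,A1R,200,P4a,150,465-510
9,2DS4FL,kir_b,2DS4FL,250,2DS4R2,500,P5b,150,618-660
9,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
10,2DS5,kir_a,B6F2,200,B6R3,200,P4b,150,465-510
10,2DS4Total,kir_b,C5F,250,C5R,250,P5b,150,618-660
10,STAT6,reference,STAT6F,200,STAT6R,200,PSTAT6,150,533-580
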