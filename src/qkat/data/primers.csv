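assay,primer,direction,sequence,length,tm,gc_percent,exon,start,end,amplicon_bp,alleles_missed
3DL2ex4,A1F,forward,GCCCCTGCTGAAATCAGG,18,52,61.1,4,399,416,179,"3DL2*008, *021, *027, *038."
3DL2ex4,A1R,reverse,CTGCAAGGACAGGCATCAA,19,53,52.6,4,559,577,179,3DL2*048
3DP1,A4F,forward,GTCCCCTGGTGAAATCAGA,19,49,52.6,4,398,416,112,
3DP1,A5R,reverse,GTGAGGCGCAAAGTGTCA,18,52,55.6,4,492,509,112,
2DS2,A2F,forward,GTCGCCTGGTGAAATCAGA,19,49,52.6,4,398,416,111,
2DS2,A6R,reverse,TGAGGTGCAAAGTGTCCTTAT,21,51,42.9,4,488,508,111,
3DL3,A8Fa,forward,GTGAAATCGGGAGAGACG,18,50,55.6,4,406,423,139,
3DL3,A8Fb,forward,GGTGAAATCAGGAGAGACG,19,50,52.6,4,405,423,139,"3DL3*054, 3DL3*00905."
3DL3,A8R,reverse,AGTTGACCTGGGAACCCG,18,51,61.1,4,526,543,139,
3DL1ex4,B1F,forward,CATCGGTCCCATGATGCT,18,51,55.6,4,549,566,85,"3DL1*00505, 3DL1*006, 3DL1*054, 3DL1*086, 3DL1*089"
3DL1ex4,B1R,reverse,GGGAGCTGACAACTGATAGG,20,52,55.0,4,614,633,85,3DL1*00502
3DS1,B2F,forward,CATCGGTTCCATGATGCG,18,51,55.6,4,549,566,85,3DS1*047; may pick up 3DL1*054.
3DS1,B1R,reverse,GGGAGCTGACAACTGATAGG,20,52,55.0,4,614,633,85,
2DL1,B3F,forward,TTCTCCATCAGTCGCATGAC,20,52,50.0,4,544,563,96,"2DL1*020, 2DL1*028"
2DL1,B3R,reverse,GTCACTGGGAGCTGACAC,18,50,61.1,4,622,639,96,"2DL1*023, 2DL1*029, 2DL1*030"
2DS1,B4F,forward,TCTCCATCAGTCGCATGAA,19,51,47.4,4,545,563,96,2DS1*001
2DS1,B4R,reverse,GGTCACTGGGAGCTGAC,17,49,64.7,4,624,640,96,
2DS3,B5F,forward,CTCCATCGGTCGCATGAG,18,53,61.1,4,546,563,96,
2DS3,B5R,reverse,GGGTCACTGGGAGCTGAA,18,51,61.1,4,624,641,96,
2DS5,B6F2,forward,AGAGAGGGGACGTTTAACC,19,50,52.6,4,475,493,173,
2DS5,B6R3,reverse,TCCAGAGGGTCACTGGGC,18,53,66.7,4,630,647,173,2DS5*003
2DL4,C1F,forward,GCAGTGCCCAGCATCAAT,18,52,55.6,5,808,825,83,
2DL4,C1R,reverse,CCGAAGCATCTGTAGGTCT,19,52,52.6,5,872,890,83,"2DL4*018, 2DL4*019"
2DL2,2DL2F4,forward,GAGGTGGAGGCCCATGAAT,19,52,57.9,5,778,796,151,2DL2*009; 782G changed to A.
2DL2,C3R2,reverse,TCGAGTTTGACCACTCGTAT,20,51,45.0,5,909,928,151,
2DS4Total,C5F,forward,TCCCTGCAGTGCGCAGC,17,57,70.6,5,803,819,120,
2DS4Total,C5R,reverse,TTGACCACTCGTAGGGAGC,19,52,57.9,5,904,922,120,2DS4*013
2DS4Del,2DS4Del,forward,CCTTGTCCTGCAGCTCCAT,19,54,57.9,5,750,768,203,
2DS4Del,2DS4R2,reverse,TGACGGAAACAAGCAGTGGA,20,53,50.0,5,933,952,203,
2DS4FL,2DS4FL,forward,CCGGAGCTCCTATGACATG,19,53,57.9,5,744,762,209,
2DS4FL,2DS4R2,reverse,TGACGGAAACAAGCAGTGGA,20,53,50.0,5,933,952,209,
2DL3,D1F,forward,AGACCCTCAGGAGGTGA,17,48,58.8,9,1180,1196,156,
2DL3,D1R,reverse,CAGGAGACAACTTTGGATCA,20,50,45.0,9,1316,1335,156,"2DL3*010, 2DL3*017, 2DL3*01801 and 2DL3*01802"
2DL5,D2F,forward,CACTGCGTTTTCACACAGAC,20,52,50.0,9,1214,1233,120,2DL5B*011 and 2DL5B*020
2DL5,D2R,reverse,GGCAGGAGACAATGATCTT,19,49,47.4,9,1315,1333,120,
2DP1,D3F,forward,CCTCAGGAGGTGACATACGT,20,53,55.0,9,1184,1203,121,
2DP1,D3R,reverse,TTGGAAGTTCCGTGTACACT,20,50,45.0,9,1285,1304,121,
3DL1ex9,D4F,forward,CACAGTTGGATCACTGCGT,19,52,52.6,9,1203,1221,93,"3DL1*061, 3DL1*068"
3DL1ex9,D4R2,reverse,CCGTGTACAAGATGGTATCTGTA,23,53,43.5,9,1273,1295,93,"3DL1*05901, 3DL1*05902, 3DL1*060, 3DL1*061, 3DL1*064, 3DL1*065, 3DL1*094N, 3DL1*098"
3DL2ex9,D4F,forward,CACAGTTGGATCACTGCGT,19,52,52.6,9,1203,1221,156,
3DL2ex9,D5R,reverse,GACCTGACTGTGGTGCTCG,19,54,63.2,9,1340,1358,156,
STAT6,STAT6F,forward,CCAGATGCCTACCATGGTGC,20,54,60.0,,,,129,
STAT6,STAT6R,reverse,CCATCTGCACAGACCACTCC,20,54,60.0,,,,129,
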