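name,sense,dye_5p,quencher_3p,sequence,length,tm,gc_percent,exon,start,end
P4a,sense,FAM,BHQ-1,TCATCCTGCAATGTTGGTCAGATGTCA,27,60,44.4,4,425,451
P4b,antisense,FAM,BHQ-1,AACAGAACCGTAGCATCTGTAGGTCCCT,28,62,50.0,4,576,603
P5b,sense,ATTO647N,BHQ-2,AACATTCCAGGCCGACTTTCCTCTG,25,60,52.0,5,828,852
P5b-2DL4,sense,ATTO647N,BHQ-2,AACATTCCAGGCCGACTTCCCTCTG,25,61,56.0,5,828,852
P9,sense,ATTO647N,BHQ-2,CCCTTCTCAGAGGCCCAAGACACC,24,60,62.5,9,1246,1269
PSTAT6,unspecified,ATTO550,BHQ-2,CTGATTCCTCCATGAGCATGCAGCTT,26,62,50.0,,,
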