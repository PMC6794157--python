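rule_id,subrule,description,lhs,rhs
1,a,Framework genes are present on both haplotypes,3DL3,2
1,b,Framework genes are present on both haplotypes,3DP1,2
1,c,Framework genes are present on both haplotypes,2DL4,2
1,d,Framework genes are present on both haplotypes,3DL2ex4,2
1,e,Framework genes are present on both haplotypes,3DL2ex9,2
2,a,2DS2 and 2DL2 are in strong LD,2DS2,2DL2
3,a,2DL2 and 2DL3 are alleles of the same gene,2DL2+2DL3,2
4,a,2DP1 and 2DL1 are in strong LD,2DP1,2DL1
5,a,Exon 4 and exon 9 assays of 3DL1 must agree,3DL1ex4,3DL1ex9
5,b,Exon 4 and exon 9 assays of 3DL2 must agree,3DL2ex4,3DL2ex9
6,a,3DL1 and 3DS1 are alleles of the same gene,3DL1ex4+3DS1,2
7,a,2DS3 and 2DS5 are carried with 2DL5,2DS3+2DS5,2DL5
8,a,3DS1 and 2DS1 are in strong LD,3DS1,2DS1
9,a,2DS1 and 2DS4 are mutually exclusive per haplotype,2DS1+2DS4Total,2
10,a,2DS4FL and 2DS4Del are variants of 2DS4,2DS4FL+2DS4Del,2DS4Total
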