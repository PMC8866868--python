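# Reference-cohort accounting: maternal-plasma cfDNA concentration and the
# expected (from parental + amniotic-fluid genotypes) vs observed (detected
# in plasma) number of informative markers per family. Family 2's
# concentration was below the quantitation range and is stored as missing.
family_id,cfdna_conc_ng_per_ul,expected_informative,observed_informative
1,0.388,4,4
2,,2,1
3,0.754,2,2
4,0.204,4,4
5,0.266,6,6
6,0.414,6,6
7,0.716,6,6
8,0.63,3,3
9,0.2,3,3
10,0.696,2,2
11,0.632,4,4
12,0.538,3,3
13,1.03,4,4
14,1.03,2,2
15,1.12,1,1
16,0.82,1,1
17,1.115,2,2
18,1.43,3,3
19,1.14,2,2
20,0.764,1,1
21,0.606,5,5
22,0.224,4,4
23,0.54,2,2
24,0.392,0,0
25,0.156,1,1
26,0.884,4,4
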