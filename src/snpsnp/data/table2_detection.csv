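# Per-primer cffDNA detection tallies across the 26-family reference cohort:
# only the 26 primers that were informative in at least one family appear.
primer_id,successful,total,arms_amplicon_bp,sbe_amplicon_bp,observed_size_bp
MH1-F1,1,1,134,26,34
MH2-F1,4,4,108,32,41
MH2-F2,1,1,108,32,41
MH3-F1,1,2,121,36,42
MH3-F2,3,3,121,36,41
MH4-F1,5,5,101,43,46
MH4-F2,1,1,101,43,46
MH5-F1,4,4,60,52,56
MH5-F2,1,1,60,52,56
MH6-F1,5,5,114,61,64
MH6-F2,1,1,114,61,64
MH7-F1,1,1,90,65,67
MH7-F2,4,4,90,65,67
MH8-F1,7,7,126,71,77
MH8-F2,3,3,126,71,77
MH9-F1,1,1,150,27,35
MH9-F2,1,1,150,27,33
MH10-F1,2,2,106,31,39
MH10-F2,5,5,106,31,38
MH11-F1,1,1,69,35,43
MH11-F2,6,6,69,35,42
MH12-F2,2,2,141,39,44
MH13-F1,6,6,95,43,48
MH14-F2,8,8,79,58,61
MH15-F1,1,1,113,63,68
MH15-F2,1,1,113,63,68
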