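# GWAS candidate genes for adult hearing ability
PCDH20
GRM7
ESRRG
SIK3
SLC28A3
TRIOBP
ISG20
ACAN
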