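alias,gene
CD31,PECAM1
CD45,PTPRC
CD10,MME
CK18,KRT18
PDGFRB1,PDGFRB
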