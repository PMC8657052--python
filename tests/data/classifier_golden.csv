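PDGFRAB,CD45,CD34,VIM,CK18,PAX28,CXCR4,cell_type
0,0,0,0,0,0,0,Other
0,0,0,0,0,0,1,Other
0,0,0,0,0,1,0,Other
0,0,0,0,0,1,1,Tumor
0,0,0,0,1,0,0,Other
0,0,0,0,1,0,1,Tumor
0,0,0,0,1,1,0,Tumor
0,0,0,0,1,1,1,Tumor
0,0,0,1,0,0,0,Other
0,0,0,1,0,0,1,Tumor
0,0,0,1,0,1,0,Tumor
0,0,0,1,0,1,1,Tumor
0,0,0,1,1,0,0,Tumor
0,0,0,1,1,0,1,Tumor
0,0,0,1,1,1,0,Tumor
0,0,0,1,1,1,1,Tumor
0,0,1,0,0,0,0,Endothelial
0,0,1,0,0,0,1,Other
0,0,1,0,0,1,0,Other
0,0,1,0,0,1,1,Other
0,0,1,0,1,0,0,Other
0,0,1,0,1,0,1,Other
0,0,1,0,1,1,0,Other
0,0,1,0,1,1,1,Other
0,0,1,1,0,0,0,Other
0,0,1,1,0,0,1,Other
0,0,1,1,0,1,0,Other
0,0,1,1,0,1,1,Other
0,0,1,1,1,0,0,Other
0,0,1,1,1,0,1,Other
0,0,1,1,1,1,0,Other
0,0,1,1,1,1,1,Other
0,1,0,0,0,0,0,Immune
0,1,0,0,0,0,1,Immune
0,1,0,0,0,1,0,Other
0,1,0,0,0,1,1,Other
0,1,0,0,1,0,0,Other
0,1,0,0,1,0,1,Other
0,1,0,0,1,1,0,Other
0,1,0,0,1,1,1,Other
0,1,0,1,0,0,0,Immune
0,1,0,1,0,0,1,Immune
0,1,0,1,0,1,0,Other
0,1,0,1,0,1,1,Other
0,1,0,1,1,0,0,Other
0,1,0,1,1,0,1,Other
0,1,0,1,1,1,0,Other
0,1,0,1,1,1,1,Other
0,1,1,0,0,0,0,Immune
0,1,1,0,0,0,1,Immune
0,1,1,0,0,1,0,Other
0,1,1,0,0,1,1,Other
0,1,1,0,1,0,0,Other
0,1,1,0,1,0,1,Other
0,1,1,0,1,1,0,Other
0,1,1,0,1,1,1,Other
0,1,1,1,0,0,0,Immune
0,1,1,1,0,0,1,Immune
0,1,1,1,0,1,0,Other
0,1,1,1,0,1,1,Other
0,1,1,1,1,0,0,Other
0,1,1,1,1,0,1,Other
0,1,1,1,1,1,0,Other
0,1,1,1,1,1,1,Other
1,0,0,0,0,0,0,Other
1,0,0,0,0,0,1,Other
1,0,0,0,0,1,0,Other
1,0,0,0,0,1,1,Other
1,0,0,0,1,0,0,Other
1,0,0,0,1,0,1,Other
1,0,0,0,1,1,0,Other
1,0,0,0,1,1,1,Other
1,0,0,1,0,0,0,Fibroblast
1,0,0,1,0,0,1,Other
1,0,0,1,0,1,0,Other
1,0,0,1,0,1,1,Other
1,0,0,1,1,0,0,Other
1,0,0,1,1,0,1,Other
1,0,0,1,1,1,0,Other
1,0,0,1,1,1,1,Other
1,0,1,0,0,0,0,Endothelial
1,0,1,0,0,0,1,Other
1,0,1,0,0,1,0,Other
1,0,1,0,0,1,1,Other
1,0,1,0,1,0,0,Other
1,0,1,0,1,0,1,Other
1,0,1,0,1,1,0,Other
1,0,1,0,1,1,1,Other
1,0,1,1,0,0,0,Fibroblast
1,0,1,1,0,0,1,Other
1,0,1,1,0,1,0,Other
1,0,1,1,0,1,1,Other
1,0,1,1,1,0,0,Other
1,0,1,1,1,0,1,Other
1,0,1,1,1,1,0,Other
1,0,1,1,1,1,1,Other
1,1,0,0,0,0,0,Immune
1,1,0,0,0,0,1,Immune
1,1,0,0,0,1,0,Other
1,1,0,0,0,1,1,Other
1,1,0,0,1,0,0,Other
1,1,0,0,1,0,1,Other
1,1,0,0,1,1,0,Other
1,1,0,0,1,1,1,Other
1,1,0,1,0,0,0,Immune
1,1,0,1,0,0,1,Immune
1,1,0,1,0,1,0,Other
1,1,0,1,0,1,1,Other
1,1,0,1,1,0,0,Other
1,1,0,1,1,0,1,Other
1,1,0,1,1,1,0,Other
1,1,0,1,1,1,1,Other
1,1,1,0,0,0,0,Immune
1,1,1,0,0,0,1,Immune
1,1,1,0,0,1,0,Other
1,1,1,0,0,1,1,Other
1,1,1,0,1,0,0,Other
1,1,1,0,1,0,1,Other
1,1,1,0,1,1,0,Other
1,1,1,0,1,1,1,Other
1,1,1,1,0,0,0,Immune
1,1,1,1,0,0,1,Immune
1,1,1,1,0,1,0,Other
1,1,1,1,0,1,1,Other
1,1,1,1,1,0,0,Other
1,1,1,1,1,0,1,Other
1,1,1,1,1,1,0,Other
1,1,1,1,1,1,1,Other
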