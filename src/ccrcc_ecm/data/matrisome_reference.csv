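gene,division,category,go_terms
COL1A1,core matrisome,collagen,GO:0030199;GO:0031012
COL1A2,core matrisome,collagen,GO:0030199;GO:0031012
COL3A1,core matrisome,collagen,GO:0030199;GO:0031012
COL4A1,core matrisome,collagen,GO:0005604;GO:0031012
COL4A2,core matrisome,collagen,GO:0005604;GO:0031012
COL5A1,core matrisome,collagen,GO:0030199;GO:0031012
COL6A1,core matrisome,collagen,GO:0030198;GO:0031012
COL6A2,core matrisome,collagen,GO:0030198;GO:0031012
COL6A3,core matrisome,collagen,GO:0030198;GO:0031012
COL12A1,core matrisome,collagen,GO:0030199;GO:0031012
COL14A1,core matrisome,collagen,GO:0030199;GO:0031012
COL18A1,core matrisome,collagen,GO:0005604;GO:0031012
FN1,core matrisome,glycoprotein,GO:0030198;GO:0031012
TNC,core matrisome,glycoprotein,GO:0030198;GO:0031012
POSTN,core matrisome,glycoprotein,GO:0030198;GO:0031012
TGFBI,core matrisome,glycoprotein,GO:0030198;GO:0031012
FBN1,core matrisome,glycoprotein,GO:0030198;GO:0031012
LAMA4,core matrisome,glycoprotein,GO:0005604;GO:0031012
LAMA5,core matrisome,glycoprotein,GO:0005604;GO:0031012
LAMB1,core matrisome,glycoprotein,GO:0005604;GO:0031012
LAMB2,core matrisome,glycoprotein,GO:0005604;GO:0031012
LAMC1,core matrisome,glycoprotein,GO:0005604;GO:0031012
NID1,core matrisome,glycoprotein,GO:0005604;GO:0031012
VTN,core matrisome,glycoprotein,GO:0030198;GO:0031012
EMILIN1,core matrisome,glycoprotein,GO:0030198;GO:0031012
FBLN1,core matrisome,glycoprotein,GO:0030198;GO:0031012
LTBP1,core matrisome,glycoprotein,GO:0030198;GO:0031012
MFAP4,core matrisome,glycoprotein,GO:0030198;GO:0031012
HSPG2,core matrisome,proteoglycan,GO:0005604;GO:0031012
LUM,core matrisome,proteoglycan,GO:0030198;GO:0031012
DCN,core matrisome,proteoglycan,GO:0030198;GO:0031012
BGN,core matrisome,proteoglycan,GO:0030198;GO:0031012
VCAN,core matrisome,proteoglycan,GO:0030198;GO:0031012
OGN,core matrisome,proteoglycan,GO:0030198;GO:0031012
FMOD,core matrisome,proteoglycan,GO:0030198;GO:0031012
PRELP,core matrisome,proteoglycan,GO:0030198;GO:0031012
FGA,core matrisome,glycoprotein,GO:0050817;GO:0031012
FGB,core matrisome,glycoprotein,GO:0050817;GO:0031012
FGG,core matrisome,glycoprotein,GO:0050817;GO:0031012
MMP2,matrisome-associated,regulator,GO:0030574
TIMP1,matrisome-associated,regulator,GO:0010466
SERPINE1,matrisome-associated,regulator,GO:0010466;GO:0050817
ANXA2,matrisome-associated,ECM-affiliated,GO:0031012
LGALS1,matrisome-associated,ECM-affiliated,GO:0031012
S100A4,matrisome-associated,secreted factor,GO:0005615
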