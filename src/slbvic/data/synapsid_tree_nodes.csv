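node_id,age_ma,territory,label,origin_ma
Synapsida,319.5,West,Synapsida,321
A,317,West,,
B,317,West,,
A1,312,West,,
A2,306,West,,
B1,312,West,,
B2,306,West,,
Edaphosauria,303.5,West,Edaphosauria,
x6,273,West,,
Sphenacodontia,292.5,West,Sphenacodontia,
Tapinocephalidae,283.5,West,Tapinocephalidae,
Therapsida_stem,283.5,West,Therapsida_stem,
t2,273,East,,
T1,273,West,,
T2,273,West,,
T1a,265.1,West,,
T1b,265.1,West,,
T2a,265.1,West,,
T2b,265.1,West,,
Ophiacodontia_W,295,West,,
Edaphosauria_W,290,West,,
Edaphosauria_E,283,East,,
Caseidae_W,272,West,,
Caseidae_E,265,East,,
Caseidae_W2,262,West,,
Nikkasauridae_E,288,East,,
Varanopidae_W,268,West,,
Varanopidae_E,280,East,,
Therapsida_E,270,East,,
Therapsida_E2,258,East,,
Therapsida_W,256,West,,
Tapinocephalus,260.26,West,,
Moschops,260.26,West,,
Struthiocephalus,260.26,West,,
Keratocephalus,260.26,West,,
Mormosaurus,260.26,West,,
Phocosaurus,260.26,West,,
Riebeeckosaurus,260.26,West,,
Criocephalosaurus,260.26,West,,
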