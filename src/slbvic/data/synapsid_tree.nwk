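(((Ophiacodontia_W,(Edaphosauria_W,Edaphosauria_E)Edaphosauria)A1,(Caseidae_W,(Caseidae_E,Caseidae_W2)x6)A2)A,((((((Tapinocephalus,Moschops)T1a,(Struthiocephalus,Keratocephalus)T1b)T1,((Mormosaurus,Phocosaurus)T2a,(Riebeeckosaurus,Criocephalosaurus)T2b)T2)Tapinocephalidae,(Therapsida_E,(Therapsida_E2,Therapsida_W)t2)Therapsida_stem)Sphenacodontia,Nikkasauridae_E)B1,(Varanopidae_W,Varanopidae_E)B2)B)Synapsida;
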