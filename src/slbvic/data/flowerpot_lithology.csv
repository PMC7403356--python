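position,name,lithology
1,Flowerpot gypsum 1,gypsum
2,Flowerpot shale 1,shale
3,Flowerpot gypsum 2,gypsum
4,Flowerpot shale 2,shale
5,Flowerpot dolomite 1,dolomite
6,Blaine base gypsum,gypsum
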