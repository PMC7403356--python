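name,order,older_ma,younger_ma,excepted
Newwellian,1,299.5,298.5,True
Wolfcampian,2,,,False
Leonardian,3,,,False
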