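provenance,abi_kg_yr,bai_cm2_yr
SK,3.6,33.36
UA,4.0,23.20
SL,1.02,5.68
SE,1.69,
ES,,4.34
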